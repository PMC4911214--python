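"""Simulation configuration: the knobs of every synthetic-data generator.

One ``SimulationConfig`` drives all generators. Its defaults describe the study
conditions being emulated: an 18-time-point expression series with two
pre-treatment samples, ~2,000 genes with 500 bp promoter windows, a planted
ATF4-like motif in the responder decile, paired base/spent-media metabolite
panels collected over a 3-day window with 12% evaporation, 30-minute tracer
labelings at 2 x 10^6 cells in 1 ml, serially passaged growth traces, and
two-channel qPCR ladders.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

_VALID_BASES = set("ACGT")


@dataclass
class SimulationConfig:
    seed: int = 0

    # --- promoters / motif planting ---
    n_genes: int = 2000
    promoter_length: int = 500
    planted_motif: str = "TGATGCAA"
    planted_gene_fraction: float = 0.10
    planted_insert_prob: float = 0.60
    background_motif_rate: float = 0.05
    masked_fraction: float = 0.10
    mask_block_len: int = 20

    # --- expression time course ---
    n_timepoints: int = 18
    treated_days: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 17, 20, 22, 25)
    untreated_days: tuple = (-1, 0)
    expression_noise_cv: float = 0.10
    baseline_intensity: float = 500.0
    induction_fold: float = 4.0
    induction_tau_days: float = 3.0
    floor_fraction: float = 0.05
    floor_intensity: float = 10.0
    oscillator_fraction: float = 0.05
    oscillator_amplitude: float = 0.6

    # --- media panel ---
    n_metabolites: int = 40
    evaporation_fraction: float = 0.12
    window_days: float = 3.0
    media_treatment_days: tuple = (2.0, 3.0)
    media_noise_cv: float = 0.05
    media_replicates: int = 2
    flux_scale: float = 1.0
    delta_g_true: float = -0.30
    g_ctrl_true: float = 0.50
    base_abundance: float = 1000.0
    spent_floor: float = 1e-6

    # --- isotope tracer ---
    synthesis_rate_true: float = 1000.0
    consumption_rate_true: float = 10000.0
    scrambling_ratio_true: float = 0.20
    scrambling_fold_depleted: float = 3.0
    synthesis_fold_depleted: float = 2.0
    remethylation_fold_true: float = 1000.0
    tracer_noise_cv: float = 0.10
    tracer_replicates: int = 3
    labeling_volume_ml: float = 1.0
    labeling_cells: float = 2e6
    labeling_duration_hr: float = 0.5
    m0_initial_um: float = 50.0
    calibration_slope_true: float = 10.0
    calibration_intercept_true: float = 0.0
    calibration_standards_um: tuple = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0)

    # --- growth curves ---
    growth_rate_true: float = 0.50
    growth_deficit_true: float = -0.30
    passage_interval_days: float = 2.0
    n_passages: int = 4
    seed_count: float = 3e5
    count_noise_cv: float = 0.05
    growth_replicates: int = 3

    # --- qPCR ---
    copy_number_true: float = 1000.0
    sample_relative_levels: tuple = (1.0, 0.5, 0.1, 0.01)
    ct_noise_sd: float = 0.0
    qpcr_efficiency_true: float = 1.0
    qpcr_intercept_target: float = 38.0
    qpcr_intercept_nuclear: float = 34.0
    ladder_decades: int = 5
    ladder_top_copies: float = 1e7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_timepoints <= 0 or self.n_metabolites <= 0:
            raise ValueError("counts must be positive")
        if not set(self.planted_motif) <= _VALID_BASES:
            raise ValueError("planted_motif must be over {A,C,G,T}")
        if len(self.planted_motif) > self.promoter_length:
            raise ValueError("planted motif longer than promoter")
        for name in (
            "planted_gene_fraction",
            "planted_insert_prob",
            "background_motif_rate",
            "masked_fraction",
            "floor_fraction",
            "oscillator_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.evaporation_fraction < 1.0:
            raise ValueError("evaporation_fraction must lie in [0, 1)")
        if len(self.untreated_days) + len(self.treated_days) != self.n_timepoints:
            raise ValueError("day labels must cover n_timepoints columns")
        if len(self.untreated_days) < 2:
            raise ValueError("at least two untreated columns are required")
        for name in (
            "expression_noise_cv",
            "media_noise_cv",
            "tracer_noise_cv",
            "count_noise_cv",
            "ct_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.labeling_volume_ml <= 0 or self.labeling_cells <= 0:
            raise ValueError("labeling volume and cell count must be positive")
        if self.labeling_duration_hr <= 0 or self.window_days <= 0:
            raise ValueError("durations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("treated_days", "untreated_days", "media_treatment_days",
                    "calibration_standards_um", "sample_relative_levels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
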