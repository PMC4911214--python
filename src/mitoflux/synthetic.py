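"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator emulates one data structure of an mtDNA-depletion profiling
study: TSS-flanking promoter sequences with repeat-masked blocks and a planted
stress-response motif; an 18-time-point expression matrix in which the motif's
genes are smoothly induced; paired base/spent-media metabolite panels with
known signed fluxes, evaporation and a treatment growth deficit; isotopologue
concentrations with known synthesis/consumption/scrambling parameters;
serially passaged growth traces; and two-channel qPCR Ct tables from known
copy numbers.

All randomness flows from a single root seed through named substreams, so the
same ``SimulationConfig`` always reproduces byte-identical outputs and adding
a generator never perturbs the draws of another.  Noise models are the
simplest matching each measurement's support: multiplicative log-normal for
abundances and per-replicate fluxes, additive Gaussian for Ct values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import int_exp2, multiplicative_noise, substream
from .config import SimulationConfig
from .expression import ExpressionTimeCourse
from .media_flux import MediaSamplePanel
from .motifs import PromoterSet, revcomp

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def gene_ids(cfg: SimulationConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(cfg.n_genes)]


def gen_promoters(cfg: SimulationConfig) -> tuple[PromoterSet, set[str]]:
    """Random promoters with masked blocks and a planted motif.

    A fraction ``planted_gene_fraction`` of genes are designated responders;
    each responder receives one motif insertion (random strand, random
    unmasked offset) with probability ``planted_insert_prob``; non-responders
    receive one with probability ``background_motif_rate``.  Masking is drawn
    as contiguous blocks, emulating repeat masking, before insertion — so a
    planted occurrence is never destroyed by the mask.
    """
    motif = cfg.planted_motif
    k = len(motif)
    if k > cfg.promoter_length:
        raise ValueError("planted motif longer than promoter")
    rng = substream(cfg.seed, "promoters")
    ids = gene_ids(cfg)
    n_planted = int(round(cfg.planted_gene_fraction * cfg.n_genes))
    planted = set(
        ids[i] for i in rng.choice(cfg.n_genes, size=n_planted, replace=False)
    )

    L = cfg.promoter_length
    base_idx = rng.integers(0, 4, size=(cfg.n_genes, L))
    n_blocks = int(round(cfg.masked_fraction * L / max(cfg.mask_block_len, 1)))
    sequences: dict[str, str] = {}
    for row, gene in enumerate(ids):
        seq = _BASES[base_idx[row]].copy()
        if n_blocks and cfg.mask_block_len:
            starts = rng.integers(0, L - cfg.mask_block_len + 1, size=n_blocks)
            for s in starts:
                seq[s : s + cfg.mask_block_len] = "N"
        p_insert = (
            cfg.planted_insert_prob if gene in planted else cfg.background_motif_rate
        )
        if rng.random() < p_insert:
            word = motif if rng.random() < 0.5 else revcomp(motif)
            masked = seq == "N"
            window_has_n = np.convolve(masked, np.ones(k, dtype=int), "valid") > 0
            free = np.flatnonzero(~window_has_n)
            if free.size:
                offset = int(free[rng.integers(0, free.size)])
                seq[offset : offset + k] = list(word)
        sequences[gene] = "".join(seq)
    return PromoterSet(sequences, half_width=L // 2), planted


# ---------------------------------------------------------------------------
# expression time course
# ---------------------------------------------------------------------------

def _induction(day: float, fold: float, tau: float) -> float:
    """Smooth saturating induction factor; 1 before treatment, strictly
    increasing during it."""
    if day <= 0:
        return 1.0
    return 1.0 + (fold - 1.0) * (1.0 - 2.0 ** (-day / tau))


def gen_expression(
    cfg: SimulationConfig, planted: set[str]
) -> tuple[ExpressionTimeCourse, dict]:
    """Expression matrix with induced responders plus filter-exercise genes.

    Responder (planted) genes follow a smooth low-frequency induction during
    treatment; other genes are flat with multiplicative log-normal noise.  Two
    disjoint subsets of non-responders exercise the filter criteria: one held
    near the signal floor, one given a pure high-frequency (alternating)
    oscillation.  Returns the time course and the subset memberships.
    """
    rng = substream(cfg.seed, "expression")
    ids = gene_ids(cfg)
    days = np.array(sorted(cfg.untreated_days) + sorted(cfg.treated_days), float)
    treated = np.array(
        [False] * len(cfg.untreated_days) + [True] * len(cfg.treated_days)
    )
    n, m = cfg.n_genes, len(days)

    others = [g for g in ids if g not in planted]
    n_floor = int(round(cfg.floor_fraction * n))
    n_osc = int(round(cfg.oscillator_fraction * n))
    if n_floor + n_osc > len(others):
        raise ValueError("floor and oscillator fractions exceed non-planted genes")
    pick = rng.choice(len(others), size=n_floor + n_osc, replace=False)
    floor_genes = {others[i] for i in pick[:n_floor]}
    osc_genes = {others[i] for i in pick[n_floor:]}

    sigma = 0.5
    baseline = cfg.baseline_intensity * rng.lognormal(0.0, sigma, size=n)
    matrix = np.empty((n, m))
    for row, gene in enumerate(ids):
        if gene in floor_genes:
            level = np.full(m, cfg.floor_intensity)
        elif gene in osc_genes:
            level = baseline[row] * (
                1.0 + cfg.oscillator_amplitude * (-1.0) ** np.arange(m)
            )
        elif gene in planted:
            level = baseline[row] * np.array(
                [_induction(d, cfg.induction_fold, cfg.induction_tau_days)
                 for d in days]
            )
        else:
            level = np.full(m, baseline[row])
        matrix[row] = level
    matrix *= multiplicative_noise(rng, cfg.expression_noise_cv, matrix.shape)

    tc = ExpressionTimeCourse(
        values=pd.DataFrame(matrix, index=pd.Index(ids, name="probeset"),
                            columns=[f"s{i}" for i in range(m)]),
        days=days, treated=treated,
    )
    meta = {"floor_genes": sorted(floor_genes), "oscillator_genes": sorted(osc_genes)}
    return tc, meta


# ---------------------------------------------------------------------------
# media panel
# ---------------------------------------------------------------------------

def _auc(g_ctrl: float, delta_g: float, t_treat: float, T: float) -> float:
    pre = int_exp2(g_ctrl, T - t_treat)
    return pre + 2.0 ** (g_ctrl * (T - t_treat)) * int_exp2(g_ctrl + delta_g, t_treat)


def gen_media_panel(cfg: SimulationConfig) -> tuple[MediaSamplePanel, dict]:
    """Base/spent-media and cell-extract panel with known signed fluxes.

    Each metabolite gets a signed flux (positive = released, negative =
    uptaken) calibrated so the untreated spent/base ratio falls in a realistic
    range; spent media accumulates flux times the condition's AUC cell
    exposure and is then concentrated by evaporation.  Cell-extract totals
    scale with final cell number, encoding the treatment growth deficit
    delta_g; a spent abundance driven below the floor is clipped and flagged.
    """
    rng = substream(cfg.seed, "media")
    mets = [f"met{i:03d}" for i in range(cfg.n_metabolites)]
    base = cfg.base_abundance * rng.lognormal(0.0, 0.5, size=cfg.n_metabolites)

    signs = np.where(np.arange(cfg.n_metabolites) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    magnitude = cfg.flux_scale * np.where(
        signs > 0, rng.uniform(0.2, 1.5, cfg.n_metabolites),
        rng.uniform(0.2, 0.8, cfg.n_metabolites),
    )
    ratio_ctrl = 1.0 + signs * magnitude  # untreated spent/base target

    T = cfg.window_days
    g, dg = cfg.g_ctrl_true, cfg.delta_g_true
    auc_ctrl = int_exp2(g, T)
    flux = base * (ratio_ctrl - 1.0) / auc_ctrl

    conditions = {"untreated": 0.0}
    conditions.update({f"day{t:g}": float(t) for t in cfg.media_treatment_days})

    evap_factor = 1.0 / (1.0 - cfg.evaporation_fraction)  # harvest at t = T
    profile = rng.lognormal(0.0, 0.5, size=cfg.n_metabolites)

    spent_rows, extract_rows, clipped = [], [], []
    for cond, t_treat in conditions.items():
        auc = _auc(g, dg, t_treat, T)
        spent_true = base + flux * auc
        low = spent_true < cfg.spent_floor
        if low.any():
            clipped.extend((cond, mets[i]) for i in np.flatnonzero(low))
            spent_true = np.maximum(spent_true, cfg.spent_floor)
        n_final = 2.0 ** (g * T + dg * t_treat)
        for rep in range(1, cfg.media_replicates + 1):
            noise_s = multiplicative_noise(rng, cfg.media_noise_cv, cfg.n_metabolites)
            noise_e = multiplicative_noise(rng, cfg.media_noise_cv, cfg.n_metabolites)
            for i, met in enumerate(mets):
                spent_rows.append(
                    (cond, rep, met, spent_true[i] * evap_factor * noise_s[i])
                )
                extract_rows.append(
                    (cond, rep, met, profile[i] * n_final * noise_e[i])
                )

    panel = MediaSamplePanel(
        base=pd.Series(base, index=pd.Index(mets, name="metabolite")),
        spent=pd.DataFrame(
            spent_rows, columns=["condition", "replicate", "metabolite", "abundance"]
        ),
        extract=pd.DataFrame(
            extract_rows, columns=["condition", "replicate", "metabolite", "abundance"]
        ),
        window_days=T,
        treatment_days={c: t for c, t in conditions.items()},
    )
    truth = {
        "delta_g_true": dg,
        "g_ctrl_true": g,
        "flux_true": dict(zip(mets, flux.tolist())),
        "ratio_ctrl_true": dict(zip(mets, ratio_ctrl.tolist())),
        "alpha_true": {
            c: _auc(g, dg, t, T) / auc_ctrl for c, t in conditions.items()
        },
        "clipped": clipped,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# isotopologues, growth, qPCR
# ---------------------------------------------------------------------------

def _conc_from_rate(rate: float, cfg: SimulationConfig) -> float:
    """uM concentration produced in the labeling volume by a rate in
    pmol per 10^6 cells per hr."""
    amount_pmol = rate * (cfg.labeling_cells / 1e6) * cfg.labeling_duration_hr
    return amount_pmol / 1000.0 / cfg.labeling_volume_ml


def gen_isotopologues(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Serine isotopologue concentrations from known rate parameters.

    Conditions 'control' and 'depleted': depletion multiplies the synthesis
    rate and the scrambling ratio by their configured fold changes (emulating
    the induced serine-synthesis / methylene-THF phenotype).  Per-replicate
    fluxes carry multiplicative log-normal variability; concentrations follow
    exactly from the per-replicate flux.  Deuterated-formate remethylation
    rows (serine_d / methionine_d, M+1) embed the remethylation fold.
    """
    rng = substream(cfg.seed, "isotopologues")
    conditions = {
        "control": (cfg.synthesis_rate_true, cfg.scrambling_ratio_true),
        "depleted": (
            cfg.synthesis_rate_true * cfg.synthesis_fold_depleted,
            cfg.scrambling_ratio_true * cfg.scrambling_fold_depleted,
        ),
    }
    geom = dict(volume_ml=cfg.labeling_volume_ml, cells=cfg.labeling_cells,
                duration_hr=cfg.labeling_duration_hr)
    rows = []
    for cond, (synth, scramble) in conditions.items():
        for rep in range(1, cfg.tracer_replicates + 1):
            f_synth, f_cons, f_scr = multiplicative_noise(rng, cfg.tracer_noise_cv, 3)
            m3 = _conc_from_rate(synth * f_synth, cfg)
            m1 = scramble * f_scr * m3
            consumed = _conc_from_rate(cfg.consumption_rate_true * f_cons, cfg)
            m0_final = cfg.m0_initial_um - consumed
            if m0_final < 0:
                raise ValueError("consumption exceeds initial serine pool")
            for shift, conc in ((0, m0_final), (1, m1), (3, m3)):
                rows.append(dict(condition=cond, replicate=rep, metabolite="serine",
                                 mass_shift=shift, concentration_um=conc, **geom))
    # 12-hr deuterated-formate labeling: serine_d vs methionine_d M+1
    ser_d_rate = 500.0
    met_d_rate = ser_d_rate / cfg.remethylation_fold_true
    d_geom = dict(volume_ml=cfg.labeling_volume_ml, cells=cfg.labeling_cells,
                  duration_hr=12.0)
    for rep in range(1, cfg.tracer_replicates + 1):
        f_ser, f_met = multiplicative_noise(rng, cfg.tracer_noise_cv, 2)
        for met_name, rate, f in (("serine_d", ser_d_rate, f_ser),
                                  ("methionine_d", met_d_rate, f_met)):
            amount_pmol = rate * f * (cfg.labeling_cells / 1e6) * 12.0
            conc = amount_pmol / 1000.0 / cfg.labeling_volume_ml
            rows.append(dict(condition="control", replicate=rep,
                             metabolite=met_name, mass_shift=1,
                             concentration_um=conc, **d_geom))
    truth = {
        "synthesis_rate_true": {c: s for c, (s, _) in conditions.items()},
        "consumption_rate_true": cfg.consumption_rate_true,
        "scrambling_ratio_true": {c: r for c, (_, r) in conditions.items()},
        "remethylation_fold_true": cfg.remethylation_fold_true,
        "m0_initial_um": cfg.m0_initial_um,
        "serine_d_rate_true": ser_d_rate,
        "methionine_d_rate_true": met_d_rate,
    }
    return pd.DataFrame(rows), truth


def gen_calibration(cfg: SimulationConfig, noise_cv: float = 0.0) -> pd.DataFrame:
    """LC-MS/MS standard ladder: response vs concentration."""
    rng = substream(cfg.seed, "calibration")
    conc = np.asarray(cfg.calibration_standards_um, dtype=float)
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")
    resp = cfg.calibration_slope_true * conc + cfg.calibration_intercept_true
    resp = resp * multiplicative_noise(rng, noise_cv, conc.size)
    return pd.DataFrame({"concentration_um": conc, "response": resp})


def gen_growth(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Serial-passage count records from exponential growth plus count noise."""
    rng = substream(cfg.seed, "growth")
    rates = {
        "control": cfg.growth_rate_true,
        "depleted": cfg.growth_rate_true + cfg.growth_deficit_true,
    }
    rows = []
    for cond, rate in rates.items():
        for rep in range(1, cfg.growth_replicates + 1):
            for p in range(1, cfg.n_passages + 1):
                true_fold = 2.0 ** (rate * cfg.passage_interval_days)
                noise = multiplicative_noise(rng, cfg.count_noise_cv, 1)[0]
                harvest = cfg.seed_count * true_fold * noise
                if harvest <= 0:
                    raise ValueError("non-positive harvest count generated")
                rows.append(dict(condition=cond, replicate=rep, passage_index=p,
                                 seed_count=cfg.seed_count, harvest_count=harvest,
                                 interval_days=cfg.passage_interval_days))
    truth = {"growth_rate_true": rates}
    return pd.DataFrame(rows), truth


def gen_qpcr(cfg: SimulationConfig) -> tuple[dict, pd.DataFrame, dict]:
    """Two-channel qPCR ladders and sample Ct values from known copy numbers.

    Ct = intercept + slope * log10(copies) + Gaussian noise, with slope
    -1/log10(1 + efficiency).  Samples carry mtDNA at configured levels
    relative to the first (reference) sample; the nuclear channel is constant.
    """
    rng = substream(cfg.seed, "qpcr")
    slope = -1.0 / math.log10(1.0 + cfg.qpcr_efficiency_true)
    ladder_copies = cfg.ladder_top_copies / 10.0 ** np.arange(cfg.ladder_decades + 1)

    def ct_of(copies: np.ndarray, intercept: float) -> np.ndarray:
        ct = intercept + slope * np.log10(copies)
        if cfg.ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, cfg.ct_noise_sd, size=ct.shape)
        if (ct <= 0).any():
            raise ValueError("generated non-positive Ct; check intercepts")
        return ct

    ladders = {
        "target": pd.DataFrame({
            "copies": ladder_copies,
            "ct": ct_of(ladder_copies, cfg.qpcr_intercept_target),
        }),
        "nuclear": pd.DataFrame({
            "copies": ladder_copies,
            "ct": ct_of(ladder_copies, cfg.qpcr_intercept_nuclear),
        }),
    }
    cells_per_rxn = 1e4
    nuclear_copies = 2.0 * cells_per_rxn
    levels = np.asarray(cfg.sample_relative_levels, dtype=float)
    if (levels <= 0).any():
        raise ValueError("relative copy levels must be positive")
    sample_ids = [f"sample{i}" for i in range(len(levels))]
    target_copies = cfg.copy_number_true * levels * cells_per_rxn
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "ct_target": ct_of(target_copies, cfg.qpcr_intercept_target),
        "ct_nuclear": ct_of(np.full(levels.size, nuclear_copies),
                            cfg.qpcr_intercept_nuclear),
    })
    truth = {
        "copy_number_true": cfg.copy_number_true,
        "relative_levels_true": dict(zip(sample_ids, levels.tolist())),
        "reference_sample": sample_ids[0],
        "ladder_slope_true": slope,
        "efficiency_true": cfg.qpcr_efficiency_true,
    }
    return ladders, samples, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """In-memory bundle of one full synthetic study."""

    config: SimulationConfig
    promoters: PromoterSet
    planted: set[str]
    expression: ExpressionTimeCourse
    expression_meta: dict
    panel: MediaSamplePanel
    media_truth: dict
    isotopologues: pd.DataFrame
    tracer_truth: dict
    calibration: pd.DataFrame
    passages: pd.DataFrame
    growth_truth: dict
    qpcr_ladders: dict
    qpcr_samples: pd.DataFrame
    qpcr_truth: dict


def generate_all(cfg: SimulationConfig) -> SyntheticDataset:
    promoters, planted = gen_promoters(cfg)
    expr, expr_meta = gen_expression(cfg, planted)
    panel, media_truth = gen_media_panel(cfg)
    iso, tracer_truth = gen_isotopologues(cfg)
    calibration = gen_calibration(cfg)
    passages, growth_truth = gen_growth(cfg)
    ladders, qpcr_samples, qpcr_truth = gen_qpcr(cfg)
    return SyntheticDataset(
        config=cfg, promoters=promoters, planted=planted,
        expression=expr, expression_meta=expr_meta,
        panel=panel, media_truth=media_truth,
        isotopologues=iso, tracer_truth=tracer_truth, calibration=calibration,
        passages=passages, growth_truth=growth_truth,
        qpcr_ladders=ladders, qpcr_samples=qpcr_samples, qpcr_truth=qpcr_truth,
    )


def write_all(dataset: SyntheticDataset, outdir) -> dict:
    """Write every generated input as plain-text files plus a truth sidecar.

    Returns a mapping of artifact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(name: str, frame: pd.DataFrame) -> None:
        p = outdir / name
        frame.to_csv(p, index=False)
        paths[name] = p

    dataset.promoters.to_fasta(outdir / "promoters.fasta")
    paths["promoters.fasta"] = outdir / "promoters.fasta"
    dataset.expression.to_tsv(outdir / "expression.tsv")
    paths["expression.tsv"] = outdir / "expression.tsv"

    base = dataset.panel.base.reset_index()
    base.columns = ["metabolite", "abundance"]
    _csv("base_media.csv", base)
    _csv("spent_media.csv", dataset.panel.spent)
    _csv("cell_extract.csv", dataset.panel.extract)
    design = {
        "window_days": dataset.panel.window_days,
        "harvest_day": dataset.panel.harvest_day,
        "treatment_days": dataset.panel.treatment_days,
    }
    (outdir / "media_design.json").write_text(json.dumps(design, indent=2, sort_keys=True))
    paths["media_design.json"] = outdir / "media_design.json"

    _csv("isotopologues.csv", dataset.isotopologues)
    _csv("calibration.csv", dataset.calibration)
    _csv("passages.csv", dataset.passages)
    _csv("qpcr_ladder_target.csv", dataset.qpcr_ladders["target"])
    _csv("qpcr_ladder_nuclear.csv", dataset.qpcr_ladders["nuclear"])
    _csv("qpcr_samples.csv", dataset.qpcr_samples)

    truth = {
        "config": dataset.config.to_dict(),
        "planted_genes": sorted(dataset.planted),
        "expression": dataset.expression_meta,
        "media": dataset.media_truth,
        "tracer": dataset.tracer_truth,
        "growth": dataset.growth_truth,
        "qpcr": dataset.qpcr_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth.json"] = outdir / "truth.json"
    return paths
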