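"""Stage orchestration: wire the analysis modules into reproducible runs.

``run_pipeline`` executes stages in dependency order

    simulate -> media-flux / filter -> rank -> motifs / tracer / growth / mtdna

writing each stage's tables under the output directory and a JSON manifest
recording the package version, root seed, stage parameters, per-stage row
counts and SHA-256 checksums of every artifact.  Reruns with the same seed
and parameters produce identical manifests and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import expression as expr_mod
from . import growth as growth_mod
from . import media_flux as media_mod
from . import motifs as motif_mod
from . import tracer as tracer_mod
from .config import SimulationConfig
from .synthetic import generate_all, write_all

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "media-flux", "filter", "rank", "motifs",
              "tracer", "growth", "mtdna")

DEFAULTS = {
    "media_flux": {"f_evap": 0.12, "g_ctrl": 0.5, "dialect": "literal",
                   "neutral_tol": 0.05},
    "filter": {"sd_frac_min": 0.075, "signal_floor": 50.0},
    "rank": {"treated_day_min": 1.0, "treated_day_max": 10.0},
    "motifs": {"min_len": 6, "max_len": 6, "gapped9": False,
               "bidirectional": True, "exact_threshold": 8,
               "top_n": 50, "consensus": "TGATGHAAH",
               "background_rate": 0.14},
    "growth": {"window_start": 2.0, "window_end": 6.0},
    "mtdna": {"reference_sample": None},
}


def load_run_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg


def _stage_params(cfg: dict, stage: str) -> dict:
    params = dict(DEFAULTS.get(stage, {}))
    params.update(cfg.get(stage, {}) or {})
    return params


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifact {path.name} "
            f"(run its producing stage first)"
        )
    return path


def run_pipeline(cfg: dict, outdir, stages=None) -> dict:
    """Run the selected stages (default: all) and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or cfg.get("stages") or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    seed = int(cfg.get("seed", 0))
    synth_dir = outdir / "synthetic"
    manifest: dict = {"version": __version__, "seed": seed, "stages": {},
                      "artifacts": {}}

    def _record(stage: str, name: str, path: Path, rows: int | None = None):
        manifest["artifacts"][name] = {"sha256": _sha256(path)}
        if rows is not None:
            manifest["stages"][stage].setdefault("rows", {})[name] = rows

    if "simulate" in stages:
        sim_params = dict(cfg.get("simulate", {}) or {})
        sim_params["seed"] = seed
        sim_cfg = SimulationConfig.from_dict(
            {**SimulationConfig(seed=seed).to_dict(), **sim_params}
        )
        dataset = generate_all(sim_cfg)
        paths = write_all(dataset, synth_dir)
        manifest["stages"]["simulate"] = {"params": sim_cfg.to_dict()}
        for name, p in paths.items():
            _record("simulate", f"synthetic/{name}", p)

    if "media-flux" in stages:
        params = _stage_params(cfg, "media_flux")
        panel = media_mod.load_panel(
            _require(synth_dir / "base_media.csv", "media-flux"),
            _require(synth_dir / "spent_media.csv", "media-flux"),
            _require(synth_dir / "cell_extract.csv", "media-flux"),
            _require(synth_dir / "media_design.json", "media-flux"),
        )
        frames = []
        for cond, t in sorted(panel.treatment_days.items()):
            if t == 0:
                continue
            result, adj, alpha = media_mod.analyze_panel(
                panel, cond, f_evap=params["f_evap"], g_ctrl=params["g_ctrl"],
                dialect=params["dialect"], neutral_tol=params["neutral_tol"],
            )
            result.insert(0, "condition", cond)
            result["delta_g"] = adj.delta_g
            frames.append(result)
        out = pd.concat(frames, ignore_index=True)
        p = outdir / "media_flux.csv"
        out.to_csv(p, index=False)
        manifest["stages"]["media-flux"] = {"params": params}
        _record("media-flux", "media_flux.csv", p, rows=len(out))

    tc = None
    if {"filter", "rank"} & set(stages):
        tc = expr_mod.ExpressionTimeCourse.from_tsv(
            _require(synth_dir / "expression.tsv", "filter/rank")
        )

    if "filter" in stages:
        params = _stage_params(cfg, "filter")
        criteria = expr_mod.FilterCriteria(
            sd_frac_min=params["sd_frac_min"],
            signal_floor=params["signal_floor"],
        )
        flags = expr_mod.filter_probesets(tc, criteria)
        p = outdir / "filter_flags.tsv"
        flags.to_csv(p, sep="\t")
        manifest["stages"]["filter"] = {"params": params}
        _record("filter", "filter_flags.tsv", p, rows=len(flags))

    if "rank" in stages:
        params = _stage_params(cfg, "rank")
        flags_path = outdir / "filter_flags.tsv"
        keep = None
        if flags_path.exists():
            flags = pd.read_csv(flags_path, sep="\t", index_col=0)
            keep = flags.index[flags["kept"]]
        ranked = expr_mod.rank_genes(
            tc, treated_day_range=(params["treated_day_min"],
                                   params["treated_day_max"]),
            keep=keep,
        )
        p = outdir / "ranked_genes.tsv"
        ranked.to_csv(p, sep="\t", index=False)
        manifest["stages"]["rank"] = {"params": params}
        _record("rank", "ranked_genes.tsv", p, rows=len(ranked))

    if "motifs" in stages:
        params = _stage_params(cfg, "motifs")
        ranked = pd.read_csv(
            _require(outdir / "ranked_genes.tsv", "motifs"), sep="\t"
        )
        promoters = motif_mod.PromoterSet.from_fasta(
            _require(synth_dir / "promoters.fasta", "motifs")
        )
        records = motif_mod.enrichment_scan(
            ranked, promoters,
            min_len=params["min_len"], max_len=params["max_len"],
            include_gapped9=params["gapped9"],
            bidirectional=params["bidirectional"],
            exact_threshold=params["exact_threshold"],
        )
        p = outdir / "motif_enrichment.tsv"
        records.to_csv(p, sep="\t", index=False)
        top = ranked.nsmallest(params["top_n"], "rank")["gene_id"]
        k, n, p_tail = motif_mod.consensus_binomial(
            promoters, top, params["consensus"], params["background_rate"]
        )
        consensus = {"consensus": params["consensus"], "top_n": n,
                     "n_with_site": k,
                     "background_rate": params["background_rate"],
                     "binomial_tail_p": p_tail}
        cp = outdir / "consensus_test.json"
        cp.write_text(json.dumps(consensus, indent=2, sort_keys=True))
        manifest["stages"]["motifs"] = {"params": params}
        _record("motifs", "motif_enrichment.tsv", p, rows=len(records))
        _record("motifs", "consensus_test.json", cp)

    if "tracer" in stages:
        iso = pd.read_csv(_require(synth_dir / "isotopologues.csv", "tracer"))
        design = json.loads((synth_dir / "truth.json").read_text()) \
            if (synth_dir / "truth.json").exists() else {}
        m0 = design.get("tracer", {}).get("m0_initial_um", 50.0)
        rates = tracer_mod.summarize_rates(iso, m0_initial_um=m0)
        p = outdir / "tracer_rates.csv"
        rates.to_csv(p, index=False)
        manifest["stages"]["tracer"] = {"params": {"m0_initial_um": m0}}
        _record("tracer", "tracer_rates.csv", p, rows=len(rates))

    if "growth" in stages:
        params = _stage_params(cfg, "growth")
        passages = pd.read_csv(_require(synth_dir / "passages.csv", "growth"))
        rates = growth_mod.fit_growth_rates(
            passages, window=(params["window_start"], params["window_end"])
        )
        p = outdir / "growth_rates.csv"
        rates.to_csv(p, index=False)
        manifest["stages"]["growth"] = {"params": params}
        _record("growth", "growth_rates.csv", p, rows=len(rates))

    if "mtdna" in stages:
        params = _stage_params(cfg, "mtdna")
        samples = pd.read_csv(_require(synth_dir / "qpcr_samples.csv", "mtdna"))
        target = pd.read_csv(_require(synth_dir / "qpcr_ladder_target.csv", "mtdna"))
        nuclear = pd.read_csv(_require(synth_dir / "qpcr_ladder_nuclear.csv", "mtdna"))
        reference = params.get("reference_sample") or samples["sample_id"].iloc[0]
        rel = growth_mod.relative_mtdna(
            samples,
            growth_mod.ladder_fit(target["copies"], target["ct"]),
            growth_mod.ladder_fit(nuclear["copies"], nuclear["ct"]),
            reference_sample=reference,
        )
        p = outdir / "relative_copy_number.csv"
        rel.to_csv(p, index=False)
        manifest["stages"]["mtdna"] = {"params": {"reference_sample": reference}}
        _record("mtdna", "relative_copy_number.csv", p, rows=len(rel))

    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(path, fmt: str) -> dict:
    """Schema check for one input file; returns {errors: [...], warnings: [...]}.

    Formats: 'fasta' (promoters), 'expression' (two-header-row TSV), or the
    CSV tables 'media', 'isotopologues', 'passages', 'qpcr_samples',
    'qpcr_ladder'.  Errors are fatal; warnings note repairs the readers make
    (e.g. lowercase bases are uppercased on load).
    """
    path = Path(path)
    report: dict = {"errors": [], "warnings": []}
    if not path.exists():
        raise FileNotFoundError(path)
    required_columns = {
        "media": {"condition", "replicate", "metabolite", "abundance"},
        "isotopologues": {"condition", "replicate", "metabolite", "mass_shift",
                          "concentration_um", "volume_ml", "cells", "duration_hr"},
        "passages": {"condition", "replicate", "passage_index", "seed_count",
                     "harvest_count", "interval_days"},
        "qpcr_samples": {"sample_id", "ct_target", "ct_nuclear"},
        "qpcr_ladder": {"copies", "ct"},
    }
    if fmt == "fasta":
        from Bio import SeqIO

        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            n += 1
            seq = str(rec.seq)
            if seq != seq.upper():
                report["warnings"].append(
                    f"{rec.id}: lowercase bases will be uppercased on load"
                )
                seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                report["errors"].append(
                    f"{rec.id}: invalid characters {sorted(bad)}"
                )
        if n == 0:
            report["errors"].append("no FASTA records found")
    elif fmt == "expression":
        try:
            expr_mod.ExpressionTimeCourse.from_tsv(path)
        except Exception as exc:  # surfaced as a fatal schema problem
            report["errors"].append(str(exc))
    elif fmt in required_columns:
        table = pd.read_csv(path)
        missing = required_columns[fmt] - set(table.columns)
        if missing:
            report["errors"].append(f"missing columns {sorted(missing)}")
    else:
        raise ValueError(f"unknown input format {fmt!r}")
    return report
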