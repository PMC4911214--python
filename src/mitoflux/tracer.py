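"""Stable-isotope tracer readouts: serine synthesis, consumption, scrambling.

A short labeling (e.g. 30 min with U-13C glucose) converts label flow into
amounts: the M+3 serine that appears in the medium reads out de novo serine
synthesis, the unlabeled (M+0) serine that disappears reads out net
consumption, and after feeding fully labeled (M+3) serine the M+1 serine that
emerges reports reversible mitochondrial SHMT2 exchange ("scrambling") and
hence methylene-THF availability.  Labelings are short enough to be treated as
quasi-linear: rates are amounts divided by cell number and duration, in
pmol per 10^6 cells per hour.  Concentrations come from an external standard
ladder fitted by ordinary least squares.

No natural-abundance isotope correction is applied; results carry a metadata
flag noting this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: 1 uM in 1 mL is 1 nmol = 1000 pmol
PMOL_PER_UM_ML = 1000.0

#: metadata flag: no natural-abundance isotope correction is applied
NATURAL_ABUNDANCE_CORRECTED = False


@dataclass
class CalibrationCurve:
    """Least-squares response-vs-concentration standard curve."""

    standards_um: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float

    def concentration_of(self, response) -> float | np.ndarray:
        """Invert the curve; negative concentrations floor at 0 with a warning."""
        conc = (np.asarray(response, dtype=float) - self.intercept) / self.slope
        if (conc < 0).any():
            logger.warning("response below calibration intercept; flooring at 0 uM")
            conc = np.maximum(conc, 0.0)
        return float(conc) if np.isscalar(response) else conc


def calibrate(responses, standards_um) -> CalibrationCurve:
    """Fit the standard curve (ordinary least squares, response vs conc)."""
    x = np.asarray(standards_um, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("standards and responses differ in length")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationCurve(
        standards_um=x, responses=y,
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


def _check_labeling(volume_ml: float, cells: float, duration_hr: float) -> None:
    if volume_ml <= 0 or cells <= 0:
        raise ValueError("volume and cell count must be positive")
    if duration_hr <= 0:
        raise ValueError("labeling duration must be positive")


def synthesis_rate(
    m3_conc_um: float, volume_ml: float, cells: float, duration_hr: float
) -> float:
    """Serine synthesis rate from labeled (M+3) serine that emerged.

    Assumes no M+3 serine at t = 0 (unlabeled start).  Returns
    pmol per 10^6 cells per hour.
    """
    if m3_conc_um < 0:
        raise ValueError("concentration must be non-negative")
    _check_labeling(volume_ml, cells, duration_hr)
    amount_pmol = m3_conc_um * volume_ml * PMOL_PER_UM_ML
    return amount_pmol / (cells / 1e6) / duration_hr


def consumption_rate(
    m0_initial_um: float, m0_final_um: float,
    volume_ml: float, cells: float, duration_hr: float,
) -> float:
    """Net serine consumption from the unlabeled serine that disappeared.

    Positive = net uptake; a negative value means net release and is reported
    as such.  pmol per 10^6 cells per hour.
    """
    if m0_initial_um < 0 or m0_final_um < 0:
        raise ValueError("concentrations must be non-negative")
    _check_labeling(volume_ml, cells, duration_hr)
    amount_pmol = (m0_initial_um - m0_final_um) * volume_ml * PMOL_PER_UM_ML
    return amount_pmol / (cells / 1e6) / duration_hr


def scrambling_ratio(m1_conc_um: float, m3_conc_um: float) -> float:
    """M+1 / M+3 serine ratio: readout of mitochondrial methylene-THF.

    Requires delivered label (M+3 > 0).
    """
    if m1_conc_um < 0:
        raise ValueError("M+1 concentration must be non-negative")
    if m3_conc_um <= 0:
        raise ValueError("no label delivered (M+3 concentration is zero)")
    return m1_conc_um / m3_conc_um


def remethylation_ratio(met_m1_rate: float, ser_m1_rate: float) -> float:
    """Fold difference of deuterated serine vs methionine synthesis rates.

    Returns ser_m1_rate / met_m1_rate; a zero methionine rate is reported as
    infinite with a warning (remethylation below detection).
    """
    if met_m1_rate < 0 or ser_m1_rate < 0:
        raise ValueError("rates must be non-negative")
    if met_m1_rate == 0:
        logger.warning("methionine M+1 rate is zero; ratio reported as infinite")
        return math.inf
    return ser_m1_rate / met_m1_rate


def summarize_rates(
    measurements: pd.DataFrame,
    m0_initial_um: float,
) -> pd.DataFrame:
    """Per-condition replicate means and SEMs of the tracer readouts.

    ``measurements`` is long-form with columns (condition, replicate,
    metabolite, mass_shift, concentration_um, volume_ml, cells, duration_hr);
    serine rows with mass shifts 0, 1 and 3 are used.  Returns one row per
    condition with synthesis/consumption rates (pmol per 10^6 cells per hr)
    and the scrambling ratio, each with its SEM over replicates.
    """
    required = {"condition", "replicate", "metabolite", "mass_shift",
                "concentration_um", "volume_ml", "cells", "duration_hr"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    ser = measurements[measurements["metabolite"] == "serine"]
    rows = []
    for cond, grp in ser.groupby("condition", sort=True):
        per_rep: dict[str, list[float]] = {"synthesis": [], "consumption": [],
                                           "scrambling": []}
        for _, rep in grp.groupby("replicate", sort=True):
            shifts = rep.set_index("mass_shift")
            geom = rep.iloc[0]
            if 3 in shifts.index:
                m3 = float(shifts.loc[3, "concentration_um"])
                per_rep["synthesis"].append(synthesis_rate(
                    m3, geom["volume_ml"], geom["cells"], geom["duration_hr"]
                ))
                if 1 in shifts.index:
                    m1 = float(shifts.loc[1, "concentration_um"])
                    per_rep["scrambling"].append(scrambling_ratio(m1, m3))
            if 0 in shifts.index:
                m0 = float(shifts.loc[0, "concentration_um"])
                per_rep["consumption"].append(consumption_rate(
                    m0_initial_um, m0,
                    geom["volume_ml"], geom["cells"], geom["duration_hr"],
                ))
        row = {"condition": cond,
               "natural_abundance_corrected": NATURAL_ABUNDANCE_CORRECTED}
        for name, vals in per_rep.items():
            arr = np.asarray(vals, dtype=float)
            row[f"{name}_mean"] = arr.mean() if arr.size else np.nan
            row[f"{name}_sem"] = (
                arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else np.nan
            )
            row[f"{name}_n"] = arr.size
        rows.append(row)
    return pd.DataFrame(rows)
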