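"""Derived pharmacokinetic quantities and cohort summaries.

Covers the standard secondary endpoints of a serum/CSF penetration
analysis: trapezoidal AUC over the treatment span (AUCf), its daily
rescaling (AUC 0-24), the CSF/serum penetration ratio, half-lives from
clearance/volume or transfer rate constants, Cockcroft-Gault creatinine
clearance, fraction of the dosing interval above an MIC, and
median/min/max cohort summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ConcentrationProfile

__all__ = [
    "PKMetrics",
    "CohortSummary",
    "auc_trapezoid",
    "auc_daily",
    "penetration_ratio",
    "half_life_from_cl_v",
    "half_life_from_rate",
    "cockcroft_gault",
    "f_t_above_mic",
    "cohort_summary",
    "subject_metrics",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PKMetrics:
    """Per-subject exposure metrics (mg·h/L for AUCs, h for half-lives)."""

    aucf_serum: float
    aucf_csf: float
    auc24_serum: float
    auc24_csf: float
    penetration_ratio: float
    t_half_serum: float
    t_half_cb: float
    t_half_bc: float


@dataclass(frozen=True)
class CohortSummary:
    median: float
    minimum: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("summary must satisfy min <= median <= max")


def auc_trapezoid(times, concentrations) -> float:
    """Linear-trapezoid area under the concentration-time curve, mg·h/L."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two points for a trapezoidal AUC")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(conc, times))


def auc_daily(aucf: float, total_time_h: float) -> float:
    """Rescale a cumulative AUC over `total_time_h` to a daily (0-24 h) AUC."""
    if total_time_h <= 0:
        raise ValueError("total_time_h must be > 0")
    return aucf / total_time_h * 24.0


def penetration_ratio(aucf_csf: float, aucf_serum: float) -> float:
    """CSF/serum penetration: CSF AUCf divided by serum AUCf."""
    if aucf_serum <= 0:
        raise ValueError("serum AUCf must be > 0")
    return aucf_csf / aucf_serum


def half_life_from_cl_v(cl: float, v: float) -> float:
    """t1/2 = ln2 * V / CL (h) for first-order elimination."""
    if cl <= 0 or v <= 0:
        raise ValueError("cl and v must be > 0")
    return LN2 * v / cl


def half_life_from_rate(k: float) -> float:
    """t1/2 = ln2 / k (h) for a first-order transfer rate constant (1/h)."""
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    return LN2 / k


def cockcroft_gault(age_y: float, weight_kg: float, scr_mg_dl: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance, ml/min.

    ((140 - age) * weight) / (72 * serum creatinine), times 0.85 for women.
    """
    if not 18 < age_y < 120:
        raise ValueError(f"age out of supported range (18, 120): {age_y}")
    if weight_kg <= 0 or scr_mg_dl <= 0:
        raise ValueError("weight and serum creatinine must be > 0")
    sex = sex.lower()
    if sex not in {"m", "f", "male", "female"}:
        raise ValueError(f"sex must be male/female, got {sex!r}")
    crcl = (140.0 - age_y) * weight_kg / (72.0 * scr_mg_dl)
    if sex in {"f", "female"}:
        crcl *= 0.85
    return crcl


def f_t_above_mic(
    profile: ConcentrationProfile,
    mic: float,
    interval: tuple[float, float],
    which: str = "serum",
) -> float:
    """Fraction of `interval` during which concentration exceeds `mic`.

    Uses linear interpolation between grid points, so threshold crossings
    between samples are located exactly for a piecewise-linear curve.
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval must have positive length")
    if mic < 0:
        raise ValueError("mic must be >= 0")
    times = profile.times
    conc = profile.serum_conc if which == "serum" else profile.csf_conc
    if t0 < times[0] or t1 > times[-1]:
        raise ValueError("profile does not cover the requested interval")
    # clip to the interval, keeping exact endpoint values
    grid = np.unique(np.concatenate([times[(times > t0) & (times < t1)], [t0, t1]]))
    vals = np.interp(grid, times, conc)
    above_time = 0.0
    for i in range(grid.size - 1):
        a, b = vals[i], vals[i + 1]
        dt = grid[i + 1] - grid[i]
        if a > mic and b > mic:
            above_time += dt
        elif a <= mic and b <= mic:
            continue
        else:
            frac = abs((max(a, b) - mic) / (b - a))
            above_time += dt * frac
    return above_time / (t1 - t0)


def cohort_summary(values) -> CohortSummary:
    """Median (midpoint convention for even n), min, max and n."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cohort summary needs at least one value")
    return CohortSummary(
        median=float(np.median(values)),
        minimum=float(values.min()),
        maximum=float(values.max()),
        n=int(values.size),
    )


def subject_metrics(
    params, profile: ConcentrationProfile, total_time_h: float | None = None
) -> PKMetrics:
    """All derived metrics for one subject's predicted profile.

    AUCf is the trapezoidal area under the (posterior-median) predicted
    serum and CSF curves over the observed treatment span; half-lives come
    from CL/Vc and the CSF transfer rate constants.
    """
    if total_time_h is None:
        total_time_h = float(profile.times[-1] - profile.times[0])
    aucf_serum = auc_trapezoid(profile.times, profile.serum_conc)
    aucf_csf = auc_trapezoid(profile.times, profile.csf_conc)
    return PKMetrics(
        aucf_serum=aucf_serum,
        aucf_csf=aucf_csf,
        auc24_serum=auc_daily(aucf_serum, total_time_h),
        auc24_csf=auc_daily(aucf_csf, total_time_h),
        penetration_ratio=penetration_ratio(aucf_csf, aucf_serum),
        t_half_serum=half_life_from_cl_v(params.cl, params.v_c),
        t_half_cb=half_life_from_rate(params.k_cb),
        t_half_bc=half_life_from_rate(params.k_bc),
    )
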