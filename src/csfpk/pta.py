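"""Monte Carlo dosing simulation and probability of target attainment (PTA)
for meropenem trough concentrations in CSF.

Virtual patients are drawn either by resampling a discrete parameter-set
source (population support points, or the 21 per-patient posterior sets
reconstructed from the published table) or from independent log-normals
matched to the published population mean/SD.  Each draw is run to steady
state under a candidate regimen and the steady-state CSF trough is
compared against targets of 1, 2 and 4 mg/L; all drug in CSF is treated
as unbound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fixtures
from .estimate import DEFAULT_BOX
from .model import PARAM_NAMES, BatchPropagator, PKParameters, Regimen

__all__ = [
    "REGIMENS",
    "ParameterDraws",
    "PTAResult",
    "sample_parameters",
    "simulate_pta",
    "pta_table",
    "median_profiles",
]

#: The compared regimens: (dose mg, interval h, infusion h), all 4-h infusions.
REGIMENS = {
    "2000q8": (2000.0, 8.0, 4.0),
    "4000q8": (4000.0, 8.0, 4.0),
    "4000q6": (4000.0, 6.0, 4.0),
    "5000q6": (5000.0, 6.0, 4.0),
}

DEFAULT_TARGETS = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class ParameterDraws:
    """A Monte Carlo sample of parameter sets, with provenance."""

    theta: np.ndarray  # (n, 7)
    provenance: str  # "discrete" | "parametric"
    seed: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[1] != len(PARAM_NAMES) or theta.shape[0] < 1:
            raise ValueError("theta must be (n >= 1, 7)")
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise ValueError("all drawn parameters must be finite and > 0")
        object.__setattr__(self, "theta", theta)

    @property
    def n(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class PTAResult:
    """Proportion of simulated patients with steady-state CSF trough >= target."""

    regimen: str
    target: float
    proportion: float
    n: int
    metric: str = "csf_trough_steady_state"

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must lie in [0, 1]")


def table3_reconstruction() -> list[PKParameters]:
    """The 21 per-patient sets reconstructed from the published table."""
    return fixtures.table3_parameter_sets()


def sample_parameters(
    source,
    n: int,
    seed: int = 0,
    mode: str = "discrete",
    box: dict | None = None,
) -> ParameterDraws:
    """Draw `n` virtual-patient parameter sets.

    mode "discrete": i.i.d. resampling of a list of PKParameters or of a
    NonparametricPrior's support points (by their weights).
    mode "parametric": independent log-normals per parameter matched to a
    mean/SD table (rows indexed by parameter, columns "mean" and "sd"),
    truncated to the box by resampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "discrete":
        if hasattr(source, "theta") and hasattr(source, "weights"):
            theta = source.theta()
            weights = source.weights()
        else:
            source = list(source)
            if not source:
                raise ValueError("empty discrete source")
            theta = np.array([p.as_array() for p in source])
            weights = np.full(theta.shape[0], 1.0 / theta.shape[0])
        idx = rng.choice(theta.shape[0], size=n, p=weights)
        return ParameterDraws(theta=theta[idx], provenance="discrete", seed=seed)
    if mode == "parametric":
        box = dict(DEFAULT_BOX) if box is None else dict(box)
        means = np.array([float(source.loc[p, "mean"]) for p in PARAM_NAMES])
        sds = np.array([float(source.loc[p, "sd"]) for p in PARAM_NAMES])
        sigma2 = np.log1p((sds / means) ** 2)
        mu = np.log(means) - 0.5 * sigma2
        sigma = np.sqrt(sigma2)
        lo = np.array([box[p][0] for p in PARAM_NAMES])
        hi = np.array([box[p][1] for p in PARAM_NAMES])
        theta = np.empty((n, len(PARAM_NAMES)))
        for d in range(len(PARAM_NAMES)):
            draws = np.empty(0)
            while draws.size < n:
                batch = rng.lognormal(mu[d], sigma[d], size=2 * n)
                batch = batch[(batch >= lo[d]) & (batch <= hi[d])]
                draws = np.concatenate([draws, batch])
            theta[:, d] = draws[:n]
        return ParameterDraws(theta=theta, provenance="parametric", seed=seed)
    raise ValueError(f"unknown sampling mode {mode!r}")


def _steady_state_csf_troughs(
    draws: ParameterDraws, dose: float, interval: float, infusion: float
) -> np.ndarray:
    """Steady-state CSF trough per draw, de-duplicating repeated sets."""
    uniq, inverse = np.unique(draws.theta, axis=0, return_inverse=True)
    prop = BatchPropagator(uniq)
    _, _, csf_troughs, _, _ = prop.steady_state_troughs(dose, interval, infusion)
    return csf_troughs[inverse]


def simulate_pta(
    draws: ParameterDraws,
    regimen: str | tuple,
    target: float,
) -> PTAResult:
    """PTA of a steady-state CSF trough >= `target` under `regimen`.

    `regimen` is a preset name from REGIMENS or an explicit
    (dose mg, interval h, infusion h) tuple.  Attainment uses >= per the
    published definition.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    label, (dose, interval, infusion) = _resolve_regimen(regimen)
    troughs = _steady_state_csf_troughs(draws, dose, interval, infusion)
    proportion = float(np.mean(troughs >= target))
    return PTAResult(regimen=label, target=target, proportion=proportion, n=draws.n)


def _resolve_regimen(regimen):
    if isinstance(regimen, str):
        if regimen not in REGIMENS:
            raise ValueError(f"unknown regimen preset {regimen!r}")
        return regimen, REGIMENS[regimen]
    dose, interval, infusion = regimen
    return f"{dose:g}q{interval:g}", (float(dose), float(interval), float(infusion))


def pta_table(
    draws: ParameterDraws,
    regimens=tuple(REGIMENS),
    targets=DEFAULT_TARGETS,
) -> pd.DataFrame:
    """PTA for every regimen x target combination, as a tidy DataFrame."""
    rows = []
    for regimen in regimens:
        label, (dose, interval, infusion) = _resolve_regimen(regimen)
        troughs = _steady_state_csf_troughs(draws, dose, interval, infusion)
        for target in targets:
            rows.append(
                {
                    "regimen": label,
                    "target_mg_L": float(target),
                    "pta": float(np.mean(troughs >= target)),
                    "n": draws.n,
                }
            )
    return pd.DataFrame(rows)


def median_profiles(
    draws: ParameterDraws,
    regimens=tuple(REGIMENS),
    horizon_h: float = 96.0,
    dt: float = 0.25,
) -> pd.DataFrame:
    """Pointwise-median serum and CSF curves across draws, per regimen.

    Returns a long DataFrame with columns (regimen, time, serum_median,
    csf_median) on a shared grid of step `dt` over `horizon_h` hours.
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be > 0")
    times = np.arange(0.0, horizon_h + 0.5 * dt, dt)
    uniq, inverse = np.unique(draws.theta, axis=0, return_inverse=True)
    prop = BatchPropagator(uniq)
    frames = []
    for regimen in regimens:
        label, (dose, interval, infusion) = _resolve_regimen(regimen)
        n_doses = int(np.ceil(horizon_h / interval))
        reg = Regimen.repeating(dose, interval, infusion, n_doses)
        conc = prop.concentrations(reg, times)[inverse]  # (n_draws, T, 2)
        frames.append(
            pd.DataFrame(
                {
                    "regimen": label,
                    "time": times,
                    "serum_median": np.median(conc[:, :, 0], axis=0),
                    "csf_median": np.median(conc[:, :, 1], axis=0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
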