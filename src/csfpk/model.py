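"""Three-compartment structural model of meropenem disposition.

The model tracks drug amounts in a central (serum) compartment, a
peripheral tissue compartment and a cerebrospinal-fluid (CSF)
compartment, with a zero-order infusion into the central compartment:

    dX1/dt = R(t) - (CL/Vc)*X1 - k_cp*X1 - k_cb*X1 + k_pc*X2 + k_bc*X3
    dX2/dt = k_cp*X1 - k_pc*X2
    dX3/dt = k_cb*X1 - k_bc*X3

X1, X2, X3 are amounts (mg) in central, peripheral and CSF compartments;
R(t) is the infusion rate (mg/h).  Serum concentration is X1/Vc and CSF
concentration is X3/V_CSF, where V_CSF is an apparent scaling volume,
not the physiological CSF volume.

Because the system is linear with piecewise-constant input, each segment
between infusion on/off switches is solved exactly with the matrix
exponential of the augmented 4x4 system, so the solution carries no
step-size error.  `scipy.integrate.solve_ivp` serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PARAM_NAMES",
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "SteadyStateResult",
    "infusion_rate",
    "simulate_amounts",
    "concentrations",
    "steady_state_interval",
]

PARAM_NAMES = ("cl", "v_c", "k_cp", "k_pc", "k_cb", "k_bc", "v_csf")


@dataclass(frozen=True)
class PKParameters:
    """One point in the 7-dimensional pharmacokinetic parameter space.

    Attributes
    ----------
    cl : float
        Clearance from the central compartment, L/h.
    v_c : float
        Volume of the central compartment, L.
    k_cp, k_pc : float
        First-order central<->peripheral transfer rate constants, 1/h.
    k_cb, k_bc : float
        First-order central<->CSF transfer rate constants, 1/h.
    v_csf : float
        Apparent CSF volume, L (a concentration scalar).
    """

    cl: float
    v_c: float
    k_cp: float
    k_pc: float
    k_cb: float
    k_bc: float
    v_csf: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(
                    f"PKParameters.{name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "PKParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion: `amount` mg over `duration` h."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusion events (times in h since first dose)."""

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(self.events)
        if any(not isinstance(e, DoseEvent) for e in events):
            raise TypeError("Regimen events must be DoseEvent instances")
        if list(events) != sorted(events, key=lambda e: e.start_time):
            events = tuple(sorted(events, key=lambda e: e.start_time))
        object.__setattr__(self, "events", events)

    @classmethod
    def repeating(
        cls, dose_mg: float, interval_h: float, infusion_h: float, n_doses: int
    ) -> "Regimen":
        """Convenience constructor: `n_doses` equal infusions every `interval_h` h."""
        if infusion_h > interval_h:
            raise ValueError("infusion duration must not exceed the dosing interval")
        if n_doses < 1:
            raise ValueError("need at least one dose")
        return cls(
            tuple(
                DoseEvent(start_time=i * interval_h, amount=dose_mg, duration=infusion_h)
                for i in range(n_doses)
            )
        )

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    def span(self) -> float:
        """End of the last infusion, h (0 for an empty regimen)."""
        return max((e.end_time for e in self.events), default=0.0)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Serum and CSF concentration curves on a common time grid."""

    times: np.ndarray
    serum_conc: np.ndarray
    csf_conc: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        serum = np.asarray(self.serum_conc, dtype=float)
        csf = np.asarray(self.csf_conc, dtype=float)
        if not (times.shape == serum.shape == csf.shape):
            raise ValueError("times, serum_conc and csf_conc must have equal shape")
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "serum_conc", serum)
        object.__setattr__(self, "csf_conc", csf)


def infusion_rate(regimen: Regimen, t: float) -> float:
    """Total infusion rate R(t) in mg/h at time `t`.

    An event contributes amount/duration on [start, start+duration).
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return sum(e.rate for e in regimen.events if e.start_time <= t < e.end_time)


def _rate_matrix_batch(theta: np.ndarray) -> np.ndarray:
    """(n,7) parameter array -> (n,3,3) compartmental rate matrices."""
    cl, v_c, k_cp, k_pc, k_cb, k_bc = (theta[:, i] for i in range(6))
    n = theta.shape[0]
    a = np.zeros((n, 3, 3))
    a[:, 0, 0] = -(cl / v_c + k_cp + k_cb)
    a[:, 0, 1] = k_pc
    a[:, 0, 2] = k_bc
    a[:, 1, 0] = k_cp
    a[:, 1, 1] = -k_pc
    a[:, 2, 0] = k_cb
    a[:, 2, 2] = -k_bc
    return a


class BatchPropagator:
    """Exact piecewise-constant-input propagation for a batch of parameter sets.

    Holds an (n,7) parameter array and caches the augmented-system matrix
    exponential per (segment length, infusion rate) pair, which makes
    repeated simulation on regular dosing/sampling grids cheap.
    """

    def __init__(self, theta: np.ndarray):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if theta.shape[1] != len(PARAM_NAMES):
            raise ValueError(f"theta must be (n, {len(PARAM_NAMES)})")
        if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
            raise ValueError("all parameters must be finite and > 0")
        self.theta = theta
        self.n = theta.shape[0]
        self._a = _rate_matrix_batch(theta)
        self._cache: dict = {}

    def _segment_operator(self, dt: float, rate: float) -> np.ndarray:
        key = (round(dt, 10), round(rate, 8))
        op = self._cache.get(key)
        if op is None:
            m = np.zeros((self.n, 4, 4))
            m[:, :3, :3] = self._a
            m[:, 0, 3] = rate
            op = expm(m * dt)
            self._cache[key] = op
        return op

    def amounts(self, regimen: Regimen, times) -> np.ndarray:
        """Amount trajectories, shape (n, len(times), 3)."""
        times = np.asarray(times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
            raise ValueError("times must be sorted and >= 0")
        out = np.zeros((self.n, times.size, 3))
        if times.size == 0:
            return out
        # breakpoints where the total rate changes, merged with output times
        switch = {0.0}
        t_max = float(times[-1])
        for e in regimen.events:
            if e.start_time <= t_max:
                switch.add(e.start_time)
            if e.end_time <= t_max:
                switch.add(e.end_time)
        grid = np.unique(np.concatenate([np.array(sorted(switch)), times]))
        state = np.zeros((self.n, 4))
        state[:, 3] = 1.0
        pos = {t: i for i, t in enumerate(grid)}
        wanted = np.searchsorted(grid, times)
        snapshots = np.zeros((self.n, grid.size, 3))
        snapshots[:, 0, :] = state[:, :3]
        for i in range(grid.size - 1):
            t0, t1 = grid[i], grid[i + 1]
            rate = infusion_rate(regimen, 0.5 * (t0 + t1))
            op = self._segment_operator(t1 - t0, rate)
            state = np.einsum("nij,nj->ni", op, state)
            snapshots[:, i + 1, :] = state[:, :3]
        out = snapshots[:, wanted, :]
        # exact arithmetic can round to tiny negatives
        np.clip(out, 0.0, None, out=out)
        return out

    def concentrations(self, regimen: Regimen, times) -> np.ndarray:
        """(n, len(times), 2): serum and CSF concentrations, mg/L."""
        amounts = self.amounts(regimen, times)
        conc = np.empty(amounts.shape[:2] + (2,))
        conc[:, :, 0] = amounts[:, :, 0] / self.theta[:, 1][:, None]
        conc[:, :, 1] = amounts[:, :, 2] / self.theta[:, 6][:, None]
        return conc

    def interval_map(self, dose_mg: float, interval_h: float, infusion_h: float):
        """Affine map of the state over one dosing interval.

        Returns the 4x4 batch operator E such that x4_(k+1) = E @ x4_k for
        the augmented state (X1, X2, X3, 1).
        """
        if infusion_h > interval_h:
            raise ValueError("infusion duration must not exceed the dosing interval")
        on = self._segment_operator(infusion_h, dose_mg / infusion_h)
        if interval_h > infusion_h:
            off = self._segment_operator(interval_h - infusion_h, 0.0)
            return np.einsum("nij,njk->nik", off, on)
        return on

    def steady_state_troughs(
        self,
        dose_mg: float,
        interval_h: float,
        infusion_h: float,
        rel_tol: float = 1e-3,
        max_intervals: int = 50,
    ):
        """Iterate dosing intervals until troughs settle; return end-of-interval state.

        Returns (state (n,4), serum troughs (n,), csf troughs (n,),
        n_intervals, converged per set (n,) bool).
        """
        op = self.interval_map(dose_mg, interval_h, infusion_h)
        state = np.zeros((self.n, 4))
        state[:, 3] = 1.0
        prev = np.full((self.n, 2), np.nan)
        converged = np.zeros(self.n, dtype=bool)
        k = 0
        for k in range(1, max_intervals + 1):
            state = np.einsum("nij,nj->ni", op, state)
            troughs = np.stack(
                [state[:, 0] / self.theta[:, 1], state[:, 2] / self.theta[:, 6]], axis=1
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(troughs - prev) / np.where(troughs > 0, troughs, np.inf)
            converged = np.all(rel < rel_tol, axis=1)
            prev = troughs
            if np.all(converged):
                break
        return state, prev[:, 0], prev[:, 1], k, converged


def simulate_amounts(params: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Solve the model for one parameter set.

    Returns an array of shape (len(times), 3) with amounts (mg) in the
    central, peripheral and CSF compartments.
    """
    prop = BatchPropagator(params.as_array()[None, :])
    return prop.amounts(regimen, times)[0]


def concentrations(params: PKParameters, regimen: Regimen, times) -> ConcentrationProfile:
    """Serum (X1/Vc) and CSF (X3/V_CSF) concentrations at `times`."""
    amounts = simulate_amounts(params, regimen, times)
    return ConcentrationProfile(
        times=np.asarray(times, dtype=float),
        serum_conc=amounts[:, 0] / params.v_c,
        csf_conc=amounts[:, 2] / params.v_csf,
    )


@dataclass(frozen=True)
class SteadyStateResult:
    """One dosing interval at steady state plus the trough values."""

    profile: ConcentrationProfile
    serum_trough: float
    csf_trough: float
    n_intervals: int
    converged: bool


def steady_state_interval(
    params: PKParameters,
    dose_mg: float,
    interval_h: float,
    infusion_h: float,
    grid_step: float = 0.05,
    rel_tol: float = 1e-3,
    max_intervals: int = 50,
) -> SteadyStateResult:
    """Simulate repeated dosing to steady state and return the final interval.

    Dosing intervals are iterated until the serum and CSF troughs change by
    less than `rel_tol` (relative) between successive intervals, capped at
    `max_intervals`; `converged` is False when the cap is hit first.  The
    returned profile covers one interval with time 0 at the infusion start.
    """
    prop = BatchPropagator(params.as_array()[None, :])
    state, serum_trough, csf_trough, k, conv = prop.steady_state_troughs(
        dose_mg, interval_h, infusion_h, rel_tol=rel_tol, max_intervals=max_intervals
    )
    # one more interval from the settled pre-dose state, on a fine grid
    n_steps = max(2, int(round(interval_h / grid_step)) + 1)
    times = np.linspace(0.0, interval_h, n_steps)
    single = Regimen((DoseEvent(0.0, dose_mg, infusion_h),))
    # by linearity: fresh-interval response + input-free decay of the
    # settled pre-dose amounts
    a0 = state[0, :3]
    amounts = simulate_amounts(params, single, times) + _decay_initial(params, a0, times)
    profile = ConcentrationProfile(
        times=times,
        serum_conc=amounts[:, 0] / params.v_c,
        csf_conc=amounts[:, 2] / params.v_csf,
    )
    return SteadyStateResult(
        profile=profile,
        serum_trough=float(serum_trough[0]),
        csf_trough=float(csf_trough[0]),
        n_intervals=k,
        converged=bool(conv[0]),
    )


def _decay_initial(params: PKParameters, a0: np.ndarray, times) -> np.ndarray:
    """Input-free decay of initial amounts `a0` at `times` (exact)."""
    a = _rate_matrix_batch(params.as_array()[None, :])[0]
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, 3))
    for i, t in enumerate(times):
        out[i] = expm(a * t) @ a0
    return out
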