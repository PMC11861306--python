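"""Estimation of the velocity-split parameters (k, RP0, FP0) and validation.

The central-side constants (FC0, RC0, r, L) are taken as known (joint-level
three-compartment values); the three parameters introduced by the peripheral
pathway are estimated from per-phase normalized strengths of one or more test
sessions by a seeded population-based global search (differential evolution)
with a stall-based stop rule: terminate once the average change of the best
objective over a window of generations falls below a tolerance.

The misfit is least squares between the model's residual capacity at each
isometric phase's first MVIC onset and the measured per-phase normalized
strength, weighted by the number of MVIC samples in the phase (the measured
strength is one constant per phase, so repeating it per sample time is a
weight).  RP0 and FP0 are searched in log10 space — they are positive and
plausible values span decades — and k in linear space.

Identifiability: FP0 and k enter only through FP0*(1 - exp(-k*V)), which
vanishes at V = 0, so sessions must include nonzero velocities (two or more
distinct ones to separate k from FP0).  ``estimate_parameters`` raises on
all-isometric data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import _kernels
from .core_model import FatigueParameters
from .protocols import TaskProfile
from .simulator import segment_counts

__all__ = [
    "Session",
    "FitResult",
    "DEFAULT_BOUNDS",
    "objective",
    "estimate_parameters",
    "pearson_validation",
    "session_pearson",
]

#: Search bounds bracketing published joint-level values by >= 3x each side:
#: k (s/degree), RP0 (1/s), FP0 (1/s).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (0.0, 0.1),
    "RP0": (1e-7, 1e-3),
    "FP0": (1e-4, 1.0),
}


@dataclass(frozen=True)
class Session:
    """Measured strengths of one test session plus the protocol that made them.

    ``strengths`` are the five per-phase representative strengths normalized
    to the first phase (so strengths[0] == 1).
    """

    strengths: np.ndarray
    profile: TaskProfile
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=float)
        object.__setattr__(self, "strengths", s)
        onsets, counts = _phase_onsets(self.profile)
        if len(s) != len(onsets):
            raise ValueError(
                f"{len(s)} strengths for {len(onsets)} isometric phases"
            )

    @property
    def velocity(self) -> float:
        return float(self.profile.v.max())


@dataclass(frozen=True)
class FitResult:
    """Outcome of one parameter search."""

    k: float
    RP0: float
    FP0: float
    objective: float
    n_evaluations: int
    seed: int | None
    converged: bool
    message: str = ""
    bounds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    best_history: tuple[float, ...] = ()  # best objective after each generation

    def as_dict(self) -> dict:
        return {
            "k": self.k, "RP0": self.RP0, "FP0": self.FP0,
            "objective": self.objective, "n_evaluations": self.n_evaluations,
            "seed": self.seed, "converged": self.converged,
            "message": self.message, "bounds": self.bounds, "config": self.config,
            "best_history": list(self.best_history),
        }


def _phase_onsets(profile: TaskProfile) -> tuple[np.ndarray, np.ndarray]:
    """First MVIC time and MVIC count of each isometric phase."""
    groups = profile.mvic_times_by_phase()
    onsets = np.array([g[0] for g in groups])
    counts = np.array([len(g) for g in groups], dtype=float)
    return onsets, counts


class _ObjectiveCache:
    """Evaluate the misfit, simulating each distinct profile once per candidate."""

    def __init__(self, sessions: Sequence[Session], fixed: dict, dt: float):
        if not sessions:
            raise ValueError("no sessions supplied")
        self.fixed = dict(fixed)
        self.dt = dt
        self.n_evaluations = 0
        self._profiles: list[tuple[TaskProfile, np.ndarray, np.ndarray, list]] = []
        seen: dict[int, int] = {}
        for s in sessions:
            key = id(s.profile)
            if key not in seen:
                onsets, counts = _phase_onsets(s.profile)
                seen[key] = len(self._profiles)
                self._profiles.append((s.profile, onsets, counts, []))
            self._profiles[seen[key]][3].append(np.asarray(s.strengths, float))

    def __call__(self, candidate) -> float:
        k, RP0, FP0 = candidate
        f = self.fixed
        self.n_evaluations += 1
        total = 0.0
        for profile, onsets, counts, strength_list in self._profiles:
            segs = segment_counts(profile.breakpoints, self.dt)
            caps, status = _kernels.final_capacity(
                profile.breakpoints, profile.tl, profile.v, segs,
                f["FC0"], FP0, f["RC0"], RP0, f.get("r", 1.0), abs(k),
                f.get("L", 20.0), f.get("rest_multiplier_at_rest", True),
                onsets,
            )
            if status != _kernels.STATUS_OK:
                return math.inf
            pred = caps / caps[0]
            for meas in strength_list:
                d = pred - meas
                total += float(counts @ (d * d))
        return total


def objective(
    candidate: Sequence[float],
    sessions: Sequence[Session],
    fixed: dict,
    dt: float = 0.01,
) -> float:
    """Nonnegative misfit of one (k, RP0, FP0) candidate against sessions."""
    return _ObjectiveCache(sessions, fixed, dt)(candidate)


def _to_x(k, RP0, FP0):
    return np.array([k, math.log10(RP0), math.log10(FP0)])


def _from_x(x):
    return float(x[0]), float(10.0 ** x[1]), float(10.0 ** x[2])


def estimate_parameters(
    sessions: Sequence[Session],
    fixed: dict,
    bounds: dict | None = None,
    seed: int | None = None,
    population: int = 12,
    max_generations: int = 60,
    stall_generations: int = 15,
    tolerance: float = 1e-10,
    dt: float = 0.01,
) -> FitResult:
    """Seeded global search for (k, RP0, FP0) with a stall-based stop rule.

    Differential evolution over (k, log10 RP0, log10 FP0) followed by a
    bounded quasi-Newton polish.  The search stops early once the average
    change in the best objective over ``stall_generations`` consecutive
    generations is at most ``tolerance``.  Deterministic for a given seed.
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    for name, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"degenerate bounds for {name}: ({lo}, {hi})")
    if all(s.velocity == 0.0 for s in sessions):
        raise ValueError(
            "all sessions are isometric (V=0): FP0 and k are unidentifiable "
            "because FP = FP0*(1 - exp(-k*V)) vanishes"
        )
    cache = _ObjectiveCache(sessions, fixed, dt)
    x_bounds = [
        bounds["k"],
        (math.log10(bounds["RP0"][0]), math.log10(bounds["RP0"][1])),
        (math.log10(bounds["FP0"][0]), math.log10(bounds["FP0"][1])),
    ]

    def fun(x):
        return cache(_from_x(x))

    history: list[float] = []
    stalled = {"flag": False}

    def callback(xk, convergence=None):
        history.append(fun_best["value"])
        if len(history) > stall_generations:
            window = history[-(stall_generations + 1):]
            avg_change = abs(window[0] - window[-1]) / stall_generations
            if avg_change <= tolerance:
                stalled["flag"] = True
                return True
        return False

    fun_best = {"value": math.inf}

    def tracked(x):
        v = fun(x)
        if v < fun_best["value"]:
            fun_best["value"] = v
        return v

    result = optimize.differential_evolution(
        tracked,
        x_bounds,
        seed=seed,
        popsize=population,
        maxiter=max_generations,
        tol=0.0,
        callback=callback,
        polish=False,
        init="sobol",
        updating="deferred",
    )
    polished = optimize.minimize(
        fun, result.x, method="L-BFGS-B", bounds=x_bounds,
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    x = polished.x if polished.fun <= result.fun else result.x
    best = min(float(polished.fun), float(result.fun))
    k, RP0, FP0 = _from_x(x)
    return FitResult(
        k=k, RP0=RP0, FP0=FP0,
        objective=best,
        n_evaluations=cache.n_evaluations,
        seed=seed,
        converged=bool(stalled["flag"] or result.success or polished.success),
        message=("stall rule met" if stalled["flag"] else str(result.message)),
        bounds=bounds,
        config={
            "population": population,
            "max_generations": max_generations,
            "stall_generations": stall_generations,
            "tolerance": tolerance,
            "dt": dt,
            "search_space": "k linear, RP0/FP0 log10",
        },
        best_history=tuple(history),
    )


def pearson_validation(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Pearson r between predicted and measured strength series.

    Series must be aligned and of equal length >= 3.  A constant series makes
    the coefficient undefined; it is reported as missing (NaN).
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or len(p) < 3:
        raise ValueError("need two aligned 1-d series of length >= 3")
    if np.ptp(p) == 0.0 or np.ptp(m) == 0.0:
        return math.nan
    return float(stats.pearsonr(p, m).statistic)


def session_pearson(
    params: FatigueParameters, session: Session, dt: float = 0.01
) -> float:
    """Validate one session: model capacity at every MVIC sample time against
    the per-phase measured strength repeated for each sample time in the phase
    (one constant per isometric phase, used 5 or 6 times depending on the
    joint's stop count)."""
    from .simulator import integrate

    traj = integrate(session.profile, params, dt=dt)
    groups = session.profile.mvic_times_by_phase()
    pred: list[float] = []
    meas: list[float] = []
    cap = np.interp(session.profile.mvic_times, traj.t, traj.residual_capacity)
    base = None
    i = 0
    for g, s in zip(groups, session.strengths):
        for _ in g:
            c = cap[i]
            if base is None:
                base = c
            pred.append(c / base)
            meas.append(float(s))
            i += 1
    return pearson_validation(pred, meas)
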