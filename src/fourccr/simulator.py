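"""Fixed-step integration of the 4CCr equations over a task profile.

The integrator is classical fourth-order Runge-Kutta on a grid split at every
profile breakpoint, so the piecewise-constant (TL, V) inputs are never
averaged across a discontinuity.  The controller gain L = 20 sets the fastest
time constant (1/L = 0.05 s); the default step dt = 0.01 s resolves it.
States are clipped to [0, 1] and renormalized when the pool sum drifts beyond
1e-12; any excursion beyond [-1e-6, 1 + 1e-6] before clipping aborts with a
step-size diagnostic.

An explicit first-order (Euler) mode serves as an independent oracle for the
main integrator, and :func:`reference_3ccr` provides a separately coded
three-compartment (3CCr) trajectory: at V = 0 the four-compartment model has
no flow into the peripheral pool and must reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_model import RESTED_STATE, CompartmentState, FatigueParameters
from .protocols import TaskProfile

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "residual_capacity_at",
    "reference_3ccr",
    "segment_counts",
]

DEFAULT_DT = 0.01


class IntegrationError(RuntimeError):
    """Raised when a compartment leaves [0, 1] beyond tolerance mid-run."""


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed compartment states from one simulation.

    ``states`` is (n, 4) ordered (MA, MR, MFP, MFC); ``tl`` and ``v`` carry
    the input values on the segment each grid point belongs to.  MVIC sample
    times are copied from the profile with the residual capacity interpolated
    at each.
    """

    t: np.ndarray
    states: np.ndarray
    tl: np.ndarray
    v: np.ndarray
    mvic_times: np.ndarray
    mvic_capacities: np.ndarray

    @property
    def MA(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def MR(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def MFP(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def MFC(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def residual_capacity(self) -> np.ndarray:
        """Unfatigued fraction MA + MR = 1 - MFP - MFC along the run."""
        return self.states[:, 0] + self.states[:, 1]

    def final_state(self) -> CompartmentState:
        MA, MR, MFP, MFC = self.states[-1]
        return CompartmentState(MA=MA, MR=MR, MFP=MFP, MFC=MFC)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t,
            "MA": self.MA,
            "MR": self.MR,
            "MFP": self.MFP,
            "MFC": self.MFC,
            "residual_capacity": self.residual_capacity,
            "TL": self.tl,
            "V": self.v,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def segment_counts(breakpoints: np.ndarray, dt: float) -> np.ndarray:
    """Sub-steps per segment so each step is <= dt and ends on a breakpoint."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    widths = np.diff(breakpoints)
    return np.maximum(1, np.ceil(widths / dt - 1e-9)).astype(np.int64)


def integrate(
    profile: TaskProfile,
    params: FatigueParameters,
    dt: float = DEFAULT_DT,
    initial_state: CompartmentState = RESTED_STATE,
    method: str = "rk4",
) -> Trajectory:
    """Simulate the 4CCr model over ``profile`` from a (default rested) start."""
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")
    counts = segment_counts(profile.breakpoints, dt)
    t, states, tl, v, status, i_bad = _kernels.integrate_profile(
        profile.breakpoints, profile.tl, profile.v, counts,
        params.FC0, params.FP0, params.RC0, params.RP0,
        params.r, params.k, params.L, params.rest_multiplier_at_rest,
        np.array(initial_state.as_tuple()),
        1 if method == "euler" else 4,
    )
    if status != _kernels.STATUS_OK:
        raise IntegrationError(
            f"compartment left [0, 1] near t={t[max(i_bad - 1, 0)]:.4f} s "
            f"(dt={dt}); reduce the step size (fastest time constant is "
            f"1/L = {1.0 / params.L:.3g} s)"
        )
    mvic_caps = (np.interp(profile.mvic_times, t, states[:, 0] + states[:, 1])
                 if len(profile.mvic_times) else np.empty(0))
    return Trajectory(t=t, states=states, tl=tl, v=v,
                      mvic_times=profile.mvic_times.copy(),
                      mvic_capacities=mvic_caps)


def residual_capacity_at(traj: Trajectory, times) -> np.ndarray:
    """Residual capacity linearly interpolated on the trajectory grid."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < -1e-9) or np.any(times > traj.t[-1] + 1e-9):
        raise ValueError("requested times outside the simulated horizon")
    return np.interp(times, traj.t, traj.residual_capacity)


def _deriv3(MA, MR, MF, TL, L, F, R):
    C = L * min(TL - MA, MR)
    return (-F * MA + C, R * MF - C, -R * MF + F * MA)


def reference_3ccr(
    profile: TaskProfile,
    params3: dict,
    dt: float = DEFAULT_DT,
    method: str = "rk4",
) -> Trajectory:
    """Independent three-compartment (3CCr) trajectory for the same profile.

    ``params3`` carries the single fatigue rate ``F``, recovery rate ``R``,
    rest multiplier ``r`` and controller gain ``L``.  The fatigued pool is
    reported in the MFC slot (MFP stays 0) so trajectories compare directly
    with a zero-velocity 4CCr run.  Coded separately from the main kernel on
    purpose: it is the equivalence oracle, not a wrapper.
    """
    F = float(params3["F"])
    R = float(params3["R"])
    r = float(params3.get("r", 1.0))
    L = float(params3.get("L", 20.0))
    counts = segment_counts(profile.breakpoints, dt)
    n_pts = int(counts.sum()) + 1
    t_out = np.empty(n_pts)
    states = np.zeros((n_pts, 4))
    tl_out = np.empty(n_pts)
    v_out = np.empty(n_pts)
    MA, MR, MF = 0.0, 1.0, 0.0
    t_out[0] = 0.0
    states[0, :] = (MA, MR, 0.0, MF)
    tl_out[0] = profile.tl[0]
    v_out[0] = profile.v[0]
    pos = 1
    for j, n in enumerate(counts):
        t0 = profile.breakpoints[j]
        t1 = profile.breakpoints[j + 1]
        h = (t1 - t0) / n
        TL = profile.tl[j]
        V = profile.v[j]
        Reff = r * R if TL == 0.0 else R
        for i in range(n):
            if method == "euler":
                d1 = _deriv3(MA, MR, MF, TL, L, F, Reff)
                MA += h * d1[0]
                MR += h * d1[1]
                MF += h * d1[2]
            else:
                d1 = _deriv3(MA, MR, MF, TL, L, F, Reff)
                d2 = _deriv3(MA + 0.5 * h * d1[0], MR + 0.5 * h * d1[1],
                             MF + 0.5 * h * d1[2], TL, L, F, Reff)
                d3 = _deriv3(MA + 0.5 * h * d2[0], MR + 0.5 * h * d2[1],
                             MF + 0.5 * h * d2[2], TL, L, F, Reff)
                d4 = _deriv3(MA + h * d3[0], MR + h * d3[1],
                             MF + h * d3[2], TL, L, F, Reff)
                MA += h / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
                MR += h / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
                MF += h / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
            if not (-1e-6 <= MA <= 1 + 1e-6 and -1e-6 <= MR <= 1 + 1e-6
                    and -1e-6 <= MF <= 1 + 1e-6):
                raise IntegrationError(
                    f"3CCr reference unstable near t={t0 + (i + 1) * h:.4f} s "
                    f"(dt={dt}); reduce the step size"
                )
            MA = min(max(MA, 0.0), 1.0)
            MR = min(max(MR, 0.0), 1.0)
            MF = min(max(MF, 0.0), 1.0)
            total = MA + MR + MF
            if abs(total - 1.0) > 1e-12:
                MA /= total
                MR /= total
                MF /= total
            t_out[pos] = t0 + (i + 1) * h if i + 1 < n else t1
            states[pos, 0] = MA
            states[pos, 1] = MR
            states[pos, 3] = MF
            tl_out[pos] = TL
            v_out[pos] = V
            pos += 1
    mvic_caps = (np.interp(profile.mvic_times, t_out, states[:, 0] + states[:, 1])
                 if len(profile.mvic_times) else np.empty(0))
    return Trajectory(t=t_out, states=states, tl=tl_out, v=v_out,
                      mvic_times=profile.mvic_times.copy(),
                      mvic_capacities=mvic_caps)
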