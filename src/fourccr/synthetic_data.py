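"""Synthetic dynamometer sessions from a known ground-truth 4CCr model.

Emulates the long-format peak-MVIC torque tables a Biodex-style test session
produces, so the whole processing/fitting chain can be exercised without any
experimental data: simulate the alternating isometric/isokinetic protocol with
known ("true") parameters, then emit per-stop peak torques

    torque = amplitude * shape(angle) * residual_capacity * (1 + eps)

with a smooth unimodal (Gaussian bell) torque-angle shape and multiplicative
Gaussian noise eps ~ N(0, sigma) (MVIC variability scales with torque).

Measurement model: by default the residual capacity entering a phase's
torques is sampled once, at the phase's first MVIC onset, and applied to
every ROM stop in the phase — the same negligible-within-phase-recovery
assumption the processing pipeline makes, so noiseless data close the loop
exactly.  Set ``sample_within_phase=True`` to sample capacity at each stop's
own MVIC time instead (more realistic; the per-phase scale factor then blends
within-phase recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_model import FatigueParameters, VELOCITY_PARAMETER_TABLE
from .protocols import JOINT_TABLE, JointSpec, experiment_protocol
from .simulator import Trajectory, integrate

__all__ = [
    "SyntheticSpec",
    "torque_angle_shape",
    "generate_session",
    "generate_study",
    "default_study_specs",
    "DEFAULT_CENTRAL",
]

#: Synthetic ground-truth central-side constants (1/s except r, L): magnitudes
#: representative of published joint-level three-compartment fatigue/recovery
#: values.  These are the generator's defaults, not fitted quantities.
DEFAULT_CENTRAL = {"FC0": 0.01, "RC0": 0.002, "r": 15.0, "L": 20.0}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and measurement model for one synthetic muscle group."""

    params: FatigueParameters
    joint: JointSpec
    muscle_group: str
    direction: str = "flexion"
    amplitude: float = 100.0      # N*m at the strongest angle, rested
    peak_angle: float | None = None   # degrees; default mid-ROM
    width: float = 40.0           # degrees, bell standard deviation
    sigma: float = 0.0            # multiplicative noise fraction
    seed: int = 0
    sample_within_phase: bool = False
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.peak_angle is None:
            mid = 0.5 * (min(self.joint.rom_stops) + max(self.joint.rom_stops))
            object.__setattr__(self, "peak_angle", mid)

    def shape_at(self, angle: float) -> float:
        lo, hi = min(self.joint.rom_stops), max(self.joint.rom_stops)
        return torque_angle_shape(angle, self.peak_angle, self.width, (lo, hi))


def torque_angle_shape(
    angle: float, peak_angle: float, width: float, rom_bounds: tuple[float, float]
) -> float:
    """Smooth unimodal torque-angle fraction in (0, 1], 1 at the peak angle."""
    lo, hi = rom_bounds
    if not lo <= angle <= hi:
        raise ValueError(f"angle {angle} outside ROM [{lo}, {hi}]")
    z = (angle - peak_angle) / width
    return math.exp(-0.5 * z * z)


def generate_session(
    spec: SyntheticSpec,
    velocity: float,
    participant: str = "S01",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, Trajectory, dict]:
    """One synthetic test session for one muscle group at one velocity.

    Returns the long-format torque table, the ground-truth trajectory, and a
    truth record (parameters, seed, per-record sampled residual capacities)
    for test assertions.
    """
    if velocity <= 0:
        raise ValueError("session velocity must be > 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    profile = experiment_protocol(spec.joint, velocity)
    traj = integrate(profile, spec.params, dt=spec.dt)
    phase_times = profile.mvic_times_by_phase()
    rows = []
    sampled: list[float] = []
    cap_all = np.interp(profile.mvic_times, traj.t, traj.residual_capacity)
    i = 0
    for p, times in enumerate(phase_times, start=1):
        phase_cap = cap_all[i]  # capacity at the phase's first MVIC onset
        for stop, t in zip(spec.joint.rom_stops, times):
            cap = cap_all[i] if spec.sample_within_phase else phase_cap
            eps = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
            torque = spec.amplitude * spec.shape_at(stop) * cap * (1.0 + eps)
            rows.append({
                "participant": participant,
                "joint": spec.joint.name,
                "direction": spec.direction,
                "velocity_deg_s": velocity,
                "phase": p,
                "stop_deg": float(stop),
                "peak_torque_Nm": torque,
            })
            sampled.append(cap)
            i += 1
    df = pd.DataFrame(rows)
    truth = {
        "muscle_group": spec.muscle_group,
        "participant": participant,
        "velocity_deg_s": velocity,
        "seed": spec.seed,
        "sigma": spec.sigma,
        "amplitude": spec.amplitude,
        "params": {
            "FC0": spec.params.FC0, "FP0": spec.params.FP0,
            "RC0": spec.params.RC0, "RP0": spec.params.RP0,
            "r": spec.params.r, "k": spec.params.k, "L": spec.params.L,
        },
        "sampled_residual_capacity": sampled,
        "phase_capacities": [float(cap_all[sum(map(len, phase_times[:p]))])
                             for p in range(len(phase_times))],
    }
    return df, traj, truth


def default_study_specs(central: dict | None = None) -> dict[str, SyntheticSpec]:
    """Synthetic ground truth for the full 8-muscle-group study design.

    Six groups take their velocity-split parameters (k, RP0, FP0/RP0) from the
    fitted table; the elbow groups, for which no fitted values exist, get
    synthetic values of comparable magnitude.  Central-side constants default
    to :data:`DEFAULT_CENTRAL`.
    """
    central = dict(DEFAULT_CENTRAL, **(central or {}))
    table = dict(VELOCITY_PARAMETER_TABLE)
    # synthetic elbow entries: no fitted elbow parameters exist
    table["elbow_flexors"] = {"k": 0.02, "RP0": 1.5e-5, "FP0_over_RP0": 700.0}
    table["elbow_extensors"] = {"k": 0.025, "RP0": 2.0e-5, "FP0_over_RP0": 500.0}
    direction_of = {"flexors": "flexion", "extensors": "extension"}
    specs = {}
    for group, row in sorted(table.items()):
        joint_name, muscles = group.rsplit("_", 1)
        joint = JOINT_TABLE[joint_name]
        params = FatigueParameters(
            FC0=central["FC0"], RC0=central["RC0"], r=central["r"],
            L=central["L"], k=row["k"], RP0=row["RP0"],
            FP0=row["FP0_over_RP0"] * row["RP0"], muscle_group=group,
        )
        specs[group] = SyntheticSpec(
            params=params, joint=joint, muscle_group=group,
            direction=direction_of[muscles],
        )
    return specs


def generate_study(
    specs: dict[str, SyntheticSpec] | None = None,
    n_participants: int = 1,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial synthetic study: every muscle group at each of its
    joint's tested velocities, for ``n_participants`` participants.

    With 8 muscle groups x 5 velocities x 5 isometric phases this yields 200
    per-phase strength distributions (and 8 x 5 x 4 fatigue-rate cells).
    Deterministic for a given seed.
    """
    if specs is None:
        specs = default_study_specs()
    rng = np.random.default_rng(seed)
    frames = []
    for group in sorted(specs):
        spec = replace(specs[group], sigma=sigma)
        for velocity in spec.joint.velocities:
            for p in range(n_participants):
                df, _, _ = generate_session(
                    spec, velocity, participant=f"S{p + 1:02d}", rng=rng
                )
                frames.append(df)
    return pd.concat(frames, ignore_index=True)
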