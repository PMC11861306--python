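"""Task-protocol encoding: piecewise-constant target load TL(t) and velocity V(t).

A task is a sequence of phases, each an intermittent exertion coded by the
triple (TL, DC, CT): target load as a fraction of capacity, duty cycle, and
cycle time in seconds.  Each cycle leads with its active portion (load TL for
DC*CT seconds) followed by rest (TL = 0).  Isokinetic phases additionally
carry a nominal joint velocity, held for the whole phase.

The standard dynamometer fatiguing protocol alternates five isometric
measurement phases (ISOM1..ISOM5) with four 60 s isokinetic fatiguing phases
(ISOK1..ISOK4).  Each isometric phase visits every ROM stop of the joint once,
coded (1, 0.2, 15 s) per stop; the isokinetic phases are coded
(1, 0.5, 2*ROM/V), the cycle time being one flexion-extension sweep of the
range of motion at velocity V.  MVIC sample times are the active onsets within
the isometric phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PhaseSpec",
    "JointSpec",
    "TaskProfile",
    "JOINT_TABLE",
    "intermittent_profile",
    "experiment_protocol",
]

ISOMETRIC_CT = 15.0  # s per ROM-stop visit: two 3 s MVICs + repositioning
ISOMETRIC_DC = 0.2
ISOKINETIC_DURATION = 60.0  # s, dynamometer-enforced
ISOKINETIC_DC = 0.5
_TIME_TOL = 1e-9


@dataclass(frozen=True)
class PhaseSpec:
    """One intermittent phase: (TL, DC, CT) coding plus cycle bookkeeping.

    Exactly one of ``n_cycles`` (whole cycles) or ``duration`` (fixed wall
    time; the final partial cycle is truncated, active portion first) must be
    given.
    """

    kind: str  # "isometric" | "isokinetic"
    TL: float
    DC: float
    CT: float
    n_cycles: int | None = None
    duration: float | None = None
    velocity: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("isometric", "isokinetic"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not 0.0 <= self.TL <= 1.0:
            raise ValueError(f"TL={self.TL} outside [0, 1]")
        if not 0.0 < self.DC <= 1.0:
            raise ValueError(f"DC={self.DC} outside (0, 1]")
        if self.CT <= 0:
            raise ValueError(f"CT={self.CT} must be > 0")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if (self.velocity == 0.0) != (self.kind == "isometric"):
            raise ValueError("velocity must be 0 iff the phase is isometric")
        if (self.n_cycles is None) == (self.duration is None):
            raise ValueError("give exactly one of n_cycles or duration")
        if self.n_cycles is not None and self.n_cycles <= 0:
            raise ValueError(f"n_cycles={self.n_cycles} must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError(f"duration={self.duration} must be positive")

    @property
    def total_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        return self.n_cycles * self.CT

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "TL": self.TL,
            "DC": self.DC,
            "CT": self.CT,
            "n_cycles": self.n_cycles,
            "duration": self.duration,
            "velocity": self.velocity,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseSpec":
        return cls(**{k: d.get(k) for k in (
            "kind", "TL", "DC", "CT", "n_cycles", "duration", "velocity", "label"
        ) if d.get(k) is not None or k in ("n_cycles", "duration")})


@dataclass(frozen=True)
class JointSpec:
    """A joint's tested range of motion, ROM stops and isokinetic velocities."""

    name: str
    ROM: float  # degrees
    rom_stops: tuple[float, ...]
    velocities: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rom_stops", tuple(self.rom_stops))
        object.__setattr__(self, "velocities", tuple(self.velocities))
        if len(self.rom_stops) not in (5, 6):
            raise ValueError("expected 5 or 6 ROM stops")
        if any(v <= 0 for v in self.velocities):
            raise ValueError("velocities must be > 0")
        span = max(self.rom_stops) - min(self.rom_stops)
        if abs(span - self.ROM) > 1e-9:
            raise ValueError(
                f"ROM stop span {span} inconsistent with declared ROM {self.ROM}"
            )

    @property
    def n_stops(self) -> int:
        return len(self.rom_stops)


#: Tested ROM stops (degrees) and isokinetic velocities (degree/s) per joint.
JOINT_TABLE: dict[str, JointSpec] = {
    "elbow": JointSpec("elbow", 75.0, (15, 30, 45, 60, 75, 90), (20, 30, 45, 60, 90)),
    "shoulder": JointSpec("shoulder", 120.0, (60, 90, 120, 150, 180), (20, 30, 45, 60, 75)),
    "hip": JointSpec("hip", 90.0, (0, 15, 30, 60, 75, 90), (30, 45, 60, 90, 120)),
    "knee": JointSpec("knee", 75.0, (90, 75, 60, 45, 30, 15), (30, 60, 90, 120, 150)),
}


@dataclass(frozen=True)
class TaskProfile:
    """Piecewise-constant (TL, V) profile with phase labels and MVIC times.

    ``breakpoints`` has one more entry than ``tl``/``v``; segment ``i`` covers
    ``[breakpoints[i], breakpoints[i+1])`` with constant load ``tl[i]`` and
    velocity ``v[i]``.
    """

    breakpoints: np.ndarray
    tl: np.ndarray
    v: np.ndarray
    phase_bounds: tuple[tuple[float, float], ...]
    phase_labels: tuple[str, ...]
    mvic_times: np.ndarray
    phases: tuple[PhaseSpec, ...] = field(default=())

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "tl", np.asarray(self.tl, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "mvic_times", np.asarray(self.mvic_times, dtype=float))
        if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and strictly increase")
        if len(self.tl) != len(bp) - 1 or len(self.v) != len(bp) - 1:
            raise ValueError("need one (TL, V) pair per segment")
        if np.any(self.tl < 0) or np.any(self.tl > 1):
            raise ValueError("TL must lie in [0, 1] everywhere")
        if np.any(self.v < 0):
            raise ValueError("V must be >= 0 everywhere")

    @property
    def total_duration(self) -> float:
        return float(self.breakpoints[-1])

    def _segment_index(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < -_TIME_TOL) or np.any(t > self.total_duration + _TIME_TOL):
            raise ValueError("time outside the profile horizon")
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        return np.clip(idx, 0, len(self.tl) - 1)

    def tl_at(self, t):
        return self.tl[self._segment_index(t)]

    def v_at(self, t):
        return self.v[self._segment_index(t)]

    def mvic_times_by_phase(self) -> list[np.ndarray]:
        """MVIC sample times grouped by isometric phase, in order."""
        out = []
        for (t0, t1), label in zip(self.phase_bounds, self.phase_labels):
            times = self.mvic_times[
                (self.mvic_times >= t0 - _TIME_TOL) & (self.mvic_times < t1 - _TIME_TOL)
            ]
            if len(times):
                out.append(times)
        return out

    def to_phase_dicts(self) -> list[dict]:
        if not self.phases:
            raise ValueError("profile was not built from phase specs")
        return [p.to_dict() for p in self.phases]

    @classmethod
    def from_phases(cls, phases: Iterable[PhaseSpec]) -> "TaskProfile":
        return _build_profile(list(phases))


def _build_profile(phases: Sequence[PhaseSpec]) -> TaskProfile:
    breaks = [0.0]
    tls: list[float] = []
    vs: list[float] = []
    bounds = []
    labels = []
    mvic_times: list[float] = []
    t = 0.0
    for i, ph in enumerate(phases):
        t_start = t
        t_end = t_start + ph.total_duration
        active_len = ph.DC * ph.CT
        n_full = int(math.floor(ph.total_duration / ph.CT + _TIME_TOL))
        # lay down complete cycles, then a truncated partial cycle if any
        for c in range(n_full + 1):
            c_start = t_start + c * ph.CT
            if c_start >= t_end - _TIME_TOL:
                break
            a_end = min(c_start + active_len, t_end)
            if ph.kind == "isometric" and ph.TL > 0:
                mvic_times.append(c_start)
            _append_segment(breaks, tls, vs, a_end, ph.TL, ph.velocity)
            c_end = min(c_start + ph.CT, t_end)
            if c_end > a_end + _TIME_TOL:
                # velocity is a phase property: held nominal through the rest half
                _append_segment(breaks, tls, vs, c_end, 0.0, ph.velocity)
        t = t_end
        bounds.append((t_start, t_end))
        labels.append(ph.label or f"PHASE{i + 1}")
    return TaskProfile(
        breakpoints=np.array(breaks),
        tl=np.array(tls),
        v=np.array(vs),
        phase_bounds=tuple(bounds),
        phase_labels=tuple(labels),
        mvic_times=np.array(mvic_times),
        phases=tuple(phases),
    )


def _append_segment(breaks, tls, vs, t_end, tl, v) -> None:
    if t_end <= breaks[-1] + _TIME_TOL:
        return
    breaks.append(t_end)
    tls.append(tl)
    vs.append(v)


def intermittent_profile(
    TL: float,
    DC: float,
    CT: float,
    n_cycles: int,
    velocity: float = 0.0,
    label: str = "",
) -> TaskProfile:
    """One intermittent phase: active (TL, V) for DC*CT s, rest for (1-DC)*CT s.

    The active portion leads each cycle, so MVIC sample times (isometric
    phases) fall at cycle onsets.
    """
    kind = "isometric" if velocity == 0.0 else "isokinetic"
    ph = PhaseSpec(kind=kind, TL=TL, DC=DC, CT=CT, n_cycles=n_cycles,
                   velocity=velocity, label=label)
    return _build_profile([ph])


def experiment_protocol(joint: JointSpec, velocity: float) -> TaskProfile:
    """Alternating dynamometer protocol: 5 isometric x 4 isokinetic phases.

    Isometric phases visit each ROM stop once (one 15 s cycle per stop, duty
    cycle 0.2, TL = 1, V = 0); isokinetic phases last 60 s at duty cycle 0.5
    with cycle time 2*ROM/velocity (one full sweep each way).  For a joint
    with 6 ROM stops the total duration is 5*90 + 4*60 = 690 s.
    """
    if velocity <= 0:
        raise ValueError("isokinetic velocity must be > 0")
    if velocity not in joint.velocities:
        warnings.warn(
            f"velocity {velocity} degree/s was not in the tested set for the "
            f"{joint.name}; the model extrapolates",
            stacklevel=2,
        )
    ct_isok = 2.0 * joint.ROM / velocity
    phases: list[PhaseSpec] = []
    for p in range(1, 6):
        phases.append(PhaseSpec(
            kind="isometric", TL=1.0, DC=ISOMETRIC_DC, CT=ISOMETRIC_CT,
            n_cycles=joint.n_stops, velocity=0.0, label=f"ISOM{p}",
        ))
        if p < 5:
            phases.append(PhaseSpec(
                kind="isokinetic", TL=1.0, DC=ISOKINETIC_DC, CT=ct_isok,
                duration=ISOKINETIC_DURATION, velocity=velocity,
                label=f"ISOK{p}",
            ))
    return _build_profile(phases)
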