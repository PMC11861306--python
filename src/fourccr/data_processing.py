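"""Dynamometer torque processing: peak MVICs -> per-phase strengths -> fatigue rates.

One test session yields peak isometric torques at n ROM stops in each of five
isometric measurement phases.  The pipeline:

1. normalize each phase's torques by that phase's maximum (torque-angle shape);
2. average the five normalized curves into one subject/session curve;
3. for each phase, scale the curve back onto the raw torques by least squares
   over every simple-majority subset of ceil((n+1)/2) stops, keeping the scale
   of the subset with the lowest summed squared residuals (robust to a
   minority of corrupted stops);
4. express consecutive scale-factor drops, relative to the first phase, as
   fatigue rates in %MVC per minute of intervening isokinetic work (recovery
   within the isometric phases is treated as negligible);
5. regress fatigue rate on isokinetic velocity within each muscle group x
   iteration cell (ordinary least squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TORQUE_COLUMNS",
    "StrengthSeries",
    "load_torque_csv",
    "normalize_phase",
    "subject_curve",
    "representative_scale",
    "fatigue_rates",
    "velocity_regression",
    "process_session",
    "process_dataset",
    "fatigue_rate_table",
    "regression_table",
]

TORQUE_COLUMNS = (
    "participant", "joint", "direction", "velocity_deg_s",
    "phase", "stop_deg", "peak_torque_Nm",
)
N_PHASES = 5
SESSION_KEYS = ["participant", "joint", "direction", "velocity_deg_s"]


@dataclass(frozen=True)
class StrengthSeries:
    """Per-phase representative strengths for one session (one muscle group)."""

    participant: str
    joint: str
    direction: str
    velocity: float
    scales: np.ndarray               # raw scale factors, N*m, phases 1..5
    subsets: tuple[tuple[int, ...], ...]
    residuals: np.ndarray            # summed squared residuals per phase
    stops: np.ndarray                # stop angles shared by all phases

    def __post_init__(self) -> None:
        if np.any(self.scales <= 0):
            raise ValueError("scale factors must be positive")

    @property
    def muscle_group(self) -> str:
        return f"{self.joint}_{self.direction}"

    @property
    def normalized(self) -> np.ndarray:
        """Strengths relative to the first isometric phase (phase 1 = 1)."""
        return self.scales / self.scales[0]


def load_torque_csv(path) -> pd.DataFrame:
    """Read and validate a long-format torque table.

    Raises ValueError naming the offending row/field for schema violations
    (missing columns, non-positive torque, phase outside 1..5).
    """
    df = pd.read_csv(path)
    missing = [c for c in TORQUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"torque CSV missing columns: {missing}")
    bad = df.index[df["peak_torque_Nm"] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive peak_torque_Nm at row {bad[0]} "
            f"(value {df.loc[bad[0], 'peak_torque_Nm']}): sensor artifact"
        )
    bad = df.index[~df["phase"].isin(range(1, N_PHASES + 1))]
    if len(bad):
        raise ValueError(f"phase outside 1..{N_PHASES} at row {bad[0]}")
    return df


def normalize_phase(torques: Sequence[float]) -> np.ndarray:
    """Normalize one phase's per-stop peaks by the phase maximum (max -> 1)."""
    t = np.asarray(torques, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 ROM stops per phase")
    if np.any(t <= 0):
        raise ValueError("non-positive peak torque (flag and exclude the record)")
    return t / t.max()


def subject_curve(phase_sets: Sequence[Sequence[float]]) -> np.ndarray:
    """Average the five normalized torque-angle curves of one session."""
    if len(phase_sets) != N_PHASES:
        raise ValueError(f"expected {N_PHASES} normalized phase sets")
    arr = np.asarray(phase_sets, dtype=float)
    if arr.ndim != 2:
        raise ValueError("phase sets must share one common stop set")
    return arr.mean(axis=0)


def majority_subset_size(n: int) -> int:
    """Simple-majority subset size ceil((n+1)/2); 4 of 6 stops, 3 of 5."""
    return math.ceil((n + 1) / 2)


def representative_scale(
    curve: Sequence[float], raw_phase: Sequence[float]
) -> tuple[float, tuple[int, ...], float]:
    """Best least-squares scale of ``curve`` onto a majority of raw torques.

    Every combination of ceil((n+1)/2) stops is fitted with the closed-form
    scale s = sum(y*c)/sum(c^2); the subset with the lowest summed squared
    residuals wins, ties broken by lowest lexicographic stop-index subset.
    Returns (scale, chosen subset, summed squared residuals).
    """
    c = np.asarray(curve, dtype=float)
    y = np.asarray(raw_phase, dtype=float)
    n = len(c)
    if len(y) != n:
        raise ValueError("curve and raw phase must cover the same stops")
    if n < 3:
        raise ValueError("need at least 3 ROM stops")
    m = majority_subset_size(n)
    best: tuple[float, tuple[int, ...], float] | None = None
    for subset in combinations(range(n), m):
        idx = list(subset)
        cc = c[idx]
        denom = float(cc @ cc)
        if denom == 0.0:
            continue  # degenerate: curve vanishes on this subset
        s = float(y[idx] @ cc) / denom
        res = y[idx] - s * cc
        rss = float(res @ res)
        if best is None or rss < best[2]:
            best = (s, subset, rss)
    if best is None:
        raise ValueError("curve is zero on every candidate subset")
    return best


def fatigue_rates(scales: Sequence[float], isok_minutes: float = 1.0) -> np.ndarray:
    """Strength declines between consecutive phases, %MVC per minute.

    Scales are first normalized by the session's phase-1 scale, so a drop of
    0.05 over one minute of isokinetic work reads as 5 %MVC/min.  Negative
    declines (apparent gains) are preserved.
    """
    s = np.asarray(scales, dtype=float)
    if len(s) != N_PHASES:
        raise ValueError(f"expected {N_PHASES} scale factors")
    s = s / s[0]
    return 100.0 * (s[:-1] - s[1:]) / isok_minutes


def velocity_regression(velocities: Sequence[float], rates: Sequence[float]):
    """OLS of fatigue rate on velocity: slope, 95% CI, two-sided p-value.

    Slope units are %MVC.s/(degree.min): change in normalized fatigue rate per
    unit change in angular velocity.
    """
    import statsmodels.api as sm

    v = np.asarray(velocities, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(np.unique(v)) < 3:
        raise ValueError("need rates at >= 3 distinct velocities")
    model = sm.OLS(y, sm.add_constant(v)).fit()
    ci = model.conf_int(alpha=0.05)
    return {
        "slope": float(model.params[1]),
        "ci_low": float(ci[1][0]),
        "ci_high": float(ci[1][1]),
        "p_value": float(model.pvalues[1]),
        "intercept": float(model.params[0]),
        "n": int(len(y)),
    }


def process_session(session_df: pd.DataFrame) -> StrengthSeries:
    """Run steps 1-3 of the pipeline on one session's torque records."""
    meta = session_df.iloc[0]
    phases = []
    stops_ref: np.ndarray | None = None
    for p in range(1, N_PHASES + 1):
        sub = session_df[session_df["phase"] == p].sort_values("stop_deg")
        if sub.empty:
            raise ValueError(f"session is missing isometric phase {p}")
        stops = sub["stop_deg"].to_numpy(dtype=float)
        if stops_ref is None:
            stops_ref = stops
        elif not np.array_equal(stops, stops_ref):
            raise ValueError("ROM stop sets differ between phases of one session")
        phases.append(sub["peak_torque_Nm"].to_numpy(dtype=float))
    normalized = [normalize_phase(t) for t in phases]
    curve = subject_curve(normalized)
    scales, subsets, rss = [], [], []
    for raw in phases:
        s, subset, r = representative_scale(curve, raw)
        scales.append(s)
        subsets.append(subset)
        rss.append(r)
    return StrengthSeries(
        participant=str(meta["participant"]),
        joint=str(meta["joint"]),
        direction=str(meta["direction"]),
        velocity=float(meta["velocity_deg_s"]),
        scales=np.array(scales),
        subsets=tuple(subsets),
        residuals=np.array(rss),
        stops=stops_ref,
    )


def process_dataset(df: pd.DataFrame) -> list[StrengthSeries]:
    """Split a long-format table into sessions and process each."""
    return [process_session(g) for _, g in df.groupby(SESSION_KEYS, sort=True)]


def strength_frame(series: Sequence[StrengthSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for p in range(N_PHASES):
            rows.append({
                "participant": s.participant,
                "muscle_group": s.muscle_group,
                "velocity_deg_s": s.velocity,
                "phase": p + 1,
                "scale_Nm": s.scales[p],
                "normalized_strength": s.normalized[p],
                "subset": ",".join(map(str, s.subsets[p])),
                "rss": s.residuals[p],
            })
    return pd.DataFrame(rows)


def fatigue_rate_frame(series: Sequence[StrengthSeries]) -> pd.DataFrame:
    """Per-session fatigue rates, one row per isokinetic iteration."""
    rows = []
    for s in series:
        for i, rate in enumerate(fatigue_rates(s.scales), start=1):
            rows.append({
                "participant": s.participant,
                "muscle_group": s.muscle_group,
                "velocity_deg_s": s.velocity,
                "iteration": f"ISOK{i}",
                "rate_pct_mvc_per_min": rate,
            })
    return pd.DataFrame(rows)


def fatigue_rate_table(rate_df: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of fatigue rate per muscle group x velocity x iteration."""
    g = rate_df.groupby(["muscle_group", "velocity_deg_s", "iteration"])
    out = g["rate_pct_mvc_per_min"].agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_rate", "std": "sd_rate", "count": "n"})


def regression_table(rate_df: pd.DataFrame) -> pd.DataFrame:
    """Velocity regression per muscle group x iteration over session rates."""
    rows = []
    for (group, it), sub in rate_df.groupby(["muscle_group", "iteration"]):
        fit = velocity_regression(sub["velocity_deg_s"], sub["rate_pct_mvc_per_min"])
        rows.append({"muscle_group": group, "iteration": it, **fit})
    return pd.DataFrame(rows)
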