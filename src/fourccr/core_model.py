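"""Four-compartment controller (4CCr) muscle fatigue model: governing equations.

The motor-unit pool of one functional muscle group (FMG) is split into four
compartments expressed as fractions of total force capacity:

* ``MA`` — active (producing force now),
* ``MR`` — resting (available for immediate recruitment),
* ``MFP`` — peripherally fatigued (impairment at/distal to the neuromuscular
  junction: excitation–contraction coupling, metabolic),
* ``MFC`` — centrally fatigued (impaired voluntary activation).

Flows between compartments::

    dMA/dt  = -FP*MA - FC*MA + C(t)
    dMR/dt  =  RP*MFP + RC*MFC - C(t)
    dMFP/dt = -RP*MFP + FP*MA
    dMFC/dt = -RC*MFC + FC*MA

with a bidirectional proportional controller ``C(t) = L*min(TL - MA, MR)``
driving recruitment toward the target load TL (fraction of current maximal
capacity).  Joint angular velocity V (degree/s, concentric agonist convention)
splits fatigue between the central and peripheral routes:

    FP = FP0*(1 - exp(-k*V)),    FC = FC0*exp(-k*V)

so isometric work (V=0) is purely central and fast dynamic work increasingly
peripheral.  Peripheral recovery is constant (RP = RP0); central recovery is
enhanced by a rest multiplier r when the muscle is unloaded (TL = 0).

At V=0 the model reduces algebraically to the three-compartment controller
model with enhanced recovery (3CCr), with the single fatigued pool playing the
role of MFC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple
import warnings

__all__ = [
    "FatigueParameters",
    "CompartmentState",
    "RateCoefficients",
    "RESTED_STATE",
    "VELOCITY_PARAMETER_TABLE",
    "controller_drive",
    "fatigue_coefficients",
    "recovery_coefficients",
    "compartment_derivatives",
    "derivatives",
    "load_parameters",
]

_SUM_TOL = 1e-9
_L_WARN_THRESHOLD = 10.0


@dataclass(frozen=True)
class FatigueParameters:
    """Rate constants and coefficients of the 4CCr model.

    Parameters
    ----------
    FC0, FP0 : float
        Central / peripheral fatigue rate constants (1/s).
    RC0, RP0 : float
        Central / peripheral recovery rate constants (1/s).
    r : float
        Central recovery multiplier applied at rest (TL = 0), dimensionless,
        >= 1.
    k : float
        Velocity coefficient magnitude (s/degree).  Stored as ``|k|``; fitted
        tables sometimes report the signed exponent coefficient instead.
    L : float
        Force development/relaxation controller gain (dimensionless).  Values
        above ~10 give fast, accurate tracking of TL; default 20.
    rest_multiplier_at_rest : bool
        If True (default) the multiplier r applies when TL = 0; if False it
        applies when TL > 0 (sensitivity switch for the opposite reading of
        the recovery branch).
    muscle_group : str, optional
        Label for provenance/reporting only.
    """

    FC0: float
    FP0: float
    RC0: float
    RP0: float
    r: float = 1.0
    k: float = 0.0
    L: float = 20.0
    rest_multiplier_at_rest: bool = True
    muscle_group: str = ""

    def __post_init__(self) -> None:
        for name in ("FC0", "FP0", "RC0", "RP0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.k < 0:
            # tables report the signed exponent coefficient; store magnitude
            object.__setattr__(self, "k", -self.k)
        if self.L < _L_WARN_THRESHOLD:
            warnings.warn(
                f"controller gain L={self.L} < {_L_WARN_THRESHOLD}: "
                "force tracking of TL may be poor",
                stacklevel=2,
            )

    def with_updates(self, **kwargs) -> "FatigueParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompartmentState:
    """Fractions of the motor-unit pool in each compartment (sum to 1)."""

    MA: float
    MR: float
    MFP: float = 0.0
    MFC: float = 0.0

    def __post_init__(self) -> None:
        for name in ("MA", "MR", "MFP", "MFC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.MA + self.MR + self.MFP + self.MFC
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"compartments sum to {total}, expected 1")

    @property
    def residual_capacity(self) -> float:
        """Fraction of capacity not fatigued: MA + MR = 1 - MFP - MFC."""
        return self.MA + self.MR

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.MA, self.MR, self.MFP, self.MFC)


RESTED_STATE = CompartmentState(MA=0.0, MR=1.0, MFP=0.0, MFC=0.0)


class RateCoefficients(NamedTuple):
    """Instantaneous fatigue/recovery rates (1/s) at one (TL, V) condition."""

    FP: float
    FC: float
    RP: float
    RC: float


def _check_tl(TL: float) -> None:
    if not 0.0 <= TL <= 1.0:
        raise ValueError(f"target load TL={TL} outside [0, 1]")


def controller_drive(TL: float, MA: float, MR: float, L: float = 20.0) -> float:
    """Bidirectional activation/deactivation drive C(t) = L*min(TL - MA, MR).

    Positive when more motor units are needed and rested ones are available;
    negative (deactivation) when the active pool exceeds the demand.
    """
    _check_tl(TL)
    if L <= 0:
        raise ValueError(f"controller gain L must be > 0, got {L}")
    if not 0.0 <= MA <= 1.0 or not 0.0 <= MR <= 1.0:
        raise ValueError("MA and MR must lie in [0, 1]")
    return L * min(TL - MA, MR)


def fatigue_coefficients(V: float, params: FatigueParameters) -> tuple[float, float]:
    """Velocity-dependent fatigue rates (FP, FC).

    FP = FP0*(1 - e^(-k*V)) grows with velocity; FC = FC0*e^(-k*V) shrinks,
    so the central share of fatigue dominates slow/static work and the
    peripheral share dominates fast work.  V is the joint angular velocity in
    degree/s under the concentric-agonist convention, hence V >= 0.
    """
    if V < 0:
        raise ValueError(f"velocity must be >= 0 (concentric convention), got {V}")
    decay = math.exp(-params.k * V)
    return params.FP0 * (1.0 - decay), params.FC0 * decay


def recovery_coefficients(TL: float, params: FatigueParameters) -> tuple[float, float]:
    """Recovery rates (RP, RC): RP is constant, RC is boosted by r at rest."""
    _check_tl(TL)
    at_rest = TL == 0.0
    if params.rest_multiplier_at_rest:
        RC = params.r * params.RC0 if at_rest else params.RC0
    else:
        RC = params.RC0 if at_rest else params.r * params.RC0
    return params.RP0, RC


def compartment_derivatives(
    state: CompartmentState, rates: RateCoefficients, C: float
) -> tuple[float, float, float, float]:
    """Raw compartment flow balance for given rates and controller drive C."""
    MA, MR, MFP, MFC = state.as_tuple()
    dMA = -rates.FP * MA - rates.FC * MA + C
    dMR = rates.RP * MFP + rates.RC * MFC - C
    dMFP = -rates.RP * MFP + rates.FP * MA
    dMFC = -rates.RC * MFC + rates.FC * MA
    return dMA, dMR, dMFP, dMFC


def derivatives(
    state: CompartmentState, TL: float, V: float, params: FatigueParameters
) -> tuple[float, float, float, float]:
    """Time derivatives (dMA, dMR, dMFP, dMFC) at one instant.

    The four flows are pairwise opposed, so the derivatives sum to zero and
    the total motor-unit pool is conserved exactly.
    """
    FP, FC = fatigue_coefficients(V, params)
    RP, RC = recovery_coefficients(TL, params)
    C = controller_drive(TL, state.MA, state.MR, params.L)
    return compartment_derivatives(state, RateCoefficients(FP, FC, RP, RC), C)


# Fitted velocity-split parameters per functional muscle group: velocity
# coefficient magnitude k (s/degree), peripheral recovery RP0 (1/s) and the
# ratio FP0/RP0 (dimensionless).  FP0 = ratio * RP0.  Central-side constants
# (FC0, RC0, r) are joint-level three-compartment quantities and must be
# supplied by the caller; no defaults ship for them.
VELOCITY_PARAMETER_TABLE: dict[str, dict[str, float]] = {
    "shoulder_flexors": {"k": 0.0086, "RP0": 1.2e-5, "FP0_over_RP0": 1211.0},
    "shoulder_extensors": {"k": 0.0233, "RP0": 8.2e-6, "FP0_over_RP0": 884.0},
    "hip_flexors": {"k": 0.0254, "RP0": 1.0e-5, "FP0_over_RP0": 848.0},
    "hip_extensors": {"k": 0.0319, "RP0": 3.2e-5, "FP0_over_RP0": 552.0},
    "knee_flexors": {"k": 0.0182, "RP0": 1.0e-5, "FP0_over_RP0": 927.0},
    "knee_extensors": {"k": 0.0147, "RP0": 2.2e-5, "FP0_over_RP0": 223.0},
}


def load_parameters(source: str | Path | dict) -> FatigueParameters:
    """Build FatigueParameters from a mapping or a JSON/YAML file.

    Expected keys: ``muscle_group, FC0, RC0, r, L, k, RP0`` and either
    ``FP0`` directly or the ratio ``FP0_over_RP0`` (then FP0 = ratio * RP0).
    Extra keys (e.g. ``provenance``) are ignored but preserved nowhere —
    keep provenance in the config file itself.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    else:
        data = dict(source)
    if "FP0" in data:
        FP0 = float(data["FP0"])
    elif "FP0_over_RP0" in data:
        FP0 = float(data["FP0_over_RP0"]) * float(data["RP0"])
    else:
        raise KeyError("parameter file must define FP0 or FP0_over_RP0")
    return FatigueParameters(
        FC0=float(data["FC0"]),
        FP0=FP0,
        RC0=float(data["RC0"]),
        RP0=float(data["RP0"]),
        r=float(data.get("r", 1.0)),
        k=float(data.get("k", 0.0)),
        L=float(data.get("L", 20.0)),
        rest_multiplier_at_rest=bool(data.get("rest_multiplier_at_rest", True)),
        muscle_group=str(data.get("muscle_group", "")),
    )
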