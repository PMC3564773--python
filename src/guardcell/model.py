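"""Core kinetic model of ABA/ethylene-induced stomatal closure.

The model tracks six quantities in guard cells, each expressed as percent
of the untreated control: reactive oxygen species (ROS, here hydrogen
peroxide and associated species), two antioxidant activities (AOX1, AOX2),
nitric oxide (NO), active outward-rectifying K+ channels (Kout), and
cytosolic K+ — the last being a direct proxy for stomatal aperture.  Two
external inputs, the hormone doses [ABA] and [ACC] (the ethylene precursor),
are applied as a step at t = 0 and held constant.

Five of the variables obey coupled nonlinear ODEs; AOX2 is available in
closed form as the terminal species of a linear activation cascade driven
by the product of two Michaelis–Menten factors, so it is treated as an
explicit forcing function of time.  The cascade response is the normalised
lower incomplete gamma function P(n, rate*t).

Two model variants are supported:

``primary``
    Ethylene produces NO directly (rate ``alpha32``); ``alpha43`` unused.
``ph_variant``
    Ethylene instead raises cytosolic pH, recruiting outward K+ channels
    (rate ``alpha43``); ``alpha32`` is forced to zero.

Either variant has 28 free parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import special

__all__ = [
    "PARAM_NAMES",
    "VARIANTS",
    "StimulusDose",
    "ModelParameters",
    "ModelState",
    "cascade_response",
    "aox2_level",
    "derivatives",
    "count_free_parameters",
    "free_parameter_names",
    "make_basal_consistent",
]

#: Control level: every state variable is 100 at t = 0 (percent of control).
CONTROL_LEVEL = 100.0

#: Recognised model variant tags.
VARIANTS = ("primary", "ph_variant")

#: Canonical parameter order (29 symbols; each variant uses 28 of them).
PARAM_NAMES = (
    # ROS balance
    "alpha10", "alpha11", "alpha12", "k11", "k12", "beta11", "beta12",
    # AOX1 balance (OR-gated cascade)
    "alpha20", "alpha21", "alpha22", "k21", "k22", "n1", "alpha23", "beta20",
    # AOX2 (AND-gated cascade, closed form)
    "n2", "beta13",
    # NO balance
    "alpha31", "alpha32", "k31", "beta30",
    # Outward K+ channel balance
    "alpha40", "alpha41", "alpha42", "beta40", "alpha43",
    # Cytosolic K+ balance
    "alpha51", "k51", "beta50",
)


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {VARIANTS}"
        )


@dataclass(frozen=True)
class StimulusDose:
    """Hormone doses in uM, applied as a step at t = 0 (zero before)."""

    aba: float = 0.0
    acc: float = 0.0

    def __post_init__(self) -> None:
        if self.aba < 0 or self.acc < 0:
            raise ValueError("doses must be non-negative")


@dataclass(frozen=True)
class ModelState:
    """The five ODE state variables, percent of control.

    AOX2 is not part of the state: it is an explicit function of time.
    """

    ros: float
    aox1: float
    no: float
    kout: float
    k: float

    def __post_init__(self) -> None:
        if min(self.ros, self.aox1, self.no, self.kout, self.k) < 0:
            raise ValueError("state variables must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.ros, self.aox1, self.no, self.kout, self.k])

    @classmethod
    def control(cls) -> "ModelState":
        """The all-100 initial state (percent-of-control convention)."""
        return cls(*(CONTROL_LEVEL,) * 5)


@dataclass(frozen=True)
class ModelParameters:
    """Rate, saturation and cascade-length constants of the model.

    Units: production/activation rates ``alpha*`` in %/min (except the
    couplings ``alpha23``, ``alpha42`` in 1/min and ``alpha51`` in %^2/min);
    removal coefficients ``beta*`` in 1/min (``beta11``, ``beta12``,
    ``beta50`` per unit of the partner species); saturation constants
    ``k11``/``k12``/``k21``/``k22`` in uM and ``k31``/``k51`` in percent of
    control; ``n1``, ``n2`` dimensionless cascade lengths (>= 1).

    ``alpha43`` couples ACC to channel recruitment and acts only under the
    ``ph_variant``; ``alpha32`` (ACC -> NO) acts only under ``primary``.
    """

    alpha10: float
    alpha11: float
    alpha12: float
    k11: float
    k12: float
    beta11: float
    beta12: float
    alpha20: float
    alpha21: float
    alpha22: float
    k21: float
    k22: float
    n1: float
    alpha23: float
    beta20: float
    n2: float
    beta13: float
    alpha31: float
    alpha32: float
    k31: float
    beta30: float
    alpha40: float
    alpha41: float
    alpha42: float
    beta40: float
    alpha51: float
    k51: float
    beta50: float
    alpha43: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cascade lengths n1, n2 must be >= 1")

    # -- conversions ----------------------------------------------------

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_array(self, names: Sequence[str] = PARAM_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names])

    def with_values(self, names: Iterable[str], values: Iterable[float]) -> "ModelParameters":
        return replace(self, **dict(zip(names, values)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def free_parameter_names(variant: str) -> tuple:
    """Names of the 28 independently fitted constants for a variant."""
    _check_variant(variant)
    excluded = "alpha43" if variant == "primary" else "alpha32"
    return tuple(n for n in PARAM_NAMES if n != excluded)


def count_free_parameters(variant: str) -> int:
    """Number of independently fitted constants (28 for either variant)."""
    return len(free_parameter_names(variant))


def cascade_response(n: float, rate: float, t) -> np.ndarray:
    """Terminal-species response of an n-step equal-rate linear cascade.

    Returns P(n, rate*t), the normalised lower incomplete gamma function,
    which solves the cascade dx_i/dt = rate*(x_{i-1} - x_i) with a unit
    step input x_0 = 1 and x_i(0) = 0.  Monotone non-decreasing in t, 0 at
    t = 0, with limit 1 as t -> inf.  For n = 1 it reduces to
    1 - exp(-rate*t).  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if n < 1:
        raise ValueError(f"cascade length n must be >= 1, got {n}")
    if rate < 0:
        raise ValueError(f"cascade rate must be >= 0, got {rate}")
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return special.gammainc(n, rate * t)


def aox2_level(params: ModelParameters, dose: StimulusDose, t) -> np.ndarray:
    """Closed-form AND-gated antioxidant level AOX2(t), dimensionless [0, 1).

    The product of the two Michaelis–Menten occupancy factors gates the
    cascade: AOX2 is identically zero unless both hormones are present.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    gate = (dose.aba * dose.acc) / ((params.k11 + dose.aba) * (params.k12 + dose.acc))
    return gate * cascade_response(params.n2, params.beta13, t)


def _production_mm(a_aba: float, a_acc: float, k_aba: float, k_acc: float,
                   aba: float, acc: float) -> float:
    """Compound (OR-gated) Michaelis–Menten production term.

    Shared-enzyme form: (a1*k2*ABA + a2*k1*ACC) / (k1*k2 + k2*ABA + k1*ACC).
    Bounded by max(a1, a2) and monotone in each dose.
    """
    return (a_aba * k_acc * aba + a_acc * k_aba * acc) / (
        k_aba * k_acc + k_acc * aba + k_aba * acc
    )


def derivatives(params: ModelParameters, state: ModelState, t: float,
                dose: StimulusDose, variant: str = "primary") -> np.ndarray:
    """Time derivatives (d/dt) of (ROS, AOX1, NO, Kout, K+), %/min.

    AOX2 enters through its closed form at time ``t``.  Under the
    ``ph_variant`` the ACC->NO route (``alpha32``) is switched off and the
    ACC->Kout route (``alpha43``) is active; under ``primary`` vice versa.
    """
    _check_variant(variant)
    p = params
    aba, acc = dose.aba, dose.acc
    ros, aox1, no, kout, k = state.ros, state.aox1, state.no, state.kout, state.k

    aox2 = float(aox2_level(p, dose, t))
    d_ros = (
        p.alpha10
        + _production_mm(p.alpha11, p.alpha12, p.k11, p.k12, aba, acc)
        - (p.beta11 * aox1 + p.beta12 * aox2) * ros
    )
    d_aox1 = (
        p.alpha20
        + _production_mm(p.alpha21, p.alpha22, p.k21, p.k22, aba, acc)
        * float(cascade_response(p.n1, p.alpha23, t))
        - p.beta20 * aox1
    )
    acc_no = 0.0 if variant == "ph_variant" else p.alpha32 * acc / (p.k12 + acc)
    d_no = p.alpha31 * ros / (p.k31 + ros) + acc_no - p.beta30 * no
    acc_kout = p.alpha43 * acc / (p.k12 + acc) if variant == "ph_variant" else 0.0
    d_kout = (
        p.alpha40 + p.alpha41 * aba / (p.k11 + aba) + p.alpha42 * no + acc_kout
        - p.beta40 * kout
    )
    d_k = p.alpha51 / (p.k51 + no) - p.beta50 * kout * k
    return np.array([d_ros, d_aox1, d_no, d_kout, d_k])


def make_basal_consistent(params: ModelParameters) -> ModelParameters:
    """Re-solve the constant production terms so that the unstimulated
    all-100 state is a fixed point.

    With zero doses and AOX2 = 0, the basal balance of each equation fixes
    one production constant: alpha10 (ROS), alpha20 (AOX1), alpha31 (NO),
    alpha40 (Kout) and alpha51 (K+).  Used by the synthetic-data generator
    so that control trajectories stay flat at 100; fitting does not enforce
    this constraint.

    Raises if a required removal coefficient (beta11, beta20, beta40,
    beta50) is zero, or if the channel balance would need alpha40 < 0
    (i.e. alpha42 > beta40).
    """
    c = CONTROL_LEVEL
    for name in ("beta11", "beta20", "beta40", "beta50"):
        if getattr(params, name) == 0:
            raise ValueError(f"basal consistency requires {name} > 0")
    alpha40 = c * (params.beta40 - params.alpha42)
    if alpha40 < 0:
        raise ValueError(
            "basal consistency needs alpha42 <= beta40 "
            f"(got alpha42={params.alpha42}, beta40={params.beta40})"
        )
    return replace(
        params,
        alpha10=params.beta11 * c * c,
        alpha20=params.beta20 * c,
        alpha31=params.beta30 * (params.k31 + c),
        alpha40=alpha40,
        alpha51=params.beta50 * c * c * (params.k51 + c),
    )
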