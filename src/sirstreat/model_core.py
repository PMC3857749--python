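"""Core model definitions: parameters, states, and the three system variants.

The model is a planar/3-D SIRS system with saturated incidence
``beta*S*I/(1 + alpha*I**2)``, constant-capacity treatment ``h(I)`` and
constant recruitment of susceptibles ``(1-p)*A`` and infectives ``p*A``.
Three right-hand sides are provided:

* :func:`rhs_full` -- the 3-D (S, I, R) system with the treatment branch.
* :func:`rhs_reduced` -- the planar (I, R) system obtained on the invariant
  plane ``S + I + R = N0`` with ``h(I) = k`` (valid on the open domain D
  where ``I > 0``).
* :func:`rhs_rescaled` -- the reduced system multiplied by the positive
  factor ``1 + alpha*I**2``; orbitally equivalent to the reduced one.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from typing import Iterable, NamedTuple

__all__ = [
    "PARAM_NAMES",
    "ModelParams",
    "StateFull",
    "StateReduced",
    "treatment",
    "rhs_full",
    "rhs_reduced",
    "rhs_rescaled",
    "compute_R0",
    "compute_N0",
    "in_domain",
]

#: Canonical ordering of the eight primitive parameters.
PARAM_NAMES = ("A", "d", "beta", "m", "gamma", "alpha", "p", "k")


@dataclass(frozen=True)
class ModelParams:
    """The eight positive rates/constants of the model.

    Parameters
    ----------
    A : float
        Recruitment rate (individuals / time).
    d : float
        Natural death rate (1 / time).
    beta : float
        Transmission proportionality constant.
    m : float
        Recovery rate (1 / time).
    gamma : float
        Immunity-loss rate (1 / time).
    alpha : float
        Inhibition (saturation) parameter (1 / individuals**2).
    p : float
        Fraction of recruitment entering the infective class; ``0 < p < 1``.
    k : float
        Constant treatment capacity (individuals / time).

    Derived quantities (``N0``, ``pA``, ``R0``) are computed on demand from
    the primitive fields and never stored.
    """

    A: float
    d: float
    beta: float
    m: float
    gamma: float
    alpha: float
    p: float
    k: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)):
                raise TypeError(f"parameter {f.name!r} must be a number, got {value!r}")
            if not math.isfinite(value):
                raise ValueError(f"parameter {f.name!r} must be finite, got {value!r}")
            if value <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {value!r}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"parameter 'p' must lie strictly inside (0, 1), got {self.p!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def N0(self) -> float:
        """Equilibrium total population size ``A / d``."""
        return self.A / self.d

    @property
    def pA(self) -> float:
        """Infective recruitment rate ``p * A``."""
        return self.p * self.A

    @property
    def R0(self) -> float:
        """Threshold ratio ``k / (p*A)`` of treatment capacity to infective inflow.

        Note this is an equilibrium-structure threshold, not the classical
        basic reproduction number.
        """
        return self.k / (self.p * self.A)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        """Build from a flat mapping, rejecting unknown and missing keys."""
        unknown = sorted(set(mapping) - set(PARAM_NAMES))
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        missing = [name for name in PARAM_NAMES if name not in mapping]
        if missing:
            raise ValueError(f"missing parameters: {', '.join(missing)}")
        return cls(**{name: float(mapping[name]) for name in PARAM_NAMES})


class StateFull(NamedTuple):
    """Full-system state (S, I, R), each compartment size >= 0."""

    S: float
    I: float
    R: float


class StateReduced(NamedTuple):
    """Reduced/rescaled-system state (I, R)."""

    I: float
    R: float


def treatment(I: float, k: float) -> float:
    """Constant-capacity treatment function ``h(I)``.

    Returns ``k`` for any ``I > 0`` and ``0`` at ``I == 0`` exactly.

    Raises
    ------
    ValueError
        If ``I`` is negative or ``k`` is not positive.
    """
    if I < 0:
        raise ValueError(f"number of infectives must be non-negative, got {I!r}")
    if k <= 0:
        raise ValueError(f"treatment capacity must be positive, got {k!r}")
    return k if I > 0 else 0.0


def rhs_reduced(state: Iterable[float], params: ModelParams) -> tuple[float, float]:
    """Planar vector field (dI/dt, dR/dt) on the invariant plane.

    ``h(I)`` is substituted by ``k`` unconditionally, which is valid on the
    domain D where ``I > 0``.
    """
    I, R = state
    incidence = params.beta * I * (params.N0 - I - R) / (1.0 + params.alpha * I * I)
    dI = params.pA - params.k + incidence - (params.d + params.m) * I
    dR = params.m * I - (params.d + params.gamma) * R + params.k
    return dI, dR


def rhs_rescaled(state: Iterable[float], params: ModelParams) -> tuple[float, float]:
    """Time-rescaled planar field: :func:`rhs_reduced` times ``1 + alpha*I**2``.

    The factor is strictly positive, so the two fields are orbitally
    equivalent: same orbits and equilibria, reparametrized time.  Uses the
    identities ``pA*R0 = k`` and ``(1 - R0)*pA = pA - k``.
    """
    I, R = state
    f = 1.0 + params.alpha * I * I
    dI = (
        params.beta * I * (params.N0 - I - R)
        - (params.d + params.m) * I * f
        + (1.0 - params.R0) * params.pA * f
    )
    dR = (params.m * I - (params.d + params.gamma) * R + params.pA * params.R0) * f
    return dI, dR


def rhs_full(state: Iterable[float], params: ModelParams) -> tuple[float, float, float]:
    """Full 3-D vector field (dS/dt, dI/dt, dR/dt).

    Keeps the discontinuous treatment branch ``h(I)``.  The derivatives sum
    to ``A - d*(S + I + R)`` identically (total population relaxes to N0).
    State ordering is (S, I, R).
    """
    S, I, R = state
    if S < 0 or I < 0 or R < 0:
        raise ValueError("compartment sizes must be non-negative")
    h = treatment(I, params.k)
    incidence = params.beta * I * S / (1.0 + params.alpha * I * I)
    dS = (1.0 - params.p) * params.A - incidence - params.d * S + params.gamma * R
    dI = params.pA + incidence - (params.d + params.m) * I - h
    dR = params.m * I - (params.d + params.gamma) * R + h
    return dS, dI, dR


def compute_R0(params: ModelParams) -> float:
    """Threshold ratio ``k / (p*A)``."""
    return params.R0


def compute_N0(params: ModelParams) -> float:
    """Equilibrium total population size ``A / d``."""
    return params.N0


def in_domain(state: Iterable[float], params: ModelParams, slack: float = 0.0) -> bool:
    """Membership of an (I, R) state in the open domain D.

    D = {(I, R) : I > 0, R > 0, I + R < N0}.  A non-negative ``slack``
    loosens the strict inequalities to tolerate round-off.
    """
    I, R = state
    return I > -slack and R > -slack and I + R < params.N0 + slack
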