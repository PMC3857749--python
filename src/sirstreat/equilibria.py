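"""Endemic equilibria via the equilibrium cubic.

Substituting ``R = (m*I + k)/(d + gamma)`` into the steady-state balance of
the reduced system yields a cubic ``f(I) = c3*I**3 + c2*I**2 + c1*I + c0``
whose positive roots inside the domain D are the endemic equilibria.  The
leading coefficient ``c3 = alpha*(d+m)`` is always positive and the constant
term ``c0 = k - p*A`` changes sign exactly at the threshold ``R0 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, in_domain, rhs_reduced

__all__ = [
    "CubicCoefficients",
    "Equilibrium",
    "ExistenceReport",
    "cubic_coefficients",
    "equilibrium_R",
    "find_equilibria",
    "vieta_check",
]


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the equilibrium cubic, highest degree first."""

    c3: float
    c2: float
    c1: float
    c0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c3, self.c2, self.c1, self.c0])

    def __call__(self, I: float) -> float:
        """Evaluate f(I) by Horner's rule."""
        return ((self.c3 * I + self.c2) * I + self.c1) * I + self.c0


@dataclass(frozen=True)
class Equilibrium:
    """A real root of the equilibrium cubic mapped to the (I, R) plane.

    ``residual`` is the larger of ``|f(I_e)|`` and the max-norm of the
    reduced vector field at (I_e, R_e); ``multiplicity`` counts clustered
    roots merged within tolerance (2 at a saddle-node tangency).
    """

    I: float
    R: float
    residual: float
    in_domain: bool
    multiplicity: int = 1

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "R": self.R,
            "in_domain": self.in_domain,
            "residual": self.residual,
            "multiplicity": self.multiplicity,
        }


@dataclass(frozen=True)
class ExistenceReport:
    """Classification of the equilibrium structure for one parameter set."""

    R0: float
    regime: str  # unique_endemic | one_or_two_endemic | threshold
    equilibria: tuple[Equilibrium, ...]
    vieta_residuals: tuple[float, float]
    roots: tuple[complex, ...] = field(default=())

    @property
    def in_domain_equilibria(self) -> tuple[Equilibrium, ...]:
        return tuple(e for e in self.equilibria if e.in_domain)

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "regime": self.regime,
            "equilibria": [e.to_dict() for e in self.equilibria],
            "vieta_residuals": list(self.vieta_residuals),
        }


def cubic_coefficients(params: ModelParams) -> CubicCoefficients:
    """Coefficients of the equilibrium cubic f(I)."""
    d, gamma = params.d, params.gamma
    c3 = params.alpha * (d + params.m)
    c2 = params.beta * (d + gamma + params.m) / (d + gamma) + (params.k - params.pA) * params.alpha
    c1 = d + params.m + params.beta * params.k / (d + gamma) - params.beta * params.N0
    c0 = params.k - params.pA
    return CubicCoefficients(c3, c2, c1, c0)


def equilibrium_R(I: float, params: ModelParams) -> float:
    """Map a root I_e to its recovered coordinate ``(m*I + k)/(d + gamma)``."""
    return (params.m * I + params.k) / (params.d + params.gamma)


def vieta_check(
    coeffs: CubicCoefficients, roots: tuple[complex, complex, complex]
) -> tuple[float, float]:
    """Absolute residuals of the two Vieta identities for the cubic.

    The sum identity ``I1+I2+I3 = -c2/c3`` and the product identity
    ``I1*I2*I3 = -c0/c3`` are algebraically exact for the true roots; on
    well-scaled inputs both residuals should be below ~1e-8.
    """
    if len(roots) != 3:
        raise ValueError("expected exactly three roots")
    r = np.asarray(roots, dtype=complex)
    residual_sum = abs(r.sum() - (-coeffs.c2 / coeffs.c3))
    residual_product = abs(r.prod() - (-coeffs.c0 / coeffs.c3))
    return float(residual_sum), float(residual_product)


def _merge_multiplicities(real_roots: np.ndarray, merge_tol: float) -> list[tuple[float, int]]:
    """Cluster sorted real roots closer than ``merge_tol`` into multiple roots."""
    merged: list[tuple[float, int]] = []
    for root in np.sort(real_roots):
        if merged and abs(root - merged[-1][0]) <= merge_tol:
            prev, mult = merged[-1]
            # centroid keeps the merged root stable against ordering
            merged[-1] = ((prev * mult + root) / (mult + 1), mult + 1)
        else:
            merged.append((float(root), 1))
    return merged


def find_equilibria(
    params: ModelParams,
    *,
    real_tol: float = 1e-9,
    merge_rtol: float = 1e-7,
    domain_slack: float = 1e-12,
    threshold_rtol: float = 1e-9,
) -> ExistenceReport:
    """Locate all equilibria and classify the existence regime.

    Roots are computed via the companion-matrix eigenvalues of the cubic
    (``numpy.roots``), which is robust near double roots.  A root counts as
    real when ``|imag| <= real_tol * (1 + |real|)``; two real roots within
    ``merge_rtol * N0`` of each other are reported once with multiplicity 2.
    Domain membership uses the strict inequalities of D with a small slack
    against round-off.  When ``R0 < 1`` the unique in-domain root is
    additionally checked against the bracket ``((pA-k)/(d+m), N0)``.

    Returns equilibria sorted ascending by I.
    """
    coeffs = cubic_coefficients(params)
    roots = np.roots(coeffs.as_array())
    real_mask = np.abs(roots.imag) <= real_tol * (1.0 + np.abs(roots.real))
    real_roots = roots.real[real_mask]

    equilibria = []
    for I_e, mult in _merge_multiplicities(real_roots, merge_rtol * params.N0):
        R_e = equilibrium_R(I_e, params)
        rhs = rhs_reduced((I_e, R_e), params)
        residual = max(abs(coeffs(I_e)), abs(rhs[0]), abs(rhs[1]))
        inside = in_domain((I_e, R_e), params, slack=domain_slack) and I_e > -domain_slack
        equilibria.append(Equilibrium(I_e, R_e, residual, inside, mult))

    R0 = params.R0
    if abs(R0 - 1.0) <= threshold_rtol:
        regime = "threshold"
    elif R0 < 1.0:
        regime = "unique_endemic"
    else:
        regime = "one_or_two_endemic"

    if regime == "unique_endemic":
        lower = (params.pA - params.k) / (params.d + params.m)
        for e in equilibria:
            if e.in_domain and not (lower < e.I < params.N0):
                raise RuntimeError(
                    f"in-domain equilibrium I={e.I} escapes the expected bracket "
                    f"({lower}, {params.N0}) despite R0 < 1"
                )

    return ExistenceReport(
        R0=R0,
        regime=regime,
        equilibria=tuple(equilibria),
        vieta_residuals=vieta_check(coeffs, tuple(roots)),
        roots=tuple(roots),
    )
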