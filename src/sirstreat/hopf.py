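"""Hopf-bifurcation machinery for the rescaled planar system.

Implements the linearization entries of the rescaled system at an interior
equilibrium, the trace-zero Hopf condition, the quantities ``delta`` and
``omega``, the closed-form Lyapunov (focal) number ``sigma`` and an optional
symbolic normal-form cross-check of ``sigma``.

.. warning::

   The closed-form quantities reproduce the source analysis as printed.  At
   a trace-zero equilibrium the rescaled Jacobian determinant equals
   ``-delta``, so ``delta > 0`` (the printed side condition) actually means
   the equilibrium is a saddle with real eigenvalues ``+/- sqrt(delta)``;
   a genuine Hopf point requires the reverse inequality.  The report fields
   expose both facts so callers can draw their own conclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import Equilibrium
from .model_core import ModelParams, rhs_rescaled

__all__ = [
    "HopfReport",
    "linearization_entries",
    "hopf_condition",
    "lyapunov_sigma",
    "focal_value_crosscheck",
]


@dataclass(frozen=True)
class HopfReport:
    """Linearization entries and Hopf diagnostics at one equilibrium."""

    a11: float
    a12: float
    a21: float
    a22: float
    trace_residual: float
    delta: float
    omega: float
    sigma: float
    delta_condition: bool
    hopf_point: bool
    criticality: str  # subcritical | supercritical | degenerate

    @property
    def det(self) -> float:
        """Determinant of the rescaled linearization (equals -delta at trace zero)."""
        return self.a11 * self.a22 - self.a12 * self.a21

    def to_dict(self) -> dict:
        return {
            "a11": self.a11,
            "a12": self.a12,
            "a21": self.a21,
            "a22": self.a22,
            "trace_residual": self.trace_residual,
            "delta": self.delta,
            "omega": self.omega,
            "sigma": self.sigma,
            "delta_condition": self.delta_condition,
            "hopf_point": self.hopf_point,
            "criticality": self.criticality,
            "det": self.det,
        }


def _require_equilibrium(eq: Equilibrium, params: ModelParams, residual_tol: float) -> None:
    from .model_core import rhs_reduced

    rhs = rhs_reduced((eq.I, eq.R), params)
    if max(abs(rhs[0]), abs(rhs[1])) > residual_tol * max(1.0, params.pA):
        raise ValueError(
            f"({eq.I}, {eq.R}) is not an equilibrium: |rhs| = {max(map(abs, rhs)):.3e}"
        )


def linearization_entries(
    eq: Equilibrium,
    params: ModelParams,
    *,
    check_equilibrium: bool = True,
    residual_tol: float = 1e-6,
) -> tuple[float, float, float, float]:
    """Jacobian entries (a11, a12, a21, a22) of the rescaled system at ``eq``.

    The a21 entry uses the equilibrium balance ``m*I - (d+gamma)*R + k = 0``
    to drop a vanishing term, so the formulas are only the true Jacobian at
    a genuine equilibrium.
    """
    if check_equilibrium:
        _require_equilibrium(eq, params, residual_tol)
    I, R = eq.I, eq.R
    f = 1.0 + params.alpha * I * I
    a11 = (
        params.beta * (params.N0 - 2.0 * I - R)
        - (params.d + params.m) * (1.0 + 3.0 * params.alpha * I * I)
        - 2.0 * params.pA * params.alpha * (params.R0 - 1.0) * I
    )
    a12 = -params.beta * I
    a21 = params.m * f
    a22 = -(params.d + params.gamma) * f
    return a11, a12, a21, a22


def lyapunov_sigma(eq: "Equilibrium | float", params: ModelParams) -> float:
    """Closed-form Lyapunov (first focal) number at an interior equilibrium.

    ``sigma = (1/16) * (2*alpha*(d+gamma)/(beta*I*) - 6*alpha*(d+m))``,
    evaluated at the equilibrium I-coordinate.  Positive sigma is classified
    as subcritical (unstable surrounding cycle), negative as supercritical.

    ``eq`` may be an :class:`~sirstreat.equilibria.Equilibrium` or the bare
    I* coordinate.
    """
    I_star = eq.I if isinstance(eq, Equilibrium) else float(eq)
    if I_star <= 0:
        raise ValueError(f"sigma is undefined for I* <= 0, got {I_star!r}")
    return (
        2.0 * params.alpha * (params.d + params.gamma) / (params.beta * I_star)
        - 6.0 * params.alpha * (params.d + params.m)
    ) / 16.0


def hopf_condition(
    eq: Equilibrium,
    params: ModelParams,
    tol: float = 1e-3,
    *,
    sigma_tol: float = 1e-9,
) -> HopfReport:
    """Evaluate the trace-zero Hopf condition and assemble a full report.

    ``hopf_point`` is True iff the relative trace residual
    ``|a11 - (d+gamma)*(1+alpha*I*^2)| <= tol*(1+|a11|)`` holds together
    with the printed side condition ``(d+gamma)^2*(1+alpha*I*^2) > m*beta*I*``.
    ``delta = (d+gamma)^2*f^2 - m*beta*I**f`` and ``omega = sqrt(delta)``
    (NaN when delta <= 0).  Criticality follows the sign of the closed-form
    sigma, with ``|sigma| <= sigma_tol`` flagged degenerate.
    """
    a11, a12, a21, a22 = linearization_entries(eq, params)
    I = eq.I
    f = 1.0 + params.alpha * I * I
    dg = params.d + params.gamma
    trace_residual = abs(a11 - dg * f)  # == |a11 + a22|
    delta = dg * dg * f * f - params.m * params.beta * I * f
    omega = math.sqrt(delta) if delta > 0 else float("nan")
    delta_condition = dg * dg * f > params.m * params.beta * I
    hopf_point = trace_residual <= tol * (1.0 + abs(a11)) and delta_condition
    sigma = lyapunov_sigma(eq, params)
    if abs(sigma) <= sigma_tol:
        criticality = "degenerate"
    else:
        criticality = "subcritical" if sigma > 0 else "supercritical"
    return HopfReport(
        a11=a11,
        a12=a12,
        a21=a21,
        a22=a22,
        trace_residual=trace_residual,
        delta=delta,
        omega=omega,
        sigma=sigma,
        delta_condition=delta_condition,
        hopf_point=hopf_point,
        criticality=criticality,
    )


def focal_value_crosscheck(eq: Equilibrium, params: ModelParams) -> float:
    """Numerical-symbolic cross-check of ``sigma`` via the planar focal-value formula.

    Builds the (u, v) coordinates from the rescaled field by the shift
    ``x = I - I*``, ``y = R - R*``, the shear ``X = x``,
    ``Y = a11*x + a12*y`` and the scaling ``u = -X``, ``v = Y/sqrt(delta)``,
    then evaluates

    ``sigma_hat = (1/16) * [F1_uuu + F1_uvv + F2_uuv + F2_vvv
    + F1_uv*(F1_uu + F1_vv) - F2_uv*(F2_uu + F2_vv)
    - F1_uu*F2_uu + F1_vv*F2_vv]``

    with all partial derivatives taken symbolically (the rescaled field is
    polynomial, so this is exact).  Derivatives of order >= 2 are unaffected
    by the linear part, so no explicit subtraction of the rotation is
    needed.  This is a loose sanity oracle: at the bundled demo equilibrium
    it agrees with :func:`lyapunov_sigma` in sign but not magnitude.

    Raises ``ValueError`` when ``delta <= 0`` (the scaling is undefined).
    """
    import sympy as sp

    a11, a12, _a21, _a22 = linearization_entries(eq, params)
    I_star, R_star = eq.I, eq.R
    f = 1.0 + params.alpha * I_star * I_star
    dg = params.d + params.gamma
    delta = dg * dg * f * f - params.m * params.beta * I_star * f
    if delta <= 0:
        raise ValueError(f"normal-form scaling undefined for delta = {delta!r} <= 0")
    sqrt_delta = math.sqrt(delta)

    u, v = sp.symbols("u v", real=True)
    x = -u
    y = (v * sqrt_delta - a11 * x) / a12
    G1, G2 = rhs_rescaled((I_star + x, R_star + y), params)
    # u' = -x' = -G1 ; v' = Y'/sqrt(delta) = (a11*x' + a12*y')/sqrt(delta)
    F1 = sp.expand(-G1)
    F2 = sp.expand((a11 * G1 + a12 * G2) / sqrt_delta)

    def D(expr, *syms) -> float:
        return float(sp.diff(expr, *syms).subs({u: 0, v: 0}))

    sigma_hat = (
        D(F1, u, u, u)
        + D(F1, u, v, v)
        + D(F2, u, u, v)
        + D(F2, v, v, v)
        + D(F1, u, v) * (D(F1, u, u) + D(F1, v, v))
        - D(F2, u, v) * (D(F2, u, u) + D(F2, v, v))
        - D(F1, u, u) * D(F2, u, u)
        + D(F1, v, v) * D(F2, v, v)
    ) / 16.0
    return float(sigma_hat)


def linear_part_uv(eq: Equilibrium, params: ModelParams, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference linear part of the transformed (u, v) field.

    Diagnostic helper for inspecting what rotation (if any) the normal-form
    transformation actually produces at ``eq``; at a genuine trace-zero
    focus this is the rotation by ``omega = sqrt(-det)`` of the shifted
    system, while a saddle yields a symmetric hyperbolic block.
    """
    a11, a12, _, _ = linearization_entries(eq, params, check_equilibrium=False)
    f = 1.0 + params.alpha * eq.I * eq.I
    dg = params.d + params.gamma
    delta = dg * dg * f * f - params.m * params.beta * eq.I * f
    if delta <= 0:
        raise ValueError(f"normal-form scaling undefined for delta = {delta!r} <= 0")
    sqrt_delta = math.sqrt(delta)

    def field(u: float, v: float) -> np.ndarray:
        x = -u
        y = (v * sqrt_delta - a11 * x) / a12
        g1, g2 = rhs_rescaled((eq.I + x, eq.R + y), params)
        return np.array([-g1, (a11 * g1 + a12 * g2) / sqrt_delta])

    J = np.zeros((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = eps
        J[:, j] = (field(*step) - field(*(-step))) / (2.0 * eps)
    return J
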