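"""Local and global stability of equilibria of the reduced system.

Local classification uses the closed-form Jacobian at an equilibrium; global
stability for ``R0 < 1`` is certified (on a sampling grid) through the Dulac
multiplier ``D(I, R) = (1 + alpha*I**2)/I``, whose multiplied divergence is
a function of I alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .equilibria import Equilibrium, find_equilibria
from .model_core import ModelParams, rhs_reduced

__all__ = [
    "StabilityReport",
    "jacobian_reduced",
    "classify_local",
    "dulac_divergence",
    "global_stability_verdict",
]


@dataclass(frozen=True)
class StabilityReport:
    """Local classification plus the grid-sampled Dulac verdict."""

    jacobian: tuple[tuple[float, float], tuple[float, float]]
    trace: float
    det: float
    discriminant: float
    local_class: str
    dulac_max: float
    globally_stable: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "jacobian": [list(row) for row in self.jacobian],
            "trace": self.trace,
            "det": self.det,
            "discriminant": self.discriminant,
            "local_class": self.local_class,
            "dulac_max": self.dulac_max,
            "globally_stable": self.globally_stable,
            "reason": self.reason,
        }


def jacobian_reduced(
    eq: Equilibrium,
    params: ModelParams,
    *,
    check_equilibrium: bool = True,
    residual_tol: float = 1e-6,
) -> np.ndarray:
    """Closed-form Jacobian of the reduced system at an equilibrium.

    The entries are::

        J11 = pA*(R0-1)/I_e - beta*I_e/f - 2*alpha*beta*I_e^2*(N0-I_e-R_e)/f^2
        J12 = -beta*I_e/f
        J21 = m
        J22 = -(d+gamma)

    with ``f = 1 + alpha*I_e**2``.  J11 uses the equilibrium balance to fold
    the incidence term into ``pA*(R0-1)/I_e``; the expression agrees with a
    finite-difference Jacobian of :func:`~sirstreat.model_core.rhs_reduced`
    only when the input is a genuine equilibrium, hence the residual check.
    """
    I_e, R_e = eq.I, eq.R
    if check_equilibrium:
        rhs = rhs_reduced((I_e, R_e), params)
        scale = residual_tol * max(1.0, params.pA)
        if max(abs(rhs[0]), abs(rhs[1])) > scale:
            raise ValueError(
                f"({I_e}, {R_e}) is not an equilibrium: |rhs| = {max(map(abs, rhs)):.3e}"
            )
    f = 1.0 + params.alpha * I_e * I_e
    j11 = (
        params.pA * (params.R0 - 1.0) / I_e
        - params.beta * I_e / f
        - 2.0 * params.alpha * params.beta * I_e * I_e * (params.N0 - I_e - R_e) / f**2
    )
    j12 = -params.beta * I_e / f
    return np.array([[j11, j12], [params.m, -(params.d + params.gamma)]])


def classify_local(jacobian: Iterable[Iterable[float]], *, tol_scale: float = 1e-7) -> str:
    """Standard planar trace/determinant classification.

    Returns one of ``stable_node``, ``stable_focus``, ``unstable_node``,
    ``unstable_focus``, ``saddle`` or ``nonhyperbolic``.  The equilibrium is
    flagged nonhyperbolic when ``|det|`` is below tolerance or when
    ``det > 0`` and ``|trace|`` is below tolerance (purely imaginary pair).
    """
    J = np.asarray(jacobian, dtype=float)
    if J.shape != (2, 2) or not np.all(np.isfinite(J)):
        raise ValueError("expected a finite 2x2 Jacobian")
    trace = float(J[0, 0] + J[1, 1])
    det = float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
    tol = tol_scale * (1.0 + abs(det))
    if abs(det) <= tol:
        return "nonhyperbolic"
    if det < 0:
        return "saddle"
    if abs(trace) <= tol:
        return "nonhyperbolic"
    discriminant = trace * trace - 4.0 * det
    if trace < 0:
        return "stable_focus" if discriminant < 0 else "stable_node"
    return "unstable_focus" if discriminant < 0 else "unstable_node"


def dulac_divergence(state: Iterable[float], params: ModelParams) -> float:
    """Divergence of the Dulac-multiplied reduced field at a point of D.

    With the multiplier ``D = (1 + alpha*I**2)/I`` the divergence collapses
    to a function of I alone::

        -beta - 2*alpha*(d+m)*I - pA*(1-R0)/I**2 + alpha*pA*(1-R0)
        - (d+gamma)/I - alpha*I*(d+gamma)

    Raises ``ValueError`` for ``I <= 0`` (outside D).
    """
    I, _R = state
    if I <= 0:
        raise ValueError(f"Dulac divergence requires I > 0, got I={I!r}")
    surplus = params.pA * (1.0 - params.R0)  # = pA - k
    return (
        -params.beta
        - 2.0 * params.alpha * (params.d + params.m) * I
        - surplus / I**2
        + params.alpha * surplus
        - (params.d + params.gamma) / I
        - params.alpha * I * (params.d + params.gamma)
    )


def global_stability_verdict(
    params: ModelParams, grid_n: int = 50, *, boundary_frac: float = 1e-6
) -> StabilityReport:
    """Grid-certified global-stability verdict for the endemic equilibrium.

    Samples the Dulac divergence on a ``grid_n x grid_n`` log-spaced grid
    over D (I down to ``boundary_frac * N0``) and records the maximum.  The
    verdict is ``globally_stable = (R0 < 1) and (max < 0) and (E0 locally
    stable)``.  Sampling cannot prove negativity on all of D; the verdict is
    certified on the grid only.  For ``R0 >= 1`` the verdict is False with
    the reason recorded.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be at least 2")
    N0 = params.N0
    I_grid = np.geomspace(boundary_frac * N0, (1.0 - 1e-9) * N0, grid_n)
    # the divergence is independent of R; sweep R anyway to honour the
    # "sampled over D" contract (R strictly below the simplex boundary)
    div = np.full((grid_n, grid_n), np.nan)
    for i, I in enumerate(I_grid):
        R_grid = np.geomspace(boundary_frac * N0, (1.0 - 1e-9) * (N0 - I), grid_n)
        for j, R in enumerate(R_grid):
            div[i, j] = dulac_divergence((I, R), params)
    dulac_max = float(np.nanmax(div))

    report = find_equilibria(params)
    inside = report.in_domain_equilibria
    target: Optional[Equilibrium] = inside[0] if inside else None
    if target is not None:
        J = jacobian_reduced(target, params, check_equilibrium=False)
        trace = float(np.trace(J))
        det = float(np.linalg.det(J))
        local_class = classify_local(J)
        jac = ((float(J[0, 0]), float(J[0, 1])), (float(J[1, 0]), float(J[1, 1])))
    else:
        trace = det = float("nan")
        local_class = "none"
        jac = ((float("nan"),) * 2,) * 2

    if params.R0 >= 1.0:
        verdict, reason = False, f"R0 = {params.R0:.6g} >= 1: hypothesis fails"
    elif target is None:
        verdict, reason = False, "no in-domain equilibrium found"
    elif dulac_max >= 0.0:
        verdict, reason = False, f"Dulac divergence reaches {dulac_max:.3g} >= 0 on grid"
    elif local_class not in ("stable_node", "stable_focus"):
        verdict, reason = False, f"E0 locally classified as {local_class}"
    else:
        verdict, reason = True, "certified on grid"

    return StabilityReport(
        jacobian=jac,
        trace=trace,
        det=det,
        discriminant=trace * trace - 4.0 * det,
        local_class=local_class,
        dulac_max=dulac_max,
        globally_stable=verdict,
        reason=reason,
    )
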