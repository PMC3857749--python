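"""ODE integration, invariance checks, and Poincaré-section cycle detection.

All three system variants are integrated with an adaptive high-order
Runge-Kutta scheme (DOP853) at tight default tolerances.  Unstable periodic
orbits are located by integrating the rescaled planar field *backward* in
time (an unstable cycle is attracting in reversed time) and watching
successive crossings of a Poincaré section converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium
from .model_core import ModelParams, rhs_full, rhs_reduced, rhs_rescaled

__all__ = [
    "Trajectory",
    "CycleReport",
    "IntegrationError",
    "integrate",
    "find_unstable_cycle",
    "check_invariance",
    "winding_number",
]

_VARIANTS: dict[str, Callable] = {
    "full": rhs_full,
    "reduced": rhs_reduced,
    "rescaled": rhs_rescaled,
}


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails (e.g. step-size collapse)."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid time t={last_valid_time:.6g})")
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution of one system variant.

    ``states`` has one row per time point; columns are (I, R) for the planar
    variants and (S, I, R) for the full one.
    """

    times: np.ndarray
    states: np.ndarray
    variant: str
    direction: str
    rtol: float
    atol: float
    seed: Optional[int] = None

    @property
    def columns(self) -> tuple[str, ...]:
        return ("t", "S", "I", "R") if self.variant == "full" else ("t", "I", "R")

    def to_csv(self, path) -> None:
        """Write `t,I,R` (or `t,S,I,R`) rows at full precision."""
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter=",", header=",".join(self.columns), comments="", fmt="%.17g")


@dataclass(frozen=True)
class CycleReport:
    """Outcome of a Poincaré-section cycle search."""

    found: bool
    period: float
    section_point: tuple[float, float]
    amplitude_I: float
    return_map_residual: float
    enclosed_equilibrium: Optional[Equilibrium]
    winding_number: int = 0
    n_returns: int = 0
    diagnostic: str = ""
    return_residuals: tuple[float, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "period": self.period,
            "section_point": list(self.section_point),
            "amplitude_I": self.amplitude_I,
            "return_map_residual": self.return_map_residual,
            "enclosed_equilibrium": (
                self.enclosed_equilibrium.to_dict() if self.enclosed_equilibrium else None
            ),
            "winding_number": self.winding_number,
            "n_returns": self.n_returns,
            "diagnostic": self.diagnostic,
        }


def _wrap_rhs(variant: str, params: ModelParams, direction: str) -> Callable:
    try:
        rhs = _VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(_VARIANTS)}")
    sign = {"forward": 1.0, "backward": -1.0}[direction]

    def fun(t, z):
        return np.multiply(sign, rhs(z, params))

    return fun


def integrate(
    variant: str,
    initial_state: Sequence[float],
    params: ModelParams,
    t_end: float,
    *,
    direction: str = "forward",
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_points: int = 1001,
    seed: Optional[int] = None,
) -> Trajectory:
    """Integrate one system variant over [0, t_end].

    ``direction='backward'`` integrates the time-reversed field (the
    returned times still run forward from 0 to ``t_end``).  Dense output is
    sampled on ``t_eval`` or a uniform grid of ``n_points``.

    Raises :class:`IntegrationError` if the adaptive solver fails.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    expected_dim = 3 if variant == "full" else 2
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (expected_dim,):
        raise ValueError(f"variant {variant!r} expects a state of length {expected_dim}")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        _wrap_rhs(variant, params, direction),
        (0.0, float(t_end)),
        y0,
        method="DOP853",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", last)
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        variant=variant,
        direction=direction,
        rtol=rtol,
        atol=atol,
        seed=seed,
    )


def winding_number(states: np.ndarray, point: Iterable[float]) -> int:
    """Winding number of a closed planar curve around ``point``.

    ``states`` is an (n, 2) array tracing the curve; the total wrapped angle
    swept around ``point`` is rounded to the nearest integer multiple of
    2*pi.
    """
    P = np.asarray(states, dtype=float)
    px, py = point
    angles = np.arctan2(P[:, 1] - py, P[:, 0] - px)
    increments = np.diff(angles)
    increments = (increments + np.pi) % (2.0 * np.pi) - np.pi
    return int(round(increments.sum() / (2.0 * np.pi)))


def find_unstable_cycle(
    params: ModelParams,
    eq: Equilibrium,
    *,
    displacement: tuple[float, float] = (1e-2, 0.0),
    residual_tol: float = 1e-7,
    max_returns: int = 200,
    max_time: float = 1e5,
    chunk_time: float = 400.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> CycleReport:
    """Search for an unstable periodic orbit around ``eq`` by backward integration.

    The rescaled planar field is integrated in reversed time from
    ``eq + displacement``; an unstable cycle, being repelling forward, is
    attracting backward.  Crossings of the Poincaré section ``{R = R_e}``
    are counted in a single direction, and convergence is declared when the
    I-coordinates of successive crossings differ by less than
    ``residual_tol``; the period is then the time between those crossings.

    Leaving the domain D or exhausting ``max_returns`` yields
    ``found=False`` with a diagnostic rather than an exception.
    """
    I_e, R_e = eq.I, eq.R
    N0 = params.N0

    def fun(t, z):
        dI, dR = rhs_rescaled(z, params)
        return (-dI, -dR)

    def section(t, z):
        return z[1] - R_e

    section.direction = 1.0  # one-directional crossings only

    def leaves_domain(t, z):
        return min(z[0], z[1], N0 - z[0] - z[1])

    leaves_domain.terminal = True
    leaves_domain.direction = -1.0

    def blows_up(t, z):
        return abs(z[0]) + abs(z[1]) - 100.0 * N0

    blows_up.terminal = True
    blows_up.direction = 1.0

    y = np.array([I_e + displacement[0], R_e + displacement[1]])
    crossings_I: list[float] = []
    crossings_t: list[float] = []
    residuals: list[float] = []
    t_offset = 0.0
    diagnostic = ""

    while len(crossings_I) <= max_returns:
        sol = solve_ivp(
            fun,
            (0.0, chunk_time),
            y,
            method="DOP853",
            events=(section, leaves_domain, blows_up),
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        for t_ev, z_ev in zip(sol.t_events[0], sol.y_events[0]):
            crossings_I.append(float(z_ev[0]))
            crossings_t.append(t_offset + float(t_ev))
            if len(crossings_I) >= 2:
                residuals.append(abs(crossings_I[-1] - crossings_I[-2]))
        if len(residuals) > 0 and residuals[-1] < residual_tol:
            break
        if sol.t_events[1].size or sol.t_events[2].size:
            diagnostic = (
                "trajectory left domain D during backward integration"
                if sol.t_events[1].size
                else "trajectory diverged during backward integration"
            )
            break
        if sol.status == -1:
            diagnostic = f"integration failed: {sol.message}"
            break
        if len(crossings_I) > max_returns:
            diagnostic = f"no convergence after {max_returns} section returns"
            break
        y = sol.y[:, -1]
        t_offset += chunk_time
        if t_offset >= max_time:
            diagnostic = f"no convergence within backward time budget t={max_time:g}"
            break

    converged = bool(residuals) and residuals[-1] < residual_tol
    if not converged:
        if not diagnostic:
            diagnostic = f"no convergence after {len(crossings_I)} section returns"
        return CycleReport(
            found=False,
            period=float("nan"),
            section_point=(float("nan"), float("nan")),
            amplitude_I=float("nan"),
            return_map_residual=residuals[-1] if residuals else float("nan"),
            enclosed_equilibrium=eq,
            n_returns=len(crossings_I),
            diagnostic=diagnostic,
            return_residuals=tuple(residuals),
        )

    period = crossings_t[-1] - crossings_t[-2]
    section_point = (crossings_I[-1], R_e)
    # one clean revolution from the converged section point, densely sampled
    orbit = integrate(
        "rescaled",
        section_point,
        params,
        period,
        direction="backward",
        rtol=rtol,
        atol=atol,
        n_points=2001,
    )
    amplitude = float(orbit.states[:, 0].max() - orbit.states[:, 0].min())
    wind = winding_number(orbit.states, (I_e, R_e))
    return CycleReport(
        found=True,
        period=float(period),
        section_point=section_point,
        amplitude_I=amplitude,
        return_map_residual=residuals[-1],
        enclosed_equilibrium=eq,
        winding_number=abs(wind),
        n_returns=len(crossings_I),
        diagnostic="converged",
        return_residuals=tuple(residuals),
    )


def check_invariance(
    params: ModelParams,
    n_starts: int = 20,
    t_end: float = 500.0,
    seed: int = 20131121,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> bool:
    """Empirical forward-invariance check of the domain D.

    Integrates ``n_starts`` seeded uniform starts in D forward to ``t_end``
    and returns True iff every sampled state satisfies ``I > -eps``,
    ``R > -eps`` and ``I + R < N0 + eps`` with ``eps = 1e-8 * N0``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    rng = np.random.default_rng(seed)
    N0 = params.N0
    eps = 1e-8 * N0
    for _ in range(n_starts):
        while True:
            I0, R0_ = rng.uniform(0.0, N0, size=2)
            if I0 > 0 and R0_ > 0 and I0 + R0_ < N0:
                break
        try:
            traj = integrate(
                "reduced", (I0, R0_), params, t_end, rtol=rtol, atol=atol, n_points=2001, seed=seed
            )
        except IntegrationError:
            # the field is only meaningful inside D; a blow-up means the
            # orbit escaped, which certainly violates invariance
            return False
        I, R = traj.states[:, 0], traj.states[:, 1]
        if (I < -eps).any() or (R < -eps).any() or (I + R > N0 + eps).any():
            return False
    return True


def reject_outside_domain(state: Sequence[float], params: ModelParams) -> None:
    """Validate that an (I, R) initial condition lies in D; raise otherwise."""
    I, R = state
    if not (I > 0 and R > 0 and I + R < params.N0):
        raise ValueError(
            f"initial state ({I}, {R}) lies outside the domain D "
            f"(requires I > 0, R > 0, I + R < {params.N0})"
        )
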