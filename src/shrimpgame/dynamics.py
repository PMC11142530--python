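"""Independent verification of the closed-form equilibria by simulation.

The equilibrium controls are constants, so the reputation state under play
has the exact solution

    x(t) = x0 e^{-delta t} + (g G / delta) (1 - e^{-delta t}),

relaxing monotonically to the steady state g G / delta.  The discounted
payoff of a constant control can therefore be computed three independent
ways — closed form, adaptive quadrature of the integrand, and quadrature
over a numerically integrated trajectory — and the agreement of all three
with the HJB value function is the package's core correctness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp

from .equilibrium import Variant, equilibrium_control, equilibrium_value, shadow_price
from .model import CanonicalProblem

__all__ = [
    "Trajectory",
    "reputation_trajectory",
    "reputation_trajectory_ode",
    "trajectory",
    "steady_state",
    "discounted_payoff",
    "constant_control_value",
    "optimality_gap",
    "HorizonError",
]


class HorizonError(ValueError):
    """The requested horizon cannot deliver the requested tolerance."""

    def __init__(self, horizon: float, required: float, tol: float):
        self.horizon = horizon
        self.required = required
        self.tol = tol
        super().__init__(
            f"horizon {horizon:g} too short for tol {tol:g}; need >= {required:g}"
        )


@dataclass(frozen=True)
class Trajectory:
    """A reputation path sampled on a time grid."""

    times: np.ndarray
    states: np.ndarray

    def to_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.states.tolist()))


def reputation_trajectory(problem: CanonicalProblem, G: float, t):
    """Exact reputation x(t) under the constant control G.

    Accepts scalar or array ``t`` (all entries >= 0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be nonnegative")
    xbar = steady_state(problem, G)
    decay = np.exp(-problem.delta * t_arr)
    out = problem.x0 * decay + xbar * (1.0 - decay)
    return out if out.ndim else float(out)


def reputation_trajectory_ode(problem: CanonicalProblem, G: float, times) -> np.ndarray:
    """Reputation path by numerical ODE integration (cross-check of the
    closed form), solving dx/dt = g G - delta x with tight tolerances."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0.0):
        raise ValueError("time must be nonnegative")
    sol = solve_ivp(
        lambda _t, x: problem.g * G - problem.delta * x,
        (0.0, float(times.max()) if times.size else 0.0),
        [problem.x0],
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
        method="RK45",
    )
    return sol.y[0]


def trajectory(problem: CanonicalProblem, G: float, t_max: float, n: int = 1001) -> Trajectory:
    """Sample the exact reputation path on a uniform grid over [0, t_max]."""
    times = np.linspace(0.0, t_max, n)
    return Trajectory(times=times, states=np.asarray(reputation_trajectory(problem, G, times)))


def steady_state(problem: CanonicalProblem, G: float) -> float:
    """Long-run reputation g G / delta under the constant control G."""
    return problem.g * G / problem.delta


def _required_horizon(problem: CanonicalProblem, G: float, tol: float) -> float:
    """Horizon T with discounted-tail bound e^{-rho T}(|u0| + l x_max)/rho
    below tol/2, where u0 is the constant part of the flow payoff."""
    p = problem
    u0 = abs(p.a * G - 0.5 * p.c * G * G)
    x_max = max(abs(p.x0), abs(steady_state(p, G)))
    bound = u0 + p.l * x_max
    if bound == 0.0:
        return 1.0
    return max(1.0, math.log(2.0 * bound / (p.rho * tol)) / p.rho)


def discounted_payoff(
    problem: CanonicalProblem,
    G: float,
    horizon: float | None = None,
    tol: float = 1e-6,
) -> float:
    """Discounted payoff of playing the constant control G, by quadrature.

    Integrates e^{-rho t} [a G - (c/2) G^2 + l x(t)] over [0, horizon] with
    adaptive quadrature and adds the exact tail of the constant part; the
    reputation tail is controlled by the horizon choice.  When ``horizon``
    is omitted it is computed from the truncation bound so the absolute
    error stays below ``tol``.

    Raises
    ------
    HorizonError
        If an explicit horizon is too short for the tolerance (the message
        reports the required horizon).
    """
    p = problem
    if p.rho <= 0.0:
        raise ValueError("rho must be > 0")
    required = _required_horizon(p, G, tol)
    if horizon is None:
        horizon = required
    elif horizon < required:
        raise HorizonError(horizon, required, tol)

    u0 = p.a * G - 0.5 * p.c * G * G

    def integrand(t: float) -> float:
        x = reputation_trajectory(p, G, t)
        return math.exp(-p.rho * t) * (u0 + p.l * x)

    head, _ = quad(integrand, 0.0, horizon, epsabs=tol / 2.0, epsrel=1e-12, limit=400)
    tail_const = math.exp(-p.rho * horizon) * u0 / p.rho
    return head + tail_const


def constant_control_value(problem: CanonicalProblem, G: float) -> float:
    """Exact discounted payoff of the constant control G:

        alpha x0 + (1/rho) [a G - (c/2) G^2 + alpha g G],

    with alpha = l / (rho + delta).  This is the closed form the quadrature
    of :func:`discounted_payoff` verifies.
    """
    p = problem
    alpha = shadow_price(p.l, p.rho, p.delta)
    return alpha * p.x0 + (p.a * G - 0.5 * p.c * G * G + alpha * p.g * G) / p.rho


def optimality_gap(problem: CanonicalProblem, G: float) -> float:
    """Value lost by playing G instead of the derived optimum G*.

    Both payoffs are evaluated in closed form, so the gap is exactly the
    parabola c (G - G*)^2 / (2 rho): nonnegative everywhere and zero at the
    derived optimum.
    """
    eq = equilibrium_value(problem, Variant.DERIVED)
    return eq.value(problem.x0) - constant_control_value(problem, G)
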