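"""Closed-form HJB equilibria of the canonical linear-state problem.

Because the reputation stock enters the running payoff linearly and the
dynamics are linear, the value function of the canonical problem

    rho V(x) = max_G [ a G - (c/2) G^2 + l x + V'(x) (g G - delta x) ]

is exactly linear, V(x) = alpha x + beta, with the shadow price of
reputation

    alpha = l / (rho + delta)

independent of everything but discounting and decay.  The maximizing
control is then the constant

    G* = (a + alpha g) / c,

and the intercept follows from the HJB identity:
beta = (a + alpha g)^2 / (2 rho c).

Two solver variants are provided.  ``DERIVED`` is the internally consistent
first-order-condition solution above.  ``AS_PRINTED_B1`` reproduces the
published closed form for the (B, 1) subproblem, whose control
G* = (a + alpha) / c drops the reputation-gain factor from the shadow-price
term; its value is then the discounted payoff of playing that constant
control.  The two variants coincide on every other subproblem.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import CanonicalProblem, Mode, Player

__all__ = [
    "Variant",
    "Equilibrium",
    "shadow_price",
    "equilibrium_control",
    "equilibrium_value",
    "hjb_residual",
    "foc_residual",
]


class Variant(str, enum.Enum):
    """Solver variant: internally consistent vs published (B, 1) form."""

    DERIVED = "derived"
    AS_PRINTED_B1 = "as_printed_B1"


@dataclass(frozen=True)
class Equilibrium:
    """Equilibrium of one canonical subproblem.

    ``alpha`` is the shadow price of reputation, ``G_star`` the constant
    feedback control, and the value function is
    ``V(x0) = v_slope * x0 + v_intercept`` with ``v_slope == alpha``.
    ``control_nonpositive`` flags G* <= 0 (the model assumes interior
    positive effort; the closed forms remain valid either way).
    """

    alpha: float
    G_star: float
    v_slope: float
    v_intercept: float
    variant: Variant = Variant.DERIVED
    control_nonpositive: bool = False

    def value(self, x0: float) -> float:
        return self.v_slope * x0 + self.v_intercept


def shadow_price(l: float, rho: float, delta: float) -> float:
    """Shadow price of reputation, alpha = l / (rho + delta).

    Strictly decreasing in both the discount rate and the decay rate and
    linear in the reputation weight ``l``; zero when reputation is
    worthless.
    """
    if rho + delta <= 0.0:
        raise ValueError(f"rho + delta must be > 0, got {rho + delta}")
    if l < 0.0:
        raise ValueError(f"l must be >= 0, got {l}")
    return l / (rho + delta)


def _is_printed_case(problem: CanonicalProblem, variant: Variant) -> bool:
    return (
        Variant(variant) == Variant.AS_PRINTED_B1
        and problem.label == (Mode.NATURAL_ENEMY, Player.US)
    )


def equilibrium_control(problem: CanonicalProblem, variant: Variant = Variant.DERIVED) -> float:
    """Equilibrium control level G* of a canonical subproblem.

    ``DERIVED``: G* = (a + alpha g) / c, the first-order condition of the
    HJB maximization.  ``AS_PRINTED_B1``: for the (B, 1) subproblem only,
    the published form G* = (a + alpha) / c; identical to ``DERIVED``
    elsewhere.
    """
    alpha = shadow_price(problem.l, problem.rho, problem.delta)
    if _is_printed_case(problem, variant):
        return (problem.a + alpha) / problem.c
    return (problem.a + alpha * problem.g) / problem.c


def equilibrium_value(problem: CanonicalProblem, variant: Variant = Variant.DERIVED) -> Equilibrium:
    """Solve a canonical subproblem in closed form.

    For the derived variant the intercept is (a + alpha g)^2 / (2 rho c).
    For the as-printed (B, 1) variant the intercept is the discounted
    payoff of the constant printed control,
    (1/rho) [a G - (c/2) G^2 + alpha g G] with G = (a + alpha) / c.
    """
    p = problem
    alpha = shadow_price(p.l, p.rho, p.delta)
    variant = Variant(variant)
    G = equilibrium_control(p, variant)
    if _is_printed_case(p, variant):
        intercept = (p.a * G - 0.5 * p.c * G * G + alpha * p.g * G) / p.rho
    else:
        intercept = (p.a + alpha * p.g) ** 2 / (2.0 * p.rho * p.c)
    return Equilibrium(
        alpha=alpha,
        G_star=G,
        v_slope=alpha,
        v_intercept=intercept,
        variant=variant,
        control_nonpositive=G <= 0.0,
    )


def hjb_residual(problem: CanonicalProblem, eq: Equilibrium, x: float) -> float:
    """HJB residual of a candidate linear value/control pair at state x.

    Returns rho V(x) - [a G - (c/2) G^2 + l x + V'(x) (g G - delta x)]
    with V(x) = v_slope x + v_intercept and G = G_star.  Identically zero
    (to rounding) for any equilibrium whose value is the true discounted
    payoff of its constant control — including the as-printed variant,
    which satisfies the un-maximized HJB even though its control fails the
    first-order condition (see :func:`foc_residual`).
    """
    p = problem
    G = eq.G_star
    V = eq.v_slope * x + eq.v_intercept
    flow = p.a * G - 0.5 * p.c * G * G + p.l * x
    drift = eq.v_slope * (p.g * G - p.delta * x)
    return p.rho * V - (flow + drift)


def foc_residual(problem: CanonicalProblem, G: float) -> float:
    """First-order-condition residual a + alpha g - c G.

    Zero iff G is the derived optimum; positive marginal value of effort
    when positive.  A diagnostic for quantifying how far a candidate
    control (e.g. the published (B, 1) form) sits from the optimum.
    """
    alpha = shadow_price(problem.l, problem.rho, problem.delta)
    return problem.a + alpha * problem.g - problem.c * G
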