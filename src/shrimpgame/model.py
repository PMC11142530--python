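"""Parameter space and canonical reduction for the shrimp-control games.

Two governments — the United States (player 1) and a cooperative country
(player 2) — each choose a control effort against an invasive black tiger
shrimp population under one of three management modes:

* ``B`` — introduce a natural enemy of the shrimp,
* ``M`` — catch the shrimp and manufacture feed,
* ``E`` — catch the shrimp and sell it as food ("bring to the table").

Each (mode, player) pairing is an independent infinite-horizon optimal
control problem with a single state, the player's reputation ``x`` for
controlling the invasion, which accumulates with effort and decays at rate
``delta`` (Nerlove–Arrow goodwill dynamics).  Because reputation enters the
running payoff linearly, every subproblem reduces to the same *canonical*
linear-state problem

    max_G  integral_0^inf  e^{-rho t} [ a G - (c/2) G^2 + l x ] dt
    s.t.   dx/dt = g G - delta x,   x(0) = x0,

fully described by the triple ``(a, c, g)`` plus the shared discounting and
reputation parameters.  This module defines the validated parameter set and
the reduction table that maps every (mode, player) pair to its canonical
problem.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "Mode",
    "Player",
    "GameParameters",
    "CanonicalProblem",
    "ParameterError",
    "validate_parameters",
    "canonical_reduction",
    "load_parameters",
    "save_parameters",
    "BASELINE",
    "PARAMETER_FIELDS",
]


class Mode(str, enum.Enum):
    """The three management modes."""

    NATURAL_ENEMY = "B"
    FEED = "M"
    TABLE = "E"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Player(enum.IntEnum):
    """Game players: the United States (1) and the cooperative country (2)."""

    US = 1
    PARTNER = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.value)


class ParameterError(ValueError):
    """A parameter set violates an admissibility constraint.

    ``field`` names the first offending parameter, so callers (CLI, config
    loaders) can point at the bad entry.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class GameParameters:
    """A complete, admissible scenario: every model parameter plus the
    initial reputations.  The single source of truth for one analysis run.

    Units are abstract "utility" per unit of control effort (a unit of
    shrimp removed per unit time); reputation has its own abstract unit.
    """

    rho: float  # discount rate, 0 < rho <= 1
    delta: float  # reputation decay rate, > 0
    b1: float  # US ecological revenue per unit control
    b2: float  # partner ecological revenue per unit control
    c1: float  # US control cost coefficient (quadratic)
    c2: float  # partner control cost coefficient (quadratic)
    l: float  # utility weight on reputation stock
    c_B: float  # ecological cost of natural-enemy reduction (mode B, partner)
    h_B: float  # natural-enemy reproduction rate (mode B)
    f1: float  # US reputation gain per unit control
    f2: float  # partner reputation gain per unit control
    f_B: float  # reputation loss per unit natural-enemy reduction (mode B)
    c_M1: float  # US feed production cost coefficient
    c_M2: float  # partner feed production cost coefficient
    q_M1: float  # US feed price
    q_M2: float  # partner feed price
    c_T: float  # shrimp transportation cost coefficient (mode E, partner)
    f_E: float  # eating-satisfaction reputation coefficient (mode E, partner)
    q_E1: float  # US direct-sale shrimp price
    q_E2: float  # partner direct-sale shrimp price
    x0_1: float  # US initial reputation
    x0_2: float  # partner initial reputation

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given fields changed and re-validated."""
        return validate_parameters(dataclasses.asdict(dataclasses.replace(self, **changes)))

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def x0(self, player: Player) -> float:
        return self.x0_1 if Player(player) == Player.US else self.x0_2


PARAMETER_FIELDS: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(GameParameters))

# Strictly positive: revenues, costs, prices, and the reputation weight.
_POSITIVE = (
    "delta", "b1", "b2", "c1", "c2", "l", "c_B",
    "c_M1", "c_M2", "q_M1", "q_M2", "c_T", "q_E1", "q_E2",
)
# Nonnegative: reputation-gain coefficients and the enemy reproduction rate
# (zero is a meaningful boundary — effort that builds no reputation).
_NONNEGATIVE = ("h_B", "f1", "f2", "f_B", "f_E", "x0_1", "x0_2")


def validate_parameters(raw: Mapping[str, Any] | GameParameters) -> GameParameters:
    """Validate a candidate parameter set and return it as ``GameParameters``.

    Checks run in declaration order and the first violated constraint is
    reported by field name.  Unknown keys and missing fields are errors.

    Raises
    ------
    ParameterError
        Naming the first missing, unknown, or out-of-range field.
    """
    if isinstance(raw, GameParameters):
        mapping: Mapping[str, Any] = raw.to_dict()
    else:
        mapping = raw

    unknown = set(mapping) - set(PARAMETER_FIELDS)
    if unknown:
        name = sorted(unknown)[0]
        raise ParameterError(name, "unknown parameter")
    for name in PARAMETER_FIELDS:
        if name not in mapping:
            raise ParameterError(name, "missing parameter")

    values = {name: float(mapping[name]) for name in PARAMETER_FIELDS}
    for name, value in values.items():
        if not math.isfinite(value):
            raise ParameterError(name, "must be finite")

    rho = values["rho"]
    if not (0.0 < rho <= 1.0):
        raise ParameterError("rho", f"must satisfy 0 < rho <= 1, got {rho}")
    for name in _POSITIVE:
        if values[name] <= 0.0:
            raise ParameterError(name, f"must be > 0, got {values[name]}")
    for name in _NONNEGATIVE:
        if values[name] < 0.0:
            raise ParameterError(name, f"must be >= 0, got {values[name]}")

    return GameParameters(**values)


@dataclass(frozen=True)
class CanonicalProblem:
    """One (mode, player) subproblem in canonical linear-state form.

    ``a`` is the effective marginal benefit of control, ``c`` the effective
    quadratic cost coefficient, ``g`` the effective reputation gain per unit
    of control.  ``g`` may be negative only for the partner under mode B,
    where the reputational cost of depleting the natural enemy (``f_B``) can
    exceed the gain from controlling the shrimp (``f2``).
    """

    a: float
    c: float
    g: float
    rho: float
    delta: float
    l: float
    x0: float
    # identity of the subproblem this reduction came from, if any; the
    # as-printed solver variant keys off (B, 1).
    label: tuple[Mode, Player] | None = None

    def __post_init__(self) -> None:
        if self.c <= 0.0:
            raise ParameterError("c", f"quadratic cost must be > 0, got {self.c}")
        if self.rho <= 0.0:
            raise ParameterError("rho", f"must be > 0, got {self.rho}")
        if self.delta <= 0.0:
            raise ParameterError("delta", f"must be > 0, got {self.delta}")


def canonical_reduction(params: GameParameters, mode: Mode, player: Player) -> CanonicalProblem:
    """Reduce a (mode, player) subproblem to its canonical ``(a, c, g)`` form.

    The reduction table (linear-in-G revenue terms are folded into ``a``;
    quadratic cost terms into ``c``; reputation-dynamics coefficients into
    ``g``):

    ========  =======================  ============  ===========
    subcase   a                        c             g
    ========  =======================  ============  ===========
    (B, 1)    b1                       c1            f1
    (B, 2)    b2 * (1 + ln(1 + h_B))   c2 + c_B      f2 - f_B
    (M, 1)    b1 + q_M1                c1 + c_M1     f1
    (M, 2)    q_M2                     c_M2          f2
    (E, 1)    b1 + q_E1                c1            f1
    (E, 2)    q_E2                     c_T           f_E + f2
    ========  =======================  ============  ===========

    The log term for (B, 2) is the extra ecological benefit of the natural
    enemy breeding at rate ``h_B``; being linear in the control it belongs
    in ``a``.
    """
    mode = Mode(mode)
    player = Player(player)
    p = params
    if mode == Mode.NATURAL_ENEMY:
        if player == Player.US:
            a, c, g = p.b1, p.c1, p.f1
        else:
            a, c, g = p.b2 * (1.0 + math.log(1.0 + p.h_B)), p.c2 + p.c_B, p.f2 - p.f_B
    elif mode == Mode.FEED:
        if player == Player.US:
            a, c, g = p.b1 + p.q_M1, p.c1 + p.c_M1, p.f1
        else:
            a, c, g = p.q_M2, p.c_M2, p.f2
    else:  # Mode.TABLE
        if player == Player.US:
            a, c, g = p.b1 + p.q_E1, p.c1, p.f1
        else:
            a, c, g = p.q_E2, p.c_T, p.f_E + p.f2

    return CanonicalProblem(
        a=a, c=c, g=g, rho=p.rho, delta=p.delta, l=p.l,
        x0=p.x0(player), label=(mode, player),
    )


def load_parameters(path: str) -> GameParameters:
    """Read a flat key-value YAML config into validated ``GameParameters``.

    Keys must be exactly the parameter names (``rho``, ``delta``, ``b1``,
    ..., ``q_E2``, ``x0_1``, ``x0_2``); unknown keys are an error.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError("<config>", "config must be a flat key-value mapping")
    return validate_parameters(data)


def save_parameters(params: GameParameters, path: str) -> None:
    """Write a parameter set as a flat key-value YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


#: The numerical-analysis baseline scenario.  f1 = f2 = 1 and
#: q_E1 = q_E2 = 1 are package defaults (the value-polynomial analysis
#: treats f1/f2 as free variables and price scenarios {1, 4} are always
#: exposed explicitly); x0 = 1 for both players.
BASELINE = GameParameters(
    rho=0.9, delta=0.1,
    b1=5.0, b2=5.0, c1=2.5, c2=2.5, l=1.0,
    c_B=0.5, h_B=2.0, f1=1.0, f2=1.0, f_B=1.0,
    c_M1=2.0, c_M2=2.0, q_M1=3.0, q_M2=3.0,
    c_T=2.5, f_E=1.5, q_E1=1.0, q_E2=1.0,
    x0_1=1.0, x0_2=1.0,
)
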