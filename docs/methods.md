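# Methods

## Model

Two governments each solve an independent infinite-horizon optimal control
problem per management mode. There is no strategic coupling: each player's
payoff depends only on its own effort and its own reputation stock, so the
"game" decomposes into six single-agent problems, and the feedback
(Markovian) equilibrium of each is found by dynamic programming alone. The
only state is reputation, a goodwill stock in the Nerlove–Arrow tradition:

    dx/dt = g G - delta x,   x(0) = x0,

with G the control effort (shrimp-units removed per unit time), g the net
reputation gain per unit effort, and delta the decay of reputation absent
effort. Running welfare is a G-linear revenue minus a G-quadratic cost plus
a linear reputation dividend l·x, discounted at rate rho. Time and utility
units are abstract; no calibration to data exists or is attempted.

Because the state enters welfare linearly and the dynamics are linear, the
HJB value function is exactly linear in x (no quadratic-in-state ansatz is
needed — the linear form is the fixed point, not an approximation):

    V(x) = alpha x + beta,   alpha = l / (rho + delta),
    G* = (a + alpha g) / c,  beta = (a + alpha g)^2 / (2 rho c).

alpha is the shadow price of reputation; feedback controls degenerate to
constants.

### The canonical reduction

Every (mode, player) subproblem maps to a triple (a, c, g):

| subcase | a | c | g |
|---|---|---|---|
| B, US      | b1                     | c1        | f1        |
| B, partner | b2 (1 + ln(1 + h_B))   | c2 + c_B  | f2 − f_B  |
| M, US      | b1 + q_M1              | c1 + c_M1 | f1        |
| M, partner | q_M2                   | c_M2      | f2        |
| E, US      | b1 + q_E1              | c1        | f1        |
| E, partner | q_E2                   | c_T       | f_E + f2  |

The partner's mode-B log term is the natural enemy's breeding bonus; being
linear in G it belongs in `a`. `g < 0` is possible only for (B, partner),
when the reputational cost of depleting the natural enemy exceeds the gain
from controlling the shrimp; the closed forms remain valid and the package
flags (rather than rejects) the resulting non-positive controls.

### Solver variants

The published closed form for the US natural-enemy subproblem uses
G* = (a + alpha)/c — the reputation-gain factor f1 is absent from the
shadow-price term, unlike the symmetric subproblems — and the published
numerical value function (6.33 + 2.67 f1) is consistent only with that
form. Both are therefore first-class:

* `derived` — the internally consistent first-order-condition solution;
  default for research use.
* `as_printed_B1` — the published (B, US) control, its value computed as
  the true discounted payoff of playing that constant; default when
  reproducing the published numerical analysis. It satisfies the
  un-maximized HJB identity but misses the first-order condition by
  exactly −1 utility/unit at the baseline with f1 = 0, and costs
  c(0.4)²/(2 rho) ≈ 0.222 of value there.

Whether the missing f1 is a typesetting loss or a modelling choice cannot
be decided from the source; neither variant is asserted as "intended".

## Parameters

All parameters are positive utilities/rates; rho is restricted to (0, 1]
(rho = 0 makes the discounted integral divergent and is rejected; rho = 1
is admissible). The reputation-gain coefficients f1, f2, f_B, f_E and the
enemy reproduction rate h_B are allowed to be zero: the numerical analysis
evaluates value functions at f = 0 and zero is a meaningful boundary
(effort that builds no reputation), so the package validates these as
nonnegative rather than strictly positive.

The baseline scenario fixes rho = 0.9, delta = 0.1, b1 = b2 = 5,
c1 = c2 = 2.5, l = 1, c_B = 0.5, h_B = 2, f_B = 1, c_M1 = c_M2 = 2,
q_M1 = q_M2 = 3, c_T = 2.5, f_E = 1.5, with direct-sale prices q_E1, q_E2
compared across {1, 4}. Initial reputations x0 = 1 for both players are
inferred from the constant "1 +" leading every published squared-form value
function; they are package defaults, overridable in any config. The
baseline also needs concrete f1 = f2 = 1 (the published analysis treats
them as free plot variables and never fixes them); the value-polynomial
functions treat the own f as free, so this choice only affects point
evaluations.

## Verification strategy

Three independent routes must agree, and the property sweep
(`shrimpgame.scenarios.property_sweep`) checks them over seeded uniform
draws from the admissible region:

1. **HJB identity** — the residual of the closed-form value/control pair in
   the HJB equation, at x ∈ {0, 1, 10}; required ≤ 1e-9.
2. **Quadrature oracle** — the discounted payoff of the constant
   equilibrium control, integrated by adaptive quadrature over a horizon
   chosen from the exponential tail bound (plus the analytic tail of the
   constant part), must equal the closed-form value within 1e-6. Applied
   to both solver variants; for `as_printed_B1` this confirms the
   published value function is the payoff of the published control.
3. **ODE cross-check** — the exact state trajectory
   x(t) = x0 e^{−delta t} + (gG/delta)(1 − e^{−delta t}) against a
   high-accuracy Runge–Kutta integration, max deviation ≤ 1e-6 on [0, 50].

The optimality gap of a non-equilibrium control is evaluated in closed form
(both payoffs are exact for constant controls), making the identity
gap = c (G − G*)² / (2 rho) hold to machine precision; quadrature is
reserved for the oracle role above so the check is not circular.

Comparative statics are computed by centered finite differences with
relative step 1e-6 (the controls are smooth rational functions of every
parameter; the step is far above cancellation noise and far below
curvature error at these scales). The negative cost-coefficient signs
(dG*/dc_B, dG*/dc_M) are properties of interior equilibria —
dG*/dc = −(a + alpha g)/c² flips sign when G* < 0 — so the sweep asserts
them only where G* > 0; the baseline statics are unconditional.

## Scenario generator

Scenarios are drawn parameter-wise uniformly (no distributional claim is
made by the model) from default ranges: rho ∈ [0.05, 1] (the lower bound
keeps quadrature horizons short), delta ∈ [0.01, 1], costs, prices,
revenues and l ∈ [0.5, 5], f1, f2 ∈ [0, 5], h_B ∈ [0, 5], f_B ∈ [0, 2],
f_E ∈ [0, 3], x0 ∈ [0, 2]. Generation uses a dedicated seeded generator —
no global random state — and identical (n, seed, ranges) reproduce
identical batches. Under the default ranges roughly a third of draws give
the partner a net-negative mode-B reputation gain; these are flagged and
exercised, not discarded. What the generator emulates is the admissible
parameter space only; it does not emulate data of any kind, so passing
sweeps demonstrate internal mathematical consistency, not empirical
validity.

## Published-coefficient reproduction

The reproduction report compares every published value-polynomial
coefficient against the closed-form derivation after half-even rounding at
the printed precision (2 decimals, except the 3-decimal 0.185). Fourteen
of sixteen match. Two do not, and are asserted as documented
discrepancies:

* the US feed-mode constant: printed 9.16, derivation gives 8.90
  (= 1 + 8²/8.1 with x0 = 1);
* the partner natural-enemy inner constant: printed 9.52, derivation gives
  9.49 (= 5(1 + ln 3) − 1).

Whether different unstated parameter values produced the printed numbers
is unknowable from the source. The low-reputation region in which the US
prefers feed-making over direct sale at the low shrimp price exists only
under the printed 9.16 constant (under the derived 8.90 the table mode
already dominates at f1 = 0), so the mode-preference conclusions are
evaluated on the printed fixtures by default, with the derived-source
result reported alongside.

Squared-form published polynomials are read as
"constant + coefficient · (inner linear form)²" — e.g. 1 + 1.39(2.2 +
0.4 f2)² — the only dimensionally and numerically coherent reading.

## Numerical choices

* Quadrature: `scipy.integrate.quad`, absolute tolerance tol/2, horizon
  T = ln(2(|u0| + l·x_max)/(rho·tol))/rho from the tail bound, analytic
  tail added for the constant payoff part. Default tol 1e-6.
* Root finding for crossings: companion-matrix roots of the difference
  polynomial; imaginary parts below 1e-9 count as real; coincident roots
  within 1e-9 collapse; identical polynomials (all coefficient differences
  below 1e-12) raise a degenerate-comparison error rather than return
  anything.
* Trajectory grids default to 1001 points; the f domain for comparisons
  and figures defaults to [0, 10] (the published figures state no axis
  ranges; this is a package choice).
* Property sweeps in the test suite use 100 scenarios (seed 42), which
  completes in about a second; all tolerances are met with two orders of
  magnitude to spare at that size.

## Limitations

* No shrimp-population state, no spatial structure, no stochasticity, no
  strategic interaction between the players — none exist in the model
  class; results are about reputation-driven effort choice only.
* Feed logistics costs are assumed zero; the "negative" equilibria
  (G* < 0) that arise in corner regions of parameter space are flagged,
  not economically interpreted (a clamp to zero would break the closed
  forms' exactness and is deliberately not the default).
* Figures are compared through their underlying tables; pixel-level
  reproduction of the published figures is out of scope (axis ranges were
  never stated).
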