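# shrimpgame

Differential-game analysis of international cooperation on controlling an
invasive shrimp population.

The black tiger shrimp (*Penaeus monodon*) is invasive along the US Gulf
coast but is a valued food and feed resource elsewhere. `shrimpgame` models
the US (player 1) and a cooperative country (player 2) choosing control
effort under three management modes — introducing a natural enemy (**B**),
manufacturing the catch into feed (**M**), and selling it as food, "bringing
it to the table" (**E**) — and asks which mode each government prefers and
how the preference shifts with prices and reputational stakes. It is aimed
at ecological-bioeconomics researchers who want the closed-form equilibria,
their numerical verification, and the policy comparisons in one tested,
scriptable package.

## The model

Each (mode, player) pairing is an independent infinite-horizon optimal
control problem over effort $G(t)$, with a single state: the player's
reputation $x(t)$ for fighting the invasion, which follows Nerlove–Arrow
goodwill dynamics. Every pairing reduces to the canonical linear-state
problem

$$\max_G \int_0^\infty e^{-\rho t}\Big[aG - \tfrac{c}{2}G^2 + l\,x\Big]dt,
\qquad \dot{x} = gG - \delta x,\quad x(0)=x_0,$$

where $a$ collects the linear revenues of effort (ecological benefit, feed
or shrimp price, the natural enemy's breeding bonus $b_2\ln(1+h_B)$), $c$
the quadratic costs, and $g$ the net reputation gain per unit effort
(negative for the partner under mode B when depleting its natural enemy
costs more reputation $f_B$ than the control earns $f_2$). Because the
state enters the payoff linearly, the Hamilton–Jacobi–Bellman value
function is exactly linear, $V(x) = \alpha x + \beta$, with shadow price

$$\alpha = \frac{l}{\rho+\delta}, \qquad
G^* = \frac{a + \alpha g}{c}, \qquad
\beta = \frac{(a+\alpha g)^2}{2\rho c}.$$

Two solver variants are provided: `derived` (the first-order-condition
solution above) and `as_printed_B1`, which reproduces the published
closed form for the US natural-enemy subproblem, whose control
$G^* = (a+\alpha)/c$ drops the reputation-gain factor; the variants agree
everywhere else. Everything downstream — value polynomials in the
reputation-gain coefficients $f_1, f_2$, mode-preference crossings,
signed comparative statics — is built from these closed forms, and an
independent simulation oracle (exact state trajectory plus adaptive
quadrature of the discounted payoff) verifies them.

## Worked example

```python
from shrimpgame import *

prob = canonical_reduction(BASELINE, Mode.FEED, Player.PARTNER)
eq = equilibrium_value(prob)
print("canonical (a, c, g):", (prob.a, prob.c, prob.g))
print(f"shadow price alpha = {eq.alpha:.3f}")
print(f"equilibrium control G* = {eq.G_star:.3f}")
print(f"value V(x0=1) = {eq.value(1.0):.3f}")
print(f"quadrature payoff = {discounted_payoff(prob, eq.G_star, tol=1e-8):.3f}")
print(f"long-run reputation = {steady_state(prob, eq.G_star):.1f}")

pol = value_polynomial_in_f(Mode.FEED, Player.US, BASELINE)
print(f"US feed-mode value polynomial: {pol.k2:.4f} f1^2 + {pol.k1:.4f} f1 + {pol.k0:.4f}")

m = printed_fixture(Mode.FEED, Player.US)
e = printed_fixture(Mode.TABLE, Player.US, 1.0)
print("feed/table crossing (published curves, q_E1=1):", [round(c, 4) for c in crossing_points(m, e)])
```

prints

```
canonical (a, c, g): (3.0, 2.0, 1.0)
shadow price alpha = 1.000
equilibrium control G* = 2.000
value V(x0=1) = 5.444
quadrature payoff = 5.444
long-run reputation = 20.0
US feed-mode value polynomial: 0.1235 f1^2 + 1.9753 f1 + 8.9012
feed/table crossing (published curves, q_E1=1): [0.3455]
```

Reading it: at the baseline the partner's feed-mode marginal revenue is the
feed price $q_{M2}=3$, its cost coefficient $c_{M2}=2$, and each unit of
effort earns $f_2=1$ reputation. With $\alpha = 1/(0.9+0.1) = 1$ the
optimal effort is $(3+1)/2 = 2$ shrimp-units per unit time, worth 5.444 in
discounted welfare — and the independent quadrature oracle returns the same
number. The US feed-mode value as a function of its reputation-gain
coefficient $f_1$ is the quadratic shown, and against the published
table-mode curve at the low shrimp price the preference switches from
feed-making to direct sale at $f_1 \approx 0.35$: feed is better only for a
country whose control effort earns little reputation.

The same computations are available from a shell:

```sh
shrimpgame solve                 # equilibrium table, all six subproblems
shrimpgame figures --out figs    # the four value-vs-reputation panels + CSVs
shrimpgame statics               # signed comparative statics
shrimpgame verify --n 100        # full property sweep + coefficient checks
shrimpgame sample --n 10 --seed 42 --out scenarios.yaml
```

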