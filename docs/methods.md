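# Methods

`intercoop` models the co-evolution of cooperation and interaction
structure on two interdependent groups of players.  This note records
the model, the analytical layer derived from it, the numerical and
design choices, and what the synthetic experiments do and do not show.

## The microscopic model

Two groups of sizes N1, N2 hold a fixed total of L = L1 + L2 + L12
undirected links (L1, L2 inside each group, L12 across; only the total
is conserved by the dynamics).  Each player is a cooperator (C) or a
defector (D) of a donation-game prisoner's dilemma: per interaction a C
pays cost c and hands its partner benefit b (b > c > 0), a D pays and
hands nothing.  In (C, D) ordering the payoff matrix is
M = [[b−c, −c], [b, 0]], which satisfies T > R > P > S.

At each event, with probability W a **strategy update** occurs,
otherwise a **link update**:

- *Link update.*  A uniform link is selected.  A link whose endpoints
  play strategies (s, s′) breaks with probability k_ss′ (the breaking
  schedule k_CC, k_CD, k_DD; a per-type override map is accepted for
  group-dependent variants).  If it breaks, one endpoint is retained
  uniformly and rewires: with probability p (the *intra-group attaching
  bias*) to a uniformly chosen non-neighbor in its own group, otherwise
  to a uniformly chosen non-neighbor in the other group.  Link lifetimes
  are therefore geometric with mean 1/k_ss′, so 1/k is the expected
  number of interaction rounds a pair plays together.
- *Strategy update.*  Players earn the accumulated payoff over all
  current neighbors (both groups alike).  A compared pair (model i,
  target j) is drawn (see "imitation rules" below) and j adopts i's
  strategy with the Fermi probability 1/(1 + exp(−w (Π_i − Π_j))),
  where w ≥ 0 is the selection intensity; w = 0 is neutral imitation
  (probability 1/2).

## Link-type Markov chain

Label each link by the unordered (strategy, group) pair of its
endpoints; there are exactly ten types, ordered
C1C1, C1D1, D1D1, C2C2, C2D2, D2D2, C1C2, C1D2, D1C2, D1D2.
With strategies frozen at cooperator frequencies (x1, x2), following
one link under repeated selections gives a 10-state chain: survive with
probability 1 − k_e, else jump to the type determined by the retained
endpoint and a fresh partner (group by the bias p, strategy by the
target group's frequency).

Because the jump destination depends only on the retained endpoint, the
group pair of the link performs an autonomous walk whose stationary
weights are (p/2, p/2, 1−p) over (intra-1, intra-2, inter) —
independent of group sizes — and endpoint strategies are independent
Bernoulli(x_g) marks.  Weighting each type by its mean holding time
1/k_e gives the closed form

    pi_e ∝ g_e / k_e,
    g_e = (p/2)(2 − δ_ss′) x_g^(s) x_g^(s′)   (intra-group g)
        = (1 − p) x_1^(s) x_2^(s′)            (inter-group),

normalized by Z = Σ_e g_e/k_e.  Two consequences worth noting: pi is
invariant under a common rescaling of all k's, and the expected type
counts are L·pi.

*Finite-population variant.*  The chain above is a mean-field
approximation: the rewiring player cannot pick itself, and its own
strategy is correlated with the link type.  With the self-exclusion
made explicit the intra-group pair weights become without-replacement
(hypergeometric) frequencies of the cooperator counts — still in closed
form, and verified against the numeric left-eigenvector solve to
10⁻¹⁵.  What neither variant carries is the exclusion of *current
neighbors*, whose composition differs from the group's when breaking
probabilities differ strongly across pairs; this O(degree/N)
correlation is visible at high simulation precision (see "validation
scales").

## Fast rewiring and the rescaled game

For W ≪ k̄/L the link population relaxes to pi between strategy
events.  A player of group g then meets partners that are, per unit of
linking turnover, distributed as the stationary environment, and the
expected payoff rates reduce to the **rescaled game**
M′ = M/k entrywise (R′ = (b−c)/k_CC, S′ = −c/k_CD, T′ = b/k_CD,
P′ = 0): robust links count for more because they are played longer.
With the biased mixing frequency

    y_g = p x_g + (1 − p) x_h        (h the other group),

the average fitness of strategy S in group g is
f_S,g = y_g M′[S,C] + (1 − y_g) M′[S,D]; the first (weight-p) term is
same-group payoff, the second cross-group payoff.

## Replicator dynamics, stability, thresholds

Under weak selection the pairwise-comparison drift reduces, after a
constant time rescaling, to an extension of the replicator dynamics,

    dx_g/dt = x_g (1 − x_g)(f_C,g − f_D,g),
    f_C,g − f_D,g = Δ y_g + S′,     Δ = (b − c)(1/k_CC − 1/k_CD).

The symmetric case (N1 = N2, L1 = L2, one shared p) is the default
analysis path; asymmetric parameters are accepted and analyzed
numerically.  On the unit square (forward invariant) the candidate
equilibria are (0,0), (1,1) and the diagonal interior point

    x* = −S′/Δ = c k_CC / ((b − c)(k_CD − k_CC)),

with Jacobian eigenvalues (χ ≡ x*(1−x*)Δ):

| equilibrium | eigenvalues       | character                                |
|-------------|-------------------|------------------------------------------|
| (0,0)       | S′, S′            | always stable                            |
| (1,1)       | −(Δ+S′), −(Δ+S′)  | stable iff b/c > k_CD/(k_CD − k_CC)      |
| (x*,x*)     | χ, χ(2p − 1)      | unstable node p > 1/2, saddle p < 1/2    |

Hence the **critical benefit-to-cost ratio** is
(b/c)* = k_CD/(k_CD − k_CC) = 1/(1 − κ) with fragility ratio
κ = k_CC/k_CD: cooperation can only be stabilized when C–C links
outlive C–D links, more easily the more fragile mixed links are.  When
the condition holds, x* ∈ (0,1) is exactly the basin boundary on the
diagonal: initial cooperator fractions above x* flow to all-C, below to
all-D (a coordination game).  x* grows with k_CC and falls with k_CD,
so sturdier C–C links widen the basin of cooperation.  The **critical
intra-group bias** p_c at which the interior point changes character
(saddle ↔ unstable node) is found by bisection on the transverse
eigenvalue sign; for the affine fitness structure it sits at exactly
1/2, independent of the other parameters.

All closed forms are continuously cross-checked by independent oracles:
the Jacobian against central finite differences (10⁻⁶), the eigenvalue
table against numerical eigenvalues (10⁻⁸), (b/c)* against an
eigenvalue-sign bisection (10⁻⁶), x* against a diagonal root-find
(10⁻⁸) and against basin bisection of integrated orbits (10⁻⁵).

### Transition probabilities and the cross-imitation channel

The per-group raising/lowering probabilities T±_g are exposed in two
forms.  The two-channel form (`cross_imitation=True`) weights a
same-group comparison by p and a cross-group comparison by 1 − p, e.g.
T+_g = p x_g(1−x_g)Θ(f_C,g − f_D,g) + (1−p) x_h(1−x_g)Θ(f_C,h − f_D,g).
Its drift contains a selection-independent term (1−p)(x_h − x_g)/2 —
neutral strategy transport between groups — which vanishes on the
diagonal x1 = x2 and therefore does not move the diagonal fixed-point
structure.  The within-group form (`cross_imitation=False`) carries the
interdependence through the fitness alone; its drift is
x_g(1−x_g) tanh(w(f_C,g − f_D,g)/2), vanishes identically at w = 0, and
its w → 0 limit is exactly the replicator field above.  The stability
and threshold layer is derived from the latter; the former is provided
for studying the mixing term.

### Imitation rules in the simulator

The simulator exposes three pair-sampling rules for strategy updates:

- `"neighbor"`: uniform focal player, uniform neighbor; the focal
  player's strategy tries to replace the neighbor's (a documented
  switch reverses the direction).
- `"link"`: a uniform link with a fair coin for who is focal.
- `"global"`: uniform target player; the model player is drawn from the
  target's own group with probability p, from the other group
  otherwise.  This is the microscopic realization of the T± structure
  above: the network determines payoffs, comparison is population-wide.

The distinction matters more than is commonly appreciated.  Under
`"neighbor"`, pairs are weighted by 1/degree of the focal player, which
adds an O(1) neutral drift favoring the strategies of low-degree
players; because the linking dynamics gives defectors systematically
lower degree (their links break faster), this drift is anti-cooperative
and dominates O(w) selection — at the scales studied here it drives the
population to all-D from any initial condition.  Under `"link"` the
neutral bias disappears, but the compared payoffs are conditioned on
the pair being adjacent, which at finite degree penalizes the
cooperator endpoint of a mixed link by roughly b + c and shifts the
empirical basin boundary well above x*.  Only `"global"` removes both
conditioning effects, and it is the rule the population-level theory
describes; the analytical-correspondence experiments therefore use it,
while `"neighbor"` remains the literal reading of the verbal model
description and the default of `SimulationParams`.

## Synthetic experiments and study conditions

The bistable study preset is N1 = N2 = 100, L1 = L2 = 300, L12 = 200
(average degree 8), b = 1, c = 0.3, k = (0.3, 0.6, 0.9), p = 0.6,
W = 10⁻³, w = 0.1, started from exact-count random initial conditions.
Rationale: (b/c)* = 2 < b/c = 10/3 puts the system safely in the
coordination regime; x* = 3/7 ≈ 0.43 places the basin boundary just
below the half-filled initial condition, the regime in which the
stochastic dynamics is sensitive to the intra-group bias; W = 10⁻³ is
genuine timescale separation (the link population of L = 800 turns over
several times between strategy updates; W ≳ 10⁻² visibly is not, and
the fast-rewiring theory then does not apply); w = 0.1 keeps
w·|ΔΠ| ≲ 0.5 (weak-to-moderate selection) while leaving enough drift
for fixation within feasible horizons.  Horizons are 2–3·10⁷ events
with early stopping at monomorphic states; replicate r of an experiment
uses seed + r (plus a per-grid-point offset).

Measured under these conditions: runs started at x0 ∈ {0.2, 0.3} fixate
to all-D and x0 ∈ {0.6, 0.7} to all-C in ≥ 90% of replicates (the
empirical threshold brackets x* between 0.4 and 0.5); the 11-point
sweep of p at x0 = 0.5 peaks at an interior bias (≈ 0.4–0.6) and falls
toward both ends — at large p because the groups decouple (the
inter-group link mass equilibrates to 1 − p, so p → 1 severs the
populations, halving the effective population size and allowing
polarized one-group-C/one-group-D outcomes), at small p because
comparison and rewiring become predominantly cross-group and the noisy
inter-group transport degrades the marginal cooperative basin.

### Validation scales

The chain-vs-simulator validation freezes strategies (W = 0) on a
sparse network (degree 2, L1 = L2 = 60, L12 = 80, x = (0.5, 0.3),
p = 0.6) with the mild schedule k = (0.45, 0.5, 0.55), runs 10⁶ link
events and compares time-averaged type frequencies (sampling stride
500 events ≈ 1.4 relaxation times, batch-means standard errors over 25
batches) with the finite-population closed form.  The mild contrast is
deliberate: at k = (0.3, 0.6, 0.9) the neighbor-exclusion correlation
that the 10-state chain ignores is a measurable ~1.5-SE systematic at
this precision, i.e. the chain's own validity assumption (neighbor
composition ≈ group composition) fails before the simulator does.  The
strong-contrast regime is still validated at reduced precision, and it
is exercised end-to-end by the threshold and basin experiments.

## What the generator emulates — and what it does not

Networks are uniform random (G(N, L) per compartment) with exact link
counts and exact-count strategy placement, so initial conditions are
precisely controlled; there is no degree heterogeneity beyond that
generated by the dynamics itself, no community structure inside groups,
no mutation, and no more than two groups.  Passing tests therefore
show that the implementation realizes this model and that the model's
analytical layer is internally consistent — not that real interdependent
populations satisfy the mean-field assumptions (large N, degree ≪ N,
fast rewiring, global comparison).  The imitation-rule analysis above
is a concrete example of how sensitive the conclusions are to
micro-details the population-level equations do not see.

## Numerical choices

- Stationary distributions: closed form by default; the numeric path
  solves the left fixed vector on the recurrent class (strongly
  connected components of the positive-transition graph) and flags
  reducible chains (boundary frequencies) instead of failing; multiple
  closed classes (e.g. all k = 0) raise.  Stationarity and normalization
  are asserted at 10⁻¹⁰, closed-vs-numeric agreement at 10⁻⁸.
- ODE integration: RK45 with rtol 10⁻⁸, atol 10⁻¹²; no projection onto
  the unit square (the field is inward/tangent on the boundary);
  convergence declared within 10⁻⁶ of a fixed point, otherwise the
  trajectory is returned flagged.
- Bisections: basin boundary along the diagonal to 10⁻⁶; p_c via Brent
  on the transverse eigenvalue to 10⁻⁹.
- Breaking probabilities are accepted in [0, 1]; operations requiring
  irreducibility (rescaling, stationary laws) insist on k > 0.  k = 0
  is useful for frozen-network controls.
- The event loop is a numba kernel over an edge list plus a dense
  adjacency byte matrix (populations of a few hundred nodes); partner
  search is rejection sampling with an exact-enumeration fallback, and
  events with no eligible neighbor/partner are consumed as no-ops.
  Given identical parameters and seed, records are bit-identical on a
  given platform.

## Known limitations

- The mean-field chain ignores neighbor-exclusion correlations
  (O(degree/N)); at high Monte-Carlo precision this is detectable, as
  quantified above.
- Closed-form x*, thresholds and the eigenvalue table assume the
  symmetric case and a strategy-pair-keyed breaking schedule;
  group-dependent schedules and asymmetric sizes fall back to numeric
  analysis only.
- The finite-size noise of the strategy dynamics is represented by the
  simulator itself; no diffusion approximation or fixation-probability
  theory is provided.
- Timescale separation is assumed, not adaptive: for W ≳ 10⁻² at the
  default link counts the fast-rewiring fitness is simply the wrong
  payoff model, and simulator outcomes depart from the replicator
  predictions accordingly.
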