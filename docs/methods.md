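# Methods

## The game

`psgame` analyses producer–scrounger games of aggressive kleptoparasitism:
a group of `G` foraging predators in which each individual either hunts for
prey itself (*producer*) or attempts to steal prey held in the mouths of
group-mates (*scrounger*). Prey are swallowed whole, so there is no
finder's share: a successful theft transfers the entire item. The payoff
currency is the *average number of prey in the mouth* of a member of each
behavioural class — proportional to consumption when handling rates are
equal across strategies.

### Single-phenotype model

State variables `P` and `S` (mean prey held per producer / per scrounger)
follow linear mean-field dynamics

    dP/dt = λ − α q G P − γ P
    dS/dt = α (1 − q) G P − γ S

with capture rate `λ` (prey h⁻¹ per producer), stealing rate `α` (per
scrounger per hour per prey held by the target), combined
consumption-plus-escape rate `γ` (h⁻¹; `1/γ` is the mean handling time),
and scrounger proportion `q`. Handling time is explicitly finite: a larger
`γ` means prey are processed faster and are exposed to theft for less
time. Same-class scrounger-on-scrounger theft cancels in the class average
and does not appear.

At fixed `q` the prey dynamics settle on

    P*(q) = λ / (γ + αqG),    S*(q) = (1 − q) G α λ / (γ (γ + αqG)),

and behavioural change runs on a slower timescale τ with logistic
imitation dynamics

    dq/dτ = (S*(q) − P*(q)) · q (1 − q).

The proportionality constant of this equation is fixed at 1: τ is an
arbitrary slow timescale, and only the rest points and their stability are
scientifically meaningful. The stable rest point is the Nash equilibrium

    q* = max(0, 1 − γ/(αG)),

interior exactly when scrounging can invade (`G > γ/α`). The boundary
rest points `q ∈ {0, 1}` are dynamical equilibria but `q = 1` is never
Nash (`S*(1) = 0 < P*(1)`), and `q = 0` is Nash only when `αG ≤ γ`;
`nash_q` clamps the closed form at 0 accordingly, and equality `αG = γ`
(up to a 1e-12 relative roundoff guard) counts as no invasion.

### Two-phenotype (size-structured) model

Two body-size classes — small (subscript 1, a fraction `θ` of the group)
and large (subscript 2) — differ in stealing ability (2×2 table
`α_ij`, thief size i on target size j), handling rate (`γ₁`, `γ₂`) and
optionally capture rate (`λ₁`, `λ₂`; equal by default). With class head
counts `n1p = (1−q₁)θG`, `n1s = q₁θG`, `n2p = (1−q₂)(1−θ)G`,
`n2s = q₂(1−θ)G`, the per-capita holdings follow

    dP1/dt = λ₁ − (α₁₁ n1s + α₂₁ n2s) P1 − γ₁ P1
    dP2/dt = λ₂ − (α₁₂ n1s + α₂₂ n2s) P2 − γ₂ P2
    dS1/dt = α₁₁ n1p P1 + α₁₂ n2p P2 + [α₁₂ n2s S2 − α₂₁ n2s S1] − γ₁ S1
    dS2/dt = α₂₁ n1p P1 + α₂₂ n2p P2 + [α₂₁ n1s S1 − α₁₂ n1s S2] − γ₂ S2

The bracketed terms are *cross-phenotype scrounger-on-scrounger* theft.
Unlike same-class theft they do change the class averages, so they are
included by default (`scrounger_theft=True`); a flag disables them. Two
exact identities guard this construction:

* **symmetric reduction** — with phenotype-independent parameters the
  steady payoffs collapse onto the one-class closed form evaluated at the
  composite scrounging fraction `q̄ = θq₁ + (1−θ)q₂`, to 1e-10;
* **group conservation** — theft terms cancel exactly in the
  group-aggregate holdings budget (capture in, handling out), for any
  state, composition and flag setting.

Encounter counts use `G`, not `G − 1` (a producer "faces" all scroungers
including, formally, itself at zero rate); this mirrors the `αqG` form of
the one-class model and is negligible for groups of ten or more.

Producer steady payoffs are closed-form; scrounger payoffs solve the 2×2
linear system from `dS/dt = 0` (Cramer's rule — the expression sits inside
sweep loops and a general linear solver would dominate the runtime).
Behavioural dynamics are matching logistic equations per class:

    dq_i/dτ = (S_i* − P_i*) q_i (1 − q_i).

### Stealing-rate scenarios

Three presets span the biologically motivated orderings (units
scrounger⁻¹ h⁻¹, order α₁₁/α₁₂/α₂₁/α₂₂):

* **A** 0.36/0.36/0.36/0.36 — stealing independent of size;
* **B** 0.36/0.12/0.60/0.36 — large steal most, small least, targets
  indiscriminate;
* **C** 0.36/0.12/0.60/0.00 — as B but large never steal from large.

Baseline parameters are the field estimates λ = 0.6 prey h⁻¹,
γ₁ = 1.002 h⁻¹, γ₂ = 1.914 h⁻¹ (small predators handle prey for longer),
θ = 0.5, G = 15; the one-class baseline is α = 0.40, γ = 1.2.

## Phase-plane analysis

The strategy square [0,1]² is forward-invariant (both logistic factors
vanish on the boundary). `find_equilibria` assembles rest points from
three sources: the four corners; edge points where one coordinate is
pinned and the other class's payoff equality `S_i* = P_i*` is solved by
sign-bracketing on a 101-point grid plus Brent's method; and interior
roots of the pair of payoff equalities from a 5×5 grid of interior starts
(plus warm starts during sweeps) polished with a hybrid Powell solver.
Duplicates are merged within 1e-8, and every reported point has
behavioural-dynamics residual below 1e-8.

Stability is classified from the eigenvalues of a central-difference
Jacobian (step 1e-6): all real parts < −1e-7 → `stable`, all > +1e-7 →
`unstable`, mixed → `saddle`, any real part inside the ±1e-7 band →
`boundary-degenerate`. These tolerances reflect the problem scaling
(payoffs O(0.1–1), rates O(1)).

**Nash** requires dynamical stability *plus*, at boundary coordinates, the
unilateral-deviation inequality: at `q_i = 0` a lone scrounger must not
profit (`S_i* ≤ P_i*`), at `q_i = 1` a lone producer must not profit
(`S_i* ≥ P_i*`). Stability alone is not sufficient — the one-class `q = 1`
corner can be approached by the dynamics yet always fails the deviation
test.

When more than one stable rest point exists (a genuine bistable band
occurs nowhere at the baselines, but sweeps can cross one), the reported
Nash is the point reached by forward integration (LSODA, rtol 1e-10,
atol 1e-12, early termination once the flow speed drops below 1e-12) from
the centroid (0.5, 0.5); all stable equilibria remain available via
`nash_equilibrium(..., full=True)`.

### The equal-stealing degeneracy

When all four `α_ij` are equal (scenario A) and cross-scrounger theft is
on, the two interior payoff-equality loci coincide *exactly*: the interior
equilibrium is not a point but a neutral line (transversally attracting,
neutral along itself). The settled point then depends on the start — the
centroid by convention — and is reported with stability
`boundary-degenerate`. Group-average payoff and the composite fraction
`q̄` are constant along the line, so sweep outputs remain well defined;
the per-class split `(q₁*, q₂*)` on that line is a convention, not a
prediction, and small reported differences between the classes in
scenario A should be read accordingly.

### Sweeps and the scenario-C threshold

`sweep_group_size`, `sweep_gamma` and `sweep_theta` recompute the Nash
record per grid point, warm-starting the interior root search from the
previous point (selection itself never depends on the warm start). Grid
conventions follow the study design they emulate: γ grids 0.06–3.00 in
steps of 0.06, G from 1 to 100, θ from 0 to 1; γ and θ sweeps hold the
baseline G = 15 and θ = 0.5 fixed unless overridden.

For scenario C the package computes the smallest grid γ₂ at and above
which `q₁* = 0` for every γ₁ (`q1_extinction_threshold`). Analytically,
the `q₁ = 0` edge becomes stable at γ₂ = 2.25 h⁻¹ *independently of γ₁*
(at the edge equilibrium the large-class payoff equality pins
`P1* = λ/(α₂₁θG)`, and the lone-scrounger condition reduces to
`α₁₁θG·P1* + α₁₂(1−θ)G·λ/γ₂ ≤ λ`), and the transcritical bifurcation is
supercritical — the interior branch detaches continuously, with no
bistable fold. On the 0.06 grid the computed threshold is therefore
2.28 h⁻¹. Published analyses of closely related size-structured
producer–scrounger systems have placed this boundary nearer 2.4 h⁻¹;
the difference is consistent with reading a threshold off a coarse
heatmap near a supercritical bifurcation, where equilibrium scrounging
proportions are small but nonzero (here `q₁* ≈ 0.03` one grid step below
threshold) and finite-time integration undershoots them.

## Stochastic oracle

`stochastic.simulate` is an exact continuous-time Markov jump process on
integer prey holdings of individually tracked agents: captures are
constant-rate immigration per producer, handling terminations are linear
death per held item, and theft moves exactly one item per event at rate
`α_ij` × target holdings per (scrounger, target) pair (self-pairs
excluded; scrounger targets included per the `scrounger_theft` flag).
Because every rate is constant or linear in holdings, the expected class
means obey the mean-field ODEs *exactly* — there is no mean-field error —
so long-run time averages must match the closed-form steady payoffs
within Monte-Carlo error. `compare_to_ode` reports per-class z-scores
using batch-means standard errors (20 equal post-burn-in windows;
default horizon 2000 h, burn-in 200 h), and recomputes the ODE reference
at the *realised* integer class counts so that strategy rounding
introduces no bias. A `cap_one` variant (at most one prey in the mouth,
closer to the biology) exists for exploration but deliberately breaks
the linearity and is not used for validation.

Sampling is classic Gillespie — one seeded generator, total-rate
exponential waiting times, categorical event choice — so runs are
bit-reproducible for a fixed seed.

## Synthetic field trials

`fieldtrials.generate_trial` wraps the jump process in an observation
model emulating a scored one-hour foraging trial. The jump process only
defines captures, successful thefts and handling terminations; the
observation layer adds what a single-rate model cannot:

* strikes: each capture is the last of a geometric number of lunges,
  success probability 0.436 per strike (field average; configurable);
* failed theft attempts: geometric per successful theft, success
  probability 0.15 (the order of field success proportions; configurable);
* escape vs consumption: a handling termination is an escape with
  probability 0.2 (the order of field escape shares), otherwise a
  consumption;
* imperfect observation: records dropped independently with `miss_prob`,
  size labels replaced by `unknown` with `unknown_prob`.

Handling durations attach to acquisition records with the correct
right-censoring structure (ended by theft or trial end → censored).
`estimate_gamma` is the matching estimator: the exponential
maximum-likelihood rate (uncensored terminations / total observed
handling time) with the exact Gamma-distribution confidence interval.
The exponential (constant-hazard) form is the model-consistent choice —
the mean-field equations assume a single rate γ; Kaplan–Meier or other
parametric fits are out of scope. `rate_table` recovers per-class hourly
behaviour rates as count/(class size × duration), reporting zeros rather
than dropping them (sparse behaviours are the norm), with unknown-size
events tallied separately and excluded from per-class denominators.
`coarsen_sizes` maps three observational classes onto the two model
phenotypes (default small→small, medium and large→large).

What the generator does *not* emulate: observer disagreement about size
(beyond the unknown-label channel), depth-dependent detectability, prey
depletion within a trial (λ is constant, as in the model), satiation, or
within-trial strategy switching. Passing round-trip tests therefore show
that the estimators invert this generative model, not that the model
captures every feature of real trial data.

## Problem sizes and numerical defaults

Default analyses run in seconds on one core: the 50×50 γ sweep solves
2500 Nash problems (~15 s), oracle validation uses 2000 h horizons
(~10⁴–10⁵ events), and round-trip estimator checks use 50 seeded
one-hour trials. Key tolerances: equilibrium residual 1e-8, duplicate
merge 1e-8, Jacobian step 1e-6, eigenvalue zero band 1e-7, boundary snap
1e-9, ODE integration rtol 1e-10/atol 1e-12, statistical agreement 3
standard errors.

## Known limitations

* Two phenotypes only; no phenotype-dependent capture-rate presets
  (unequal λ₁, λ₂ are accepted as parameters but unstudied here).
* Mean-field class counts are continuous; the stochastic layer requires
  integer assignments and realises strategy proportions by rounding.
* No bifurcation continuation or analytic uniqueness results: multi-start
  root finding plus the centroid-basin rule can in principle miss exotic
  attractors, though none arise on the studied grids.
* The scenario-A equilibrium split between classes is a convention on a
  neutral line (see above).
* No spatial structure, prey depletion, satiation or group
  joining/leaving.
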