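# Methods

## Decision model

The analysis compares two fixed treatment strategies for symptomatic knee
osteoarthritis over a 6-month horizon with a decision tree. The horizon is
short enough that no discounting is applied, and outcomes are kept on their
natural scales: direct cost in USD and functional effectiveness as a
dimensionless effect size on pain/function (values above 0.5 are
conventionally regarded as clinically important). No QALY conversion, no
optimal-policy selection at the decision node, and no complication costs are
modelled.

Tree semantics: the root decision node's children are the strategies; chance
nodes carry branch probabilities (expressions over parameters, complements
written `1 - p`, validated to sum to 1 within 1e-9 absolute — expressions of
complement form are exact up to floating error); terminals carry payoff
pairs. Rollback is the standard leaves-to-root expectation; it is multilinear
in the parameters because expressions are restricted to `+`, `-`, `*`,
constants and parameter references, and each root-to-leaf path uses any one
parameter at most once. That restriction is deliberate: it covers linear cost
accumulation (device price + session price x session count) and makes two
useful facts provable — rollback is exactly linear in terminal costs, and
Monte-Carlo sampling with distributions whose mean equals the base value
gives an unbiased plane centroid.

The incremental cost-effectiveness ratio is ΔC/ΔE for a (new, standard)
strategy pair. Reported ICERs are truncated toward zero to whole dollars
(18,146.15 → 18,146; 15,576.67 → 15,576), matching the presentation of the
published totals; full precision is retained internally and in JSON output.
When ΔE = 0 the ratio is suppressed and a dominance/tie classification is
reported instead. Sign patterns map exhaustively onto: `dominant` (cheaper,
more effective), `dominated`, `NE` (more effective, more costly), `SW`,
and three tie categories (`equal`, `equal_cost`, `equal_effect`) so that
boundary cases are never folded arbitrarily into a quadrant.

Medicare-to-commercial payment conversion uses the exact ratio 1/0.75
(Medicare assumed to pay 75% of commercial rates); the familiar "$1.33 per
$1" multiplier is that ratio rounded to cents. The conversion is exposed as
a standalone utility and deliberately not baked into the bundled model,
because it is not stated whether the $41.80/session PT price is already a
commercial rate; the model uses the printed price directly.

## The bundled knee-OA model (`knee_oa_2020`)

The published analysis prints strategy-level totals and headline parameters
but not the stage-level table behind them (its appendix of variable
distributions and equations is not publicly available). The bundled model is
therefore an explicit reconstruction with three classes of numbers:

**Printed anchors.** SAM device price $4,635 entering the SAM arm at
certainty; PT priced at $41.80 per 15-min session with 2–4 sessions per
visit; strategy totals (cost, effect) of ($8,641, 0.52) for SAM vs
($6,282, 0.39) for SOC on the initial pathway, and ($13,967, 0.77) vs
($9,294, 0.47) on the later pathway (SAM+PT vs topical-NSAID+PT). One
published erratum is resolved here: the source text computes the base-case
ICER with "0.53" in one spot while printing 0.52 everywhere else; 0.52 is
the value consistent with 2359/0.13 = 18,146 and is used throughout.
Modelling the device at certainty is justified by the arithmetic identity
4635 − (8641 − 6282) = 2276 matching the published device break-even
exactly.

**Reverse-engineered structural constants.** The published break-evens pin
down the PT utilisation structure. The slope of ΔC in the PT session price
must be ΔC(88) = 0, giving a net differential of −2359/(88 − 41.80) ≈
−51.06 sessions (SAM arm minus SOC arm): the SOC pathway consumes more
clinic PT, the SAM arm substitutes wearable home therapy. Jointly with the
144-total-session break-even, the base session count given PT initiation is
n = 41.8·144/(41.8 + 46.2) = 68.4 (≈ 22.8 visits at 3 sessions/visit over
6 months; the 2–4 sessions/visit range scales this to 45.6–91.2). Because
these constants are derived *from* the published $88 and 144 break-evens,
reproducing those two values is a consistency check of the reconstruction,
not an independent validation; the device-price break-even and both ICERs,
by contrast, follow from printed numbers alone.

**Placeholders plus calibration residuals.** Stage success probabilities
(0.70 SAM; 0.55/0.60/0.55 for NSAID/steroid/HA), stage therapy costs
($75/$150/$1,000), stage effect sizes, and the declining PT-course fractions
for later starts (1.0/0.8/0.6) are plausible-scale placeholders, marked
`reconstructed` in the model file. One cost and one effect residual per arm
are then solved (calibration is a direct subtraction because each residual
enters every terminal of its arm at coefficient 1) so rollback reproduces
the printed totals exactly. The residuals — about $3,780 (SAM) and $3,600
(SOC) — absorb all unmodelled cost (consumables, clinician visits, imaging)
and are reported transparently as point-mass parameters. Calibration fails
loudly if a target implies a negative cost residual. Patient-population
constraints (under-65, non-Medicare) are documentation: they determine which
payment rates feed the file, not the tree structure.

Parameter ranges for the tornado analysis are fixture choices where not
printed: device $2,000–$6,500, PT price $20–$100 per session, plus modest
ranges on stage costs, probabilities and effects. Under these documented
ranges the swing ranking reproduces the published top three (device price,
PT session price, PT session count); the ordering is a property of the
reconstruction, not newly inferred evidence.

## Sensitivity analysis

One-way sweeps re-evaluate both arms with a single parameter overridden.
Break-even search uses bisection (monotone ΔC in each cost parameter for
this model family), requiring a sign change over the bracket and stopping at
|ΔC| ≤ $0.01 or when the bracket shrinks to 1e-6 of its initial width;
thresholds are displayed rounded to whole dollars, full precision kept.
A missing sign change raises an error rather than clamping. Tornado rows
evaluate ΔC at each parameter's low and high with others at base; ties in
swing break alphabetically.

## Probabilistic sensitivity analysis

The published scatter was produced by 1,000 random model evaluations over
low/high parameter ranges; since no state-transition structure is described,
this package implements it as Monte-Carlo PSA over the decision tree (no
Markov transition matrix exists or is needed). Default distributions are
triangular(low, base, high) for every parameter with a non-degenerate range
— these use exactly the three published anchors per parameter — with uniform
and point available in the model file; distributions must respect role
bounds a priori (probabilities within [0,1]; no clipping ever). A single
root seed spawns one substream per parameter in declared order, so adding a
parameter's uncertainty never perturbs another parameter's draws, and runs
are bit-reproducible given (n, seed). Exact-zero increments land in explicit
boundary categories (measure zero under continuous specs).

Because default triangular means differ from base values for asymmetric
ranges, the PSA centroid need not equal the base-case increment; the
symmetric-spec helper (`symmetric_triangular_specs`) exists for the unbiased
variant used in validation. With the default fixture ranges and seed 1 at
n = 1000, 83.4% of iterations fall in the NE quadrant — close to the
published 84% — and the centroid is (+$1,432, +0.131) against the published
(+$2,400, +0.12); both published figures depend on the unavailable appendix
distributions, so they are plausibility checks of the reconstruction, not
validation targets.

## Synthetic generators and what tests demonstrate

`gen_tree` produces random chance trees (Dirichlet branch probabilities,
uniform payoffs on the fixture's scales: costs in [0, 10,000] USD, effects
in [0, 1]) and, at generation time and by an independent code path,
enumerates all root-to-leaf paths to give the exact expected payoff.
`gen_linear_model` builds two-strategy models with an explicit linear ΔC,
giving closed-form oracles for thresholds (−intercept/coefficient) and
tornado swings (|coefficient| x range). Tests validate the engine against
these oracles and the fixture against the printed anchors.

What passing tests do **not** show: that the reconstructed stage-level
probabilities and costs match the unpublished ones; that real-world payer
mixes match the single-price inputs; or that the clinical effect sizes
transfer beyond the cited evidence base. The synthetic generators emulate
tree shape and payoff scale, not clinical correlation structure (parameters
are sampled independently; no correlated PSA, and no expected-value-of-
perfect-information analysis).

## Numerical choices and problem sizes

Probability-sum tolerance 1e-9 absolute; bisection tolerance $0.01 on ΔC;
ICERs truncated toward zero for display; currency whole-dollar in tables,
full precision in JSON; CSV/JSON outputs round-trip to 12+ significant
digits. Validation suites run rollback-vs-enumeration on 100+ random trees
(depth ≤ 4, branching ≤ 3), PSA centroid checks at n = 10,000 draws within
±3 Monte-Carlo standard errors, and NMB/ICER sign agreement on 1,000 random
pairs — sizes chosen so the full suite completes in seconds while keeping
Monte-Carlo error far below the tolerances tested.
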