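# oacea — cost-effectiveness of sustained acoustic medicine for knee osteoarthritis

`oacea` is a decision-analytic modelling package for health economists and
musculoskeletal-care researchers. It implements a 6-month cost-effectiveness
comparison of **sustained acoustic medicine (SAM)** — a wearable, multi-hour,
home-use low-intensity therapeutic ultrasound device — against the
**standard of care (SOC)** pathway of sequential ACR-guideline therapies
(topical NSAIDs, corticosteroid injection, hyaluronic-acid injection, each
followed by physical therapy once pain permits) for symptomatic knee
osteoarthritis. The machinery is generic: any two-strategy decision tree
defined in the package's YAML model format can be analysed the same way.

## The model

Each strategy is a decision-tree arm. Chance nodes carry probabilities of a
therapy relieving pain enough to initiate physical therapy (PT); terminal
nodes carry a payoff pair — cumulative cost *C* (USD) and functional
effectiveness *E* (a dimensionless, Cohen's-d-like effect size on pain and
function) over the 6-month horizon. **Rollback** computes each arm's expected
payoffs, and the strategies are compared by the incremental
cost-effectiveness ratio

```
ICER = (C_SAM − C_SOC) / (E_SAM − E_SOC)    [USD per unit effect size]
```

reported truncated to whole dollars. Around the base case the package
provides:

- **One-way sensitivity analysis** — parameter sweeps of ΔC, bisection for
  break-even parameter values at which the strategies' costs are equal, and
  a tornado ranking of parameters by the ΔC swing over their plausible range.
- **Probabilistic sensitivity analysis (PSA)** — joint Monte-Carlo sampling
  of all parameters (triangular distributions on low/base/high by default),
  summarised on the cost-effectiveness plane (quadrant shares, centroid, net
  monetary benefit `NMB = λ·ΔE − ΔC`, and acceptability curves over
  willingness-to-pay λ).
- A bundled, calibrated knee-OA model (`knee_oa_2020`) plus synthetic
  generators with closed-form oracles for validation.

The bundled model is a documented reconstruction: headline inputs (device
price $4,635; PT at $41.80 per 15-min session, 2–4 sessions per visit) and
the strategy totals are published, while stage-level probabilities and the
net PT-utilisation differential are reconstructed and calibrated — see
`docs/methods.md` for exactly which numbers are anchors and which are
placeholders.

## Worked example

```bash
$ oa-cea base --model knee_oa_2020
         label  expected_cost  expected_effect
           SAM           8641             0.52
           SOC           6282             0.39
  SAM_PT_later          13967             0.77
NSAID_PT_later           9294             0.47
SAM vs SOC: delta cost $2,359, delta effect 0.130, ICER $18,146 [NE]
SAM_PT_later vs NSAID_PT_later: delta cost $4,673, delta effect 0.300, ICER $15,576 [NE]
```

Over 6 months the SAM pathway costs $2,359 more than SOC and gains 0.13
effect-size units, i.e. $18,146 per unit of functional effect — "NE" marks
the north-east plane quadrant (more effective, more costly). Both ICERs sit
well below the $50,000 high-value-care threshold. The later-stage comparison
(SAM+PT versus NSAID+PT) yields $15,576 per unit effect.

```bash
$ oa-cea threshold --model knee_oa_2020 --param sam_device_cost --range 0:4635
sam_device_cost: break-even at 2276.00 (~2276), below_makes_new_cheaper
```

If the device were priced below $2,276 (instead of $4,635), SAM would be the
cheaper strategy outright. A seeded PSA (`oa-cea psa --model knee_oa_2020
--n 1000 --seed 1`) places 83.4% of iterations in the NE quadrant and
estimates a 93.3% probability of cost-effectiveness at λ = $50,000.

The whole pipeline — base case, tornado, break-even table, PSA, and a
reproducibility manifest — runs with:

```bash
oa-cea full --model knee_oa_2020 --n 1000 --seed 1 --out results/full
```

As a library: `from oacea import knee_oa; model = knee_oa.load();
model.incremental(0).icer_truncated` → `18146`.

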