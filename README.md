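# dtastop

Simulation and decision-support toolkit for **technology-assisted screening
in systematic reviews of diagnostic test accuracy (DTA)**.

Screening prioritization ranks the candidate references of a systematic
review so that relevant studies are screened early, which raises an
immediate question: *when is it safe to stop screening?* For DTA reviews
the quantity that matters is not recall per se but the accuracy of the
meta-analysis — the summary sensitivity/specificity estimate computed from
the 2×2 tables (TP/FP/FN/TN) of the included studies. `dtastop` simulates
the whole loop and evaluates stopping criteria that bound the loss in
meta-analysis accuracy incurred by stopping early:

- **Ranking** — continuous active learning: the review protocol seeds a
  logistic model (SGD on tf-idf unigram/bigram features) as a single
  positive example, the unscreened pool supplies ≥ 100 pseudo-negatives,
  the model is refit each iteration and the top *B* references are
  screened, with *B* growing as *B* → *B* + ⌈*B*/10⌉. A uniformly random
  order serves as the no-technology control.
- **Meta-analysis** — the bivariate random-effects model: per-study logit
  sensitivity/specificity pairs y_i with within-study covariance V_i are
  modelled as y_i ~ N(μ, Ψ + V_i); the summary estimate is
  (expit μ₁, expit μ₂) with Wald 95% CIs on the logit scale. Fitting is
  REML (ML optional) with μ profiled out by GLS.
- **Stopping criteria** — seven rules evaluated on the replayed screening:
  recall target R; knee of the effort/loss curve; loss/effort slope
  threshold on the curve's monotone convex hull; *n* relevant found;
  found/effort (no new relevant among the last E/F screened); displacement
  MA2 (moving average of the L2 shift
  Δλ_t = √((μ_t−μ_{t−1})² + (ν_t−ν_{t−1})²) between consecutive summary
  estimates); and LOOCV displacement (median shift under leave-one-out
  refits). Criteria can be OR-combined. Losses are measured as the L2
  distance to the final estimate over all relevant studies.

A synthetic-data module generates review corpora with known truth (pool
separability, bivariate logit-normal 2×2 tables), so every component is
testable without external downloads; loaders for TREC-style qrels and flat
2×2 CSV exports cover real data.

## Worked example

```python
from dtastop import (CriterionConfig, SyntheticSpec, gen_pool, run_simulation)

ds = gen_pool(SyntheticSpec(n_candidates=800, n_relevant=30, group_sizes=(12,), seed=5))
report = run_simulation(
    ds,
    methods=("ranked", "random"),
    criteria=[CriterionConfig("relevant_found", {"n": 10}),
              CriterionConfig("displacement_ma2", {"threshold": 0.02})],
    reps=3,
    base_seed=11,
)
print(report.aggregate_frame()[
    ["order_method", "criterion", "triggered_ma", "effort_frac", "recall", "l2_mean"]
].round(3).to_string(index=False))
```

prints

```
order_method                        criterion  triggered_ma  effort_frac  recall  l2_mean
      random displacement_ma2(threshold=0.02)             3        0.386   0.411    0.021
      random             relevant_found(n=10)             3        0.340   0.333    0.022
      ranked displacement_ma2(threshold=0.02)             3        0.018   0.489    0.023
      ranked             relevant_found(n=10)             3        0.013   0.333    0.049
```

Reading: with prioritized screening the displacement criterion would have
stopped after screening 1.8% of the pool (vs 38.6% in random order), having
found about half the relevant references, and the summary
sensitivity/specificity estimate at that point sits 0.02 (L2, on the
probability scale) from the estimate that exhaustive screening would give.

More narrative scripts live in `examples/` (corpus generation, a single
bivariate fit, ranked-vs-random recall curves, criterion evaluation), and a
thin CLI (`dtastop synth|rank|fit|simulate|report`) wraps the same API for
shell use.

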