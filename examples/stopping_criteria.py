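"""Evaluate stopping criteria on a simulated screening of one review.

Replays prioritized and random screening, refits the meta-analysis at every
newly found relevant study, and prints where each criterion would have
stopped the screening and the loss in the summary estimate at that point.
"""

from dtastop import CriterionConfig, SyntheticSpec, gen_pool, run_simulation

ds = gen_pool(SyntheticSpec(n_candidates=800, n_relevant=30, group_sizes=(12,), seed=5))
criteria = [
    CriterionConfig("recall", {"R": 0.95}),
    CriterionConfig("knee"),
    CriterionConfig("relevant_found", {"n": 10}),
    CriterionConfig("found_effort", {"found_delta": 1, "effort_delta": 500}),
    CriterionConfig("displacement_ma2", {"threshold": 0.02}),
]
report = run_simulation(
    ds, methods=("ranked", "random"), criteria=criteria, reps=3, base_seed=11
)
agg = report.aggregate_frame()
cols = ["order_method", "criterion", "triggered_ma", "effort_frac", "recall", "l2_mean"]
print(agg[cols].round(3).to_string(index=False))
# effort_frac: fraction of the pool screened when the criterion fires;
# recall: fraction of relevant references found at that point; l2_mean:
# Euclidean distance of the (sens, spec) estimate from the final estimate
# over all relevant studies. Prioritized order stops far earlier at
# comparable loss; found/effort under random order never fires here
# because relevant references keep trickling in.
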