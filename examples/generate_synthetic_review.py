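"""Generate a synthetic DTA review corpus and inspect its structure.

The generator produces a candidate pool whose relevant references are
enriched for a signal vocabulary shared with the protocol text, plus 2x2
diagnostic accuracy tables drawn from a bivariate logit-normal model.
"""

from dtastop import SyntheticSpec, gen_pool

spec = SyntheticSpec(
    n_candidates=500,
    n_relevant=30,
    group_sizes=(10, 6),
    signal_weight=0.8,
    seed=7,
)
ds = gen_pool(spec)

print(f"pool: {len(ds.pool)} candidate references, {ds.n_relevant} relevant")
print(f"protocol (seed document): {ds.protocol_text[:60]}...")
for g in ds.groups:
    s = g.studies[0]
    print(
        f"meta-analysis {g.ma_id}: {g.n_studies} studies; first 2x2 = "
        f"TP {s.tp}, FP {s.fp}, FN {s.fn}, TN {s.tn}"
    )
# A study's observed sensitivity tp/(tp+fn) scatters around the summary
# value 0.85 because of both binomial sampling and between-study
# heterogeneity (tau = 0.4 on the logit scale).
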