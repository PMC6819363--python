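import numpy as np
import pytest

from dtastop.data_io import MetaAnalysisGroup, ScreeningTrace, TwoByTwo
from dtastop.synthgen import SyntheticSpec, gen_pool


def make_trace(relevant_positions, n_total, seed=0, tag="ranked"):
    """Construct a screening trace with relevant refs at the given 1-based efforts."""
    rel = set(relevant_positions)
    order, fc, relevance = [], [], {}
    found = 0
    for t in range(1, n_total + 1):
        rid = f"d{t:05d}"
        is_rel = t in rel
        found += is_rel
        order.append(rid)
        fc.append(found)
        relevance[rid] = is_rel
    return ScreeningTrace(
        order=tuple(order),
        found_curve=tuple(fc),
        n_total=n_total,
        seed=seed,
        method_tag=tag,
        relevance=relevance,
    )


@pytest.fixture
def identical_group():
    """Three copies of the same study: sens 0.8, spec 0.9, no heterogeneity."""
    return MetaAnalysisGroup(
        "ID3", tuple(TwoByTwo(tp=8, fp=1, fn=2, tn=9, study_ref=f"s{i}") for i in range(3))
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but separable synthetic review for ranking/simulation tests."""
    spec = SyntheticSpec(
        n_candidates=300,
        n_relevant=25,
        group_sizes=(8, 5),
        vocab_size=800,
        doc_length=40,
        signal_weight=0.8,
        seed=11,
    )
    return gen_pool(spec)
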