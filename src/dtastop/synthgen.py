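"""Synthetic review datasets with the structure the simulator assumes.

The generator emulates the two layers of a DTA systematic review corpus:

* **2x2 tables** — each relevant study's per-study (logit sensitivity,
  logit specificity) is drawn from a bivariate normal with stated means,
  between-study SDs and correlation; observed cell counts are binomial given
  the per-study probabilities.  This is exactly the data-generating process
  the bivariate random-effects meta-analysis model postulates.
* **Title/abstract text** — pseudo-word token streams in which relevant
  references are enriched for a small "signal" vocabulary shared with the
  review protocol, so relevance is learnable from unigram/bigram counts.
  ``signal_weight`` is the separability dial: 0 makes relevant and
  irrelevant documents exchangeable, 1 makes them trivially separable.

These are stand-ins for real corpora: the token model produces no natural
language, no citation structure and no publication bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from dtastop.data_io import (
    MetaAnalysisGroup,
    Reference,
    ReviewDataset,
    TwoByTwo,
    ValidationError,
)

__all__ = ["SyntheticSpec", "gen_2x2", "gen_pool"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic review corpus.

    Defaults describe a mid-sized DTA review: a pool of 2000 candidates with
    60 relevant studies, a main meta-analysis of 12 studies plus two smaller
    ones, summary sensitivity 0.85 / specificity 0.92 with moderate
    between-study heterogeneity (tau = 0.4 on the logit scale) and the
    negative sens/spec correlation typical of threshold effects, and 50
    diseased / 50 healthy subjects per study.
    """

    n_candidates: int = 2000
    n_relevant: int = 60
    group_sizes: tuple[int, ...] = (12, 8, 5)
    logit_sens_mean: float = float(logit(0.85))
    logit_spec_mean: float = float(logit(0.92))
    tau_sens: float = 0.4
    tau_spec: float = 0.4
    rho: float = -0.3
    n_diseased: int | tuple[int, int] = 50
    n_healthy: int | tuple[int, int] = 50
    vocab_size: int = 2000
    signal_vocab_size: int = 50
    signal_weight: float = 0.8
    doc_length: int = 60
    title_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant > self.n_candidates:
            raise ValidationError("n_relevant exceeds n_candidates")
        if sum(self.group_sizes) > self.n_relevant:
            raise ValidationError("sum of group_sizes exceeds n_relevant")
        if self.tau_sens < 0 or self.tau_spec < 0:
            raise ValidationError("between-study SDs must be >= 0")
        if abs(self.rho) > 1:
            raise ValidationError("rho must lie in [-1, 1]")
        if not 0 <= self.signal_weight <= 1:
            raise ValidationError("signal_weight must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_size(size: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(size, tuple):
        lo, hi = size
        return int(rng.integers(lo, hi + 1))
    return int(size)


def gen_2x2(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    group_sizes: Optional[Sequence[int]] = None,
    review_id: str = "SYN",
) -> list[MetaAnalysisGroup]:
    """Draw meta-analysis groups from the bivariate logit-normal model.

    For each study i, (logit se_i, logit sp_i) ~ N(mu, T) with
    mu = (logit_sens_mean, logit_spec_mean) and between-study covariance T
    built from (tau_sens, tau_spec, rho); then tp ~ Bin(n_diseased,
    expit(logit se_i)) and tn ~ Bin(n_healthy, expit(logit sp_i)), with
    fn and fp as the complements.
    """
    rng = spec.rng() if rng is None else rng
    sizes = list(spec.group_sizes if group_sizes is None else group_sizes)
    # explicit Cholesky factor of the 2x2 between-study covariance; stays
    # valid for tau = 0 and |rho| = 1 where a generic factorization fails
    rho_c = math.sqrt(max(1.0 - spec.rho**2, 0.0))
    groups = []
    counter = 0
    for gi, size in enumerate(sizes):
        studies = []
        for _ in range(size):
            z1, z2 = rng.standard_normal(2)
            se_logit = spec.logit_sens_mean + spec.tau_sens * z1
            sp_logit = spec.logit_spec_mean + spec.tau_spec * (spec.rho * z1 + rho_c * z2)
            nd = _draw_size(spec.n_diseased, rng)
            nh = _draw_size(spec.n_healthy, rng)
            tp = int(rng.binomial(nd, expit(se_logit)))
            tn = int(rng.binomial(nh, expit(sp_logit)))
            studies.append(
                TwoByTwo(tp=tp, fp=nh - tn, fn=nd - tp, tn=tn, study_ref=f"rel{counter:05d}")
            )
            counter += 1
        groups.append(MetaAnalysisGroup(ma_id=f"M{gi + 1}", studies=tuple(studies), review_id=review_id))
    return groups


def _tokens(
    n: int,
    rng: np.random.Generator,
    vocab_size: int,
    signal_vocab_size: int,
    signal_weight: float,
) -> str:
    """Draw n tokens; each comes from the signal vocabulary with the given weight.

    Background words are ``w...``, signal words ``s...``; the vocabularies
    are disjoint so signal enrichment is unambiguous.
    """
    from_signal = rng.random(n) < signal_weight
    bg = rng.integers(0, vocab_size, size=n)
    sig = rng.integers(0, signal_vocab_size, size=n)
    words = [f"s{sig[i]:04d}" if from_signal[i] else f"w{bg[i]:06d}" for i in range(n)]
    return " ".join(words)


def gen_pool(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None) -> ReviewDataset:
    """Generate a full synthetic review: pool, protocol text and 2x2 groups.

    Relevant references draw each token from the signal vocabulary with
    probability ``signal_weight``; irrelevant references draw from the
    background vocabulary only.  The protocol text is composed from the
    signal vocabulary, so it is informative about relevance exactly when
    ``signal_weight`` > 0.  2x2 groups are attached to distinct relevant
    references (``rel...`` identifiers).
    """
    rng = spec.rng() if rng is None else rng
    groups = gen_2x2(spec, rng)

    relevant_flags = np.zeros(spec.n_candidates, dtype=bool)
    rel_positions = rng.choice(spec.n_candidates, size=spec.n_relevant, replace=False)
    relevant_flags[rel_positions] = True

    protocol_text = _tokens(spec.doc_length, rng, spec.vocab_size, spec.signal_vocab_size, 1.0)

    pool = []
    rel_counter = 0
    irr_counter = 0
    for i in range(spec.n_candidates):
        if relevant_flags[i]:
            ref_id = f"rel{rel_counter:05d}"
            rel_counter += 1
            w = spec.signal_weight
        else:
            ref_id = f"irr{irr_counter:05d}"
            irr_counter += 1
            w = 0.0
        title = _tokens(spec.title_length, rng, spec.vocab_size, spec.signal_vocab_size, w)
        abstract = _tokens(spec.doc_length, rng, spec.vocab_size, spec.signal_vocab_size, w)
        pool.append(
            Reference(
                ref_id=ref_id,
                title=title,
                abstract=abstract,
                is_relevant=bool(relevant_flags[i]),
            )
        )
    return ReviewDataset(
        review_id="SYN",
        pool=tuple(pool),
        protocol_text=protocol_text,
        groups=tuple(groups),
    )
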