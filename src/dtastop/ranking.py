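"""Screening order generation: active-learning prioritization and a random control.

The prioritized order simulates continuous active learning with relevance
feedback: start from the review protocol as a single artificial positive
seed, pad the negative class with pseudo-negatives drawn from the unscreened
pool, refit a regularized logistic model (SGD) on tf-idf weighted
unigram/bigram counts each iteration, and screen the top-scored unscreened
references in batches that grow geometrically (B -> B + ceil(B/10)).

The ranker never stops on its own: a trace always covers the whole pool, and
stopping criteria are applied afterwards by the simulator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from scipy import sparse
from sklearn.feature_extraction import DictVectorizer
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.linear_model import SGDClassifier

from dtastop.data_io import ReviewDataset, ScreeningTrace

__all__ = [
    "ActiveLearnerConfig",
    "batch_schedule",
    "extract_features",
    "rank_active",
    "rank_random",
]

_TOKEN_RE = re.compile(r"\w+")

_DEFAULT_SGD = {
    "alpha": 1e-4,  # L2 regularization strength
    "passes": 5,  # epochs per refit
    "learning_rate": "optimal",
}


@dataclass(frozen=True)
class ActiveLearnerConfig:
    """Knobs of the active-learning screening simulation.

    ``n_pseudo_negatives`` is the floor on the size of the negative class at
    every refit; ``batch_start`` is the size of the first screening batch.
    """

    n_pseudo_negatives: int = 100
    batch_start: int = 1
    feature_mode: str = "uni+bi"
    sgd_params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pseudo_negatives < 1:
            raise ValueError("n_pseudo_negatives must be >= 1")
        if self.batch_start < 1:
            raise ValueError("batch_start must be >= 1")
        merged = dict(_DEFAULT_SGD)
        merged.update(self.sgd_params)
        object.__setattr__(self, "sgd_params", merged)


def batch_schedule(k: int, batch_start: int = 1) -> int:
    """Batch size B_k at iteration k: B_1 = batch_start, B_{k+1} = B_k + ceil(B_k/10)."""
    if k < 1:
        raise ValueError("iteration index must be >= 1")
    b = batch_start
    for _ in range(k - 1):
        b += math.ceil(b / 10)
    return b


def extract_features(title: str, abstract: str = "") -> dict[str, int]:
    """Case-folded unigram and adjacent-bigram counts of title + abstract.

    Tokens come from the concatenated text, so a bigram may span the
    title/abstract boundary; bigram features are rendered ``tok1_tok2``.
    """
    if not title and not abstract:
        raise ValueError("both title and abstract are empty")
    text = f"{title} {abstract}".lower()
    tokens = _TOKEN_RE.findall(text)
    feats: dict[str, int] = {}
    for tok in tokens:
        feats[tok] = feats.get(tok, 0) + 1
    for a, b in zip(tokens, tokens[1:]):
        key = f"{a}_{b}"
        feats[key] = feats.get(key, 0) + 1
    return feats


def _vectorize_pool(dataset: ReviewDataset) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """tf-idf matrix for the pool plus the protocol seed vector in that space.

    Vocabulary and document frequencies come from the pool only; the protocol
    is transformed into the same space (out-of-vocabulary tokens dropped).
    Rows are L2-normalized.
    """
    dicts = [extract_features(r.title, r.abstract) for r in dataset.pool]
    dv = DictVectorizer(sparse=True)
    counts = dv.fit_transform(dicts)
    tfidf = TfidfTransformer(norm="l2", use_idf=True, smooth_idf=True)
    X = tfidf.fit_transform(counts)
    seed_counts = dv.transform([extract_features(dataset.protocol_text)])
    X_seed = tfidf.transform(seed_counts)
    return sparse.csr_matrix(X), sparse.csr_matrix(X_seed)


def _build_trace(dataset: ReviewDataset, order_idx: list[int], seed: int, tag: str) -> ScreeningTrace:
    order = tuple(dataset.pool[i].ref_id for i in order_idx)
    rel = [dataset.pool[i].is_relevant for i in order_idx]
    found = tuple(np.cumsum(np.asarray(rel, dtype=int)).tolist())
    return ScreeningTrace(
        order=order,
        found_curve=found,
        n_total=len(order),
        seed=seed,
        method_tag=tag,
        relevance={dataset.pool[i].ref_id: dataset.pool[i].is_relevant for i in order_idx},
    )


def rank_active(
    dataset: ReviewDataset,
    config: Optional[ActiveLearnerConfig] = None,
    rng: Optional[np.random.Generator] = None,
    audit: Optional[Callable[[int, list[int], list[int], np.ndarray], None]] = None,
) -> ScreeningTrace:
    """Simulate active-learning screening and return the full prioritized order.

    Each iteration k: (1) assemble a training set from all screened
    references with their revealed labels, the protocol seed as a positive
    while no real positive has been screened, and pseudo-negatives sampled
    uniformly (fresh each iteration) from the unscreened pool so that the
    negative class holds at least ``n_pseudo_negatives`` examples; (2) refit
    an L2-regularized logistic model by SGD on tf-idf unigram/bigram
    features; (3) score the unscreened references and screen the top B_k,
    revealing their labels.  Ties in score break by original pool index.

    ``audit``, if given, is called per iteration with (k, training pool
    indices, training labels, indices screened this iteration); index -1
    denotes the protocol seed.  Deterministic given ``config.seed`` (or an
    explicit ``rng``).
    """
    if not dataset.pool:
        raise ValueError("empty pool")
    if not dataset.protocol_text:
        raise ValueError("empty protocol text")
    config = config or ActiveLearnerConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    X, x_seed = _vectorize_pool(dataset)
    n = X.shape[0]
    labels = np.array([r.is_relevant for r in dataset.pool], dtype=bool)

    alpha = float(config.sgd_params["alpha"])
    passes = int(config.sgd_params["passes"])
    lr = str(config.sgd_params["learning_rate"])

    screened: list[int] = []
    screened_mask = np.zeros(n, dtype=bool)
    order_idx: list[int] = []
    k = 0
    batch = config.batch_start
    while len(order_idx) < n:
        k += 1
        unscreened = np.flatnonzero(~screened_mask)
        pos = [i for i in screened if labels[i]]
        neg = [i for i in screened if not labels[i]]
        n_pseudo = min(max(config.n_pseudo_negatives - len(neg), 0), len(unscreened))
        pseudo = rng.choice(unscreened, size=n_pseudo, replace=False).tolist() if n_pseudo else []

        use_seed = len(pos) == 0
        train_idx = ([-1] if use_seed else []) + pos + neg + pseudo
        y = np.array(
            ([1] if use_seed else []) + [1] * len(pos) + [0] * (len(neg) + len(pseudo)), dtype=int
        )

        if y.min() == y.max():
            # degenerate single-class training set: seed-similarity fallback
            scores = (X[unscreened] @ x_seed.T).toarray().ravel()
        else:
            rows = [x_seed if i == -1 else X[i] for i in train_idx]
            X_train = sparse.vstack(rows, format="csr")
            clf = SGDClassifier(
                loss="log_loss",
                penalty="l2",
                alpha=alpha,
                max_iter=passes,
                tol=None,
                learning_rate=lr,
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(X_train, y)
            scores = clf.decision_function(X[unscreened])

        if audit is not None:
            audit(k, list(train_idx), y.tolist(), unscreened)

        take = min(batch, len(unscreened))
        top = unscreened[np.argsort(-scores, kind="stable")[:take]]
        for i in top:
            order_idx.append(int(i))
            screened.append(int(i))
            screened_mask[i] = True
        batch += math.ceil(batch / 10)

    return _build_trace(dataset, order_idx, config.seed, "ranked")


def rank_random(
    dataset: ReviewDataset, rng: Optional[np.random.Generator] = None, seed: int = 0
) -> ScreeningTrace:
    """Uniformly random screening order (the no-technology control)."""
    if not dataset.pool:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed) if rng is None else rng
    order_idx = rng.permutation(len(dataset.pool)).tolist()
    return _build_trace(dataset, order_idx, seed, "random")
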