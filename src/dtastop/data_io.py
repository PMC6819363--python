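"""Domain types and readers/writers for the external formats the tool touches.

The core objects are plain dataclasses shared by every other module: candidate
:class:`Reference` records, per-study 2x2 diagnostic accuracy tables, the
meta-analysis groupings that feed one summary estimate, screening traces, and
the criterion configuration/event records used for reporting.

File formats supported:

* TREC-style qrels (``topic iteration doc_id relevance``) as used by the
  CLEF technology-assisted-review shared task;
* a flat CSV of 2x2 tables, one row per (meta-analysis, study), with header
  ``review_id, ma_id, study_id, tp, fp, fn, tn``;
* a candidate-pool CSV (``ref_id, title, abstract[, source_id]``);
* screening-trace CSV (``position, ref_id, is_relevant``);
* simulation reports as JSON or a Table-1-shaped CSV.

All text I/O is UTF-8.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Reference",
    "TwoByTwo",
    "MetaAnalysisGroup",
    "ReviewDataset",
    "SummaryEstimate",
    "ScreeningTrace",
    "EffortLossCurve",
    "CriterionConfig",
    "CriterionEvent",
    "ParseError",
    "ValidationError",
    "read_qrels",
    "write_qrels",
    "read_2x2_table",
    "write_2x2_table",
    "read_pool_csv",
    "write_pool_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_report",
]

LOSS_KEYS = ("l2", "sens", "spec", "sens_lb", "sens_ub", "spec_lb", "spec_ub")

CRITERION_NAMES = frozenset(
    {
        "recall",
        "knee",
        "loss_effort",
        "relevant_found",
        "found_effort",
        "displacement_ma2",
        "displacement_loocv",
    }
)


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed data violated a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reference:
    """One candidate citation with text and a hidden-until-screened label.

    ``is_relevant`` plays the role of the simulated screener's judgment: the
    ranker only sees it for references that have already been "screened".
    """

    ref_id: str
    title: str
    abstract: str = ""
    is_relevant: bool = False
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.title and not self.abstract:
            raise ValidationError(f"reference {self.ref_id!r}: title and abstract both empty")


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 diagnostic accuracy table: TP/FP/FN/TN counts for one study."""

    tp: int
    fp: int
    fn: int
    tn: int
    study_ref: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name}={v!r} must be a non-negative integer")
        if self.tp + self.fn < 1:
            raise ValidationError("tp + fn must be >= 1 (no diseased subjects)")
        if self.fp + self.tn < 1:
            raise ValidationError("fp + tn must be >= 1 (no non-diseased subjects)")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetaAnalysisGroup:
    """The set S of relevant studies whose 2x2 tables feed one summary estimate."""

    ma_id: str
    studies: tuple[TwoByTwo, ...]
    review_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        refs = [s.study_ref for s in self.studies]
        if len(set(refs)) != len(refs):
            raise ValidationError(f"meta-analysis {self.ma_id!r}: duplicate study_ref")

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def analyzable(self) -> bool:
        """Summary estimates require three or more studies."""
        return self.n_studies >= 3

    def study_refs(self) -> tuple[str, ...]:
        return tuple(s.study_ref for s in self.studies)

    def without(self, index: int) -> "MetaAnalysisGroup":
        """Leave-one-out subgroup, used by the LOOCV displacement."""
        studies = self.studies[:index] + self.studies[index + 1 :]
        return MetaAnalysisGroup(ma_id=f"{self.ma_id}\\{index}", studies=studies, review_id=self.review_id)


@dataclass(frozen=True)
class ReviewDataset:
    """One systematic review: candidate pool, protocol text, meta-analyses."""

    review_id: str
    pool: tuple[Reference, ...]
    protocol_text: str
    groups: tuple[MetaAnalysisGroup, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool", tuple(self.pool))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.pool) < 1:
            raise ValidationError("pool must contain at least one reference")
        ids = [r.ref_id for r in self.pool]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ref_id in pool")
        relevant = {r.ref_id for r in self.pool if r.is_relevant}
        for g in self.groups:
            missing = set(g.study_refs()) - relevant
            if missing:
                raise ValidationError(
                    f"meta-analysis {g.ma_id!r}: study_refs not among relevant pool "
                    f"references: {sorted(missing)}"
                )

    @property
    def n_relevant(self) -> int:
        return sum(r.is_relevant for r in self.pool)

    def reference(self, ref_id: str) -> Reference:
        for r in self.pool:
            if r.ref_id == ref_id:
                return r
        raise KeyError(ref_id)


@dataclass(frozen=True)
class SummaryEstimate:
    """Fitted summary (sensitivity, specificity) with 95% CIs.

    ``logit_means`` holds the bivariate model's logit-scale means and
    ``between_cov`` the 2x2 between-study covariance of the random effects.
    """

    sens: float
    spec: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    logit_means: tuple[float, float]
    between_cov: np.ndarray
    n_studies: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.n_studies < 3:
            raise ValidationError("summary estimate requires >= 3 studies")
        if not (self.sens_ci[0] <= self.sens <= self.sens_ci[1]):
            raise ValidationError("sensitivity outside its own CI")
        if not (self.spec_ci[0] <= self.spec <= self.spec_ci[1]):
            raise ValidationError("specificity outside its own CI")

    @property
    def point(self) -> tuple[float, float]:
        return (self.sens, self.spec)


@dataclass(frozen=True)
class ScreeningTrace:
    """A complete ordering of a review's pool with the found-count curve.

    ``order[t-1]`` is the reference screened at effort t (efforts are
    1-based); ``found_curve[t-1]`` is the cumulative number of relevant
    references identified after screening t references.
    """

    order: tuple[str, ...]
    found_curve: tuple[int, ...]
    n_total: int
    seed: int
    method_tag: str
    relevance: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.order) != self.n_total or len(set(self.order)) != self.n_total:
            raise ValidationError("trace order is not a permutation of the pool")
        if len(self.found_curve) != self.n_total:
            raise ValidationError("found_curve length differs from pool size")
        if any(b < a for a, b in zip(self.found_curve, self.found_curve[1:])):
            raise ValidationError("found_curve must be non-decreasing")

    @property
    def f_total(self) -> int:
        return self.found_curve[-1] if self.found_curve else 0

    def relevant_positions(self) -> tuple[int, ...]:
        """1-based efforts at which relevant references are screened."""
        out = []
        prev = 0
        for t, f in enumerate(self.found_curve, start=1):
            if f > prev:
                out.append(t)
            prev = f
        return tuple(out)

    def position_of(self, ref_id: str) -> int:
        """1-based effort at which ``ref_id`` is screened."""
        return self.order.index(ref_id) + 1


@dataclass(frozen=True)
class EffortLossCurve:
    """(effort, L2 loss) pairs recorded at each summary-estimate update.

    ``monotone_hull`` is the lower convex envelope of the points, restricted
    to be non-increasing; it is what the loss/effort criterion inspects.
    """

    points: tuple[tuple[float, float], ...]
    monotone_hull: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        efforts = [e for e, _ in self.points]
        if any(b <= a for a, b in zip(efforts, efforts[1:])):
            raise ValidationError("efforts must be strictly increasing")


@dataclass(frozen=True)
class CriterionConfig:
    """A stopping criterion's name and its numeric parameters.

    Parameter keys by criterion: recall -> R; loss_effort -> loss_delta,
    effort_delta; relevant_found -> n; found_effort -> found_delta,
    effort_delta[, min_found]; displacement_ma2 / displacement_loocv ->
    threshold; knee -> none.
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)

    _REQUIRED = {
        "recall": ("R",),
        "knee": (),
        "loss_effort": ("loss_delta", "effort_delta"),
        "relevant_found": ("n",),
        "found_effort": ("found_delta", "effort_delta"),
        "displacement_ma2": ("threshold",),
        "displacement_loocv": ("threshold",),
    }

    def __post_init__(self) -> None:
        if self.name not in CRITERION_NAMES:
            raise ValidationError(f"unknown criterion {self.name!r}")
        object.__setattr__(self, "params", dict(self.params))
        for key in self._REQUIRED[self.name]:
            if key not in self.params:
                raise ValidationError(f"criterion {self.name!r} requires parameter {key!r}")
            if not self.params[key] > 0:
                raise ValidationError(f"criterion {self.name!r}: {key} must be > 0")
        if self.name == "recall" and not (0 < self.params["R"] <= 1):
            raise ValidationError("recall criterion requires 0 < R <= 1")

    @property
    def label(self) -> str:
        if not self.params:
            return self.name
        inner = ",".join(f"{k}={v:g}" for k, v in sorted(self.params.items()))
        return f"{self.name}({inner})"


@dataclass(frozen=True)
class CriterionEvent:
    """Where a stopping criterion triggered and the losses measured there."""

    config: CriterionConfig
    triggered: bool
    trigger_effort: Optional[int] = None
    recall_at_trigger: Optional[float] = None
    estimate_at_trigger: Optional[SummaryEstimate] = None
    losses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.triggered and self.trigger_effort is not None:
            raise ValidationError("untriggered event carries a trigger effort")
        object.__setattr__(self, "losses", dict(self.losses))


# ---------------------------------------------------------------------------
# qrels
# ---------------------------------------------------------------------------


def read_qrels(path: str | Path) -> dict[str, dict[str, bool]]:
    """Read TREC-style relevance judgments.

    Each non-blank line carries at least four whitespace-separated fields:
    ``topic iteration doc_id relevance``; the iteration column is ignored and
    a document is relevant iff its relevance integer is positive.  Topics
    with zero relevant documents are retained.
    """
    out: dict[str, dict[str, bool]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 fields, got {len(fields)}")
            topic, _iter, doc_id, rel = fields[0], fields[1], fields[2], fields[3]
            try:
                rel_int = int(rel)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer relevance {rel!r}") from None
            out.setdefault(topic, {})[doc_id] = rel_int > 0
    return out


def write_qrels(qrels: Mapping[str, Mapping[str, bool]], path: str | Path) -> None:
    """Write relevance judgments in the four-column TREC dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for topic in qrels:
            for doc_id, rel in qrels[topic].items():
                fh.write(f"{topic} 0 {doc_id} {1 if rel else 0}\n")


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

_2X2_COLUMNS = ["review_id", "ma_id", "study_id", "tp", "fp", "fn", "tn"]


def read_2x2_table(path: str | Path) -> list[MetaAnalysisGroup]:
    """Read a flat CSV of 2x2 tables, one row per (meta-analysis, study).

    Rows are grouped by (review_id, ma_id); group order follows first
    appearance in the file.  Negative counts and duplicate (ma_id, study_id)
    pairs raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype={"review_id": str, "ma_id": str, "study_id": str})
    missing = set(_2X2_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df[["tp", "fp", "fn", "tn"]] < 0).any().any():
        raise ValidationError(f"{path}: negative count")
    groups: list[MetaAnalysisGroup] = []
    for (review_id, ma_id), sub in df.groupby(["review_id", "ma_id"], sort=False):
        if sub["study_id"].duplicated().any():
            dup = sub.loc[sub["study_id"].duplicated(), "study_id"].iloc[0]
            raise ValidationError(f"{path}: duplicate study {dup!r} in meta-analysis {ma_id!r}")
        studies = tuple(
            TwoByTwo(tp=int(r.tp), fp=int(r.fp), fn=int(r.fn), tn=int(r.tn), study_ref=str(r.study_id))
            for r in sub.itertuples()
        )
        groups.append(MetaAnalysisGroup(ma_id=str(ma_id), studies=studies, review_id=str(review_id)))
    return groups


def write_2x2_table(groups: Iterable[MetaAnalysisGroup], path: str | Path) -> None:
    rows = [
        {
            "review_id": g.review_id,
            "ma_id": g.ma_id,
            "study_id": s.study_ref,
            "tp": s.tp,
            "fp": s.fp,
            "fn": s.fn,
            "tn": s.tn,
        }
        for g in groups
        for s in g.studies
    ]
    pd.DataFrame(rows, columns=_2X2_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Candidate pool and traces
# ---------------------------------------------------------------------------


def read_pool_csv(path: str | Path, qrels_topic: Optional[Mapping[str, bool]] = None) -> list[Reference]:
    """Read a candidate-pool CSV (``ref_id,title,abstract[,source_id]``).

    Relevance labels are taken from ``qrels_topic`` when given (unlisted
    references are treated as irrelevant), otherwise from an optional
    ``is_relevant`` column, otherwise all false.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "ref_id" not in df.columns or "title" not in df.columns:
        raise ParseError(f"{path}: pool CSV needs at least ref_id and title columns")
    refs = []
    for row in df.itertuples():
        rid = str(row.ref_id)
        if qrels_topic is not None:
            rel = bool(qrels_topic.get(rid, False))
        elif "is_relevant" in df.columns:
            rel = str(row.is_relevant).strip().lower() in {"1", "true", "yes"}
        else:
            rel = False
        refs.append(
            Reference(
                ref_id=rid,
                title=str(row.title),
                abstract=str(getattr(row, "abstract", "")),
                is_relevant=rel,
                source_id=str(row.source_id) if "source_id" in df.columns and row.source_id else None,
            )
        )
    return refs


def write_pool_csv(pool: Iterable[Reference], path: str | Path, include_labels: bool = True) -> None:
    cols = ["ref_id", "title", "abstract", "source_id"]
    if include_labels:
        cols.append("is_relevant")
    rows = []
    for r in pool:
        row = {"ref_id": r.ref_id, "title": r.title, "abstract": r.abstract, "source_id": r.source_id or ""}
        if include_labels:
            row["is_relevant"] = int(r.is_relevant)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_trace_csv(trace: ScreeningTrace, path: str | Path) -> None:
    """Write a screening order as CSV (position, ref_id, is_relevant)."""
    prev = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "ref_id", "is_relevant"])
        for t, (rid, f) in enumerate(zip(trace.order, trace.found_curve), start=1):
            w.writerow([t, rid, int(f > prev)])
            prev = f


def read_trace_csv(path: str | Path, seed: int = 0, method_tag: str = "ranked") -> ScreeningTrace:
    df = pd.read_csv(path, dtype={"ref_id": str})
    order = tuple(df.sort_values("position")["ref_id"])
    rel = df.sort_values("position")["is_relevant"].astype(int).to_numpy()
    found = tuple(np.cumsum(rel).tolist())
    return ScreeningTrace(
        order=order,
        found_curve=found,
        n_total=len(order),
        seed=seed,
        method_tag=method_tag,
        relevance={rid: bool(v) for rid, v in zip(order, rel)},
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_CSV_COLUMNS = [
    "order_method",
    "criterion",
    "cutoff",
    "triggered_ma",
    "triggered_sr",
    "effort_abs",
    "effort_frac",
    "recall",
    "l2_mean",
    "sens_loss_mean",
    "sens_lb",
    "sens_ub",
    "spec_loss_mean",
    "spec_lb",
    "spec_ub",
]


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Write a simulation report as JSON or a Table-1-shaped CSV.

    The CSV carries one row per (order method, criterion, cutoff) with the
    triggered counts, mean effort (absolute and as a fraction of the pool),
    mean recall, and the mean point/CI-bound losses over triggered events.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")
    elif format == "csv":
        df = report.aggregate_frame()
        for col in REPORT_CSV_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df[REPORT_CSV_COLUMNS].to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
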