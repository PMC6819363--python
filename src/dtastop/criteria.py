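"""Stopping criteria, losses, displacement series and curve utilities.

Seven criteria decide when screening could be (retrospective) or should be
(prospective) interrupted:

===================  ============  =======================================
criterion            kind          trigger condition
===================  ============  =======================================
recall               retrospective  R-th fraction of relevant found
knee                 retrospective  knee of the effort/loss curve
loss_effort          retrospective  hull slope exceeds -loss_delta/effort_delta
relevant_found       prospective    n relevant studies identified
found_effort         prospective    no relevant among last E/F screened
displacement_ma2     prospective    MA2 of estimate displacement < threshold
displacement_loocv   prospective    median leave-one-out shift < threshold
===================  ============  =======================================

Efforts are 1-based screening positions.  All threshold comparisons are
strict, matching the inequality direction of each criterion's definition.
Prospective criteria are conservative: when their preconditions are never
met (too few relevant studies found), they simply do not trigger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from dtastop.data_io import (
    CriterionConfig,
    CriterionEvent,
    EffortLossCurve,
    MetaAnalysisGroup,
    ScreeningTrace,
    SummaryEstimate,
)
from dtastop.meta_dta import fit_bivariate

__all__ = [
    "DisplacementSeries",
    "l2_loss",
    "displacement",
    "loocv_displacement",
    "monotone_hull",
    "knee_point",
    "trigger_recall",
    "trigger_loss_effort",
    "trigger_relevant_found",
    "trigger_found_effort",
    "trigger_displacement_ma2",
    "trigger_displacement_loocv",
    "trigger_knee",
    "combine_or",
]


@dataclass(frozen=True)
class DisplacementSeries:
    """Per-update displacements of the summary estimate along a trace.

    ``entries`` holds (effort, found-count, displacement) triples; the first
    displacement exists at the 4th identified relevant study (a predecessor
    estimate needs 3).  ``ma2`` holds the window-2 moving average aligned to
    ``entries`` — NaN at the first entry where no full window exists.
    """

    entries: tuple[tuple[int, int, float], ...]
    ma2: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.ma2 and len(self.ma2) != len(self.entries):
            raise ValueError("ma2 must align with entries")

    @staticmethod
    def from_displacements(efforts: Sequence[int], founds: Sequence[int], disps: Sequence[float]) -> "DisplacementSeries":
        entries = tuple(zip(efforts, founds, disps))
        ma2 = tuple(
            float("nan") if i == 0 else (disps[i] + disps[i - 1]) / 2.0 for i in range(len(disps))
        )
        return DisplacementSeries(entries=entries, ma2=ma2)


# ---------------------------------------------------------------------------
# Losses and displacements
# ---------------------------------------------------------------------------


def l2_loss(estimate: tuple[float, float], truth: tuple[float, float]) -> float:
    """Euclidean distance between a (sens, spec) estimate and the truth pair."""
    mu_hat, nu_hat = estimate
    mu, nu = truth
    for v in (mu_hat, nu_hat, mu, nu):
        if not 0 <= v <= 1:
            raise ValueError(f"sensitivity/specificity {v} outside [0, 1]")
    return math.hypot(mu - mu_hat, nu - nu_hat)


def displacement(curr: Optional[SummaryEstimate], prev: Optional[SummaryEstimate]) -> Optional[float]:
    """L2 shift between consecutive summary estimates; None while undefined.

    Undefined until at least three relevant studies have been found for each
    of the two consecutive estimates, i.e. no predecessor exists at the 3rd
    relevant study.
    """
    if curr is None or prev is None:
        return None
    return math.hypot(curr.sens - prev.sens, curr.spec - prev.spec)


def loocv_displacement(group: MetaAnalysisGroup, fit: Optional[Callable] = None) -> Optional[float]:
    """Median L2 shift of the summary estimate under leave-one-out refits.

    Each leave-one-out subset must itself be analyzable, so the value is
    undefined (None) below 4 studies.  With an even number of studies the
    median is the midpoint of the two central order statistics.
    """
    if group.n_studies < 4:
        return None
    fit = fit or (lambda g: fit_bivariate(g).estimate)
    full = fit(group)
    shifts = []
    for i in range(group.n_studies):
        sub = fit(group.without(i))
        shifts.append(math.hypot(full.sens - sub.sens, full.spec - sub.spec))
    return float(np.median(shifts))


# ---------------------------------------------------------------------------
# Curve utilities
# ---------------------------------------------------------------------------


def monotone_hull(points: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Lower convex envelope of an effort/loss curve, restricted to non-increasing.

    Computed by the monotone-chain lower hull (segment slopes non-decreasing);
    any upward-sloping tail after the hull's minimum is discarded so the
    result is monotonously decreasing.  Fewer than 2 points are returned
    unchanged.
    """
    pts = [(float(e), float(l)) for e, l in points]
    if len(pts) < 2:
        return pts
    efforts = [e for e, _ in pts]
    if any(b <= a for a, b in zip(efforts, efforts[1:])):
        raise ValueError("efforts must be strictly increasing")

    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # drop hull[-1] if it lies on or above segment hull[-2] -> p
            if (x2 - x1) * (p[1] - y1) - (p[0] - x1) * (y2 - y1) <= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    # enforce non-increasing: truncate after the minimum
    out = [hull[0]]
    for p in hull[1:]:
        if p[1] > out[-1][1]:
            break
        out.append(p)
    return out


def knee_point(points: Sequence[tuple[float, float]]) -> int:
    """Index of the knee: farthest point from the first-to-last chord.

    Both axes are min-max normalized to [0, 1] first, so the answer does not
    depend on the units of effort or loss; ties break to the smallest index.
    Requires at least 3 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("knee point needs at least 3 points")
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    q = (pts - pts.min(axis=0)) / span
    a, b = q[0], q[-1]
    chord = b - a
    norm = np.hypot(*chord)
    if norm == 0:
        return 0
    # perpendicular distance of each point to the chord
    d = np.abs(chord[0] * (a[1] - q[:, 1]) - (a[0] - q[:, 0]) * chord[1]) / norm
    return int(np.argmax(d))


# ---------------------------------------------------------------------------
# Triggers: each returns the 1-based effort position, or None (no trigger)
# ---------------------------------------------------------------------------


def trigger_recall(trace: ScreeningTrace, R: float) -> Optional[int]:
    """Effort at which recall R is reached: the ceil(R * f_total)-th relevant."""
    if not 0 < R <= 1:
        raise ValueError("R must lie in (0, 1]")
    positions = trace.relevant_positions()
    if not positions:
        return None
    k = math.ceil(R * len(positions))
    return positions[k - 1]


def trigger_loss_effort(curve: EffortLossCurve, loss_delta: float, effort_delta: float) -> Optional[int]:
    """First hull point from which the loss decays slower than loss_delta/effort_delta.

    Scans consecutive hull segments; triggers at the left endpoint of the
    first segment with slope > -loss_delta/effort_delta.
    """
    if loss_delta <= 0 or effort_delta <= 0:
        raise ValueError("loss_delta and effort_delta must be > 0")
    hull = curve.monotone_hull or tuple(monotone_hull(curve.points))
    if len(hull) < 2:
        return None
    limit = -loss_delta / effort_delta
    for (e0, l0), (e1, l1) in zip(hull, hull[1:]):
        if (l1 - l0) / (e1 - e0) > limit:
            return int(e0)
    return None


def trigger_relevant_found(trace: ScreeningTrace, n: int) -> Optional[int]:
    """Effort at which the n-th relevant reference is screened."""
    if n < 1:
        raise ValueError("n must be >= 1")
    positions = trace.relevant_positions()
    if len(positions) < n:
        return None
    return positions[n - 1]


def trigger_found_effort(
    trace: ScreeningTrace, found_delta: float, effort_delta: float, min_found: int = 3
) -> Optional[int]:
    """Trigger when no relevant reference appeared among the last E/F screened.

    Evaluated at every screened reference: triggers at the first effort t at
    or after the ``min_found``-th relevant such that the gap since the last
    relevant reference reaches effort_delta/found_delta.  Never triggers if
    the pool is exhausted first, or if fewer than ``min_found`` relevant
    references exist in the trace.
    """
    if found_delta <= 0 or effort_delta <= 0:
        raise ValueError("found_delta and effort_delta must be > 0")
    if min_found < 0:
        raise ValueError("min_found must be >= 0")
    gap = effort_delta / found_delta
    positions = trace.relevant_positions()
    if len(positions) < min_found:
        return None
    earliest = positions[min_found - 1] if min_found >= 1 else 1
    last_rel = 0
    rel_set = set(positions)
    for t in range(1, trace.n_total + 1):
        if t in rel_set:
            last_rel = t
        if t >= earliest and t - last_rel >= gap:
            return t
    return None


def trigger_displacement_ma2(series: DisplacementSeries, threshold: float) -> Optional[int]:
    """Effort of the first entry whose window-2 displacement average < threshold.

    The MA2 needs two displacements, hence at least five identified relevant
    studies; shorter series never trigger.  The comparison is strict, so a
    zero threshold never triggers.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    for (effort, _found, _d), m in zip(series.entries, series.ma2):
        if not math.isnan(m) and m < threshold:
            return int(effort)
    return None


def trigger_displacement_loocv(
    found_groups: Sequence[tuple[int, MetaAnalysisGroup]],
    threshold: float,
    fit: Optional[Callable] = None,
) -> Optional[int]:
    """Trigger when the LOOCV displacement of the found set falls below threshold.

    ``found_groups`` pairs each relevant-found event's effort with the group
    of studies identified so far; events with fewer than 4 studies are
    skipped (each leave-one-out subset must be analyzable).  The comparison
    is strict, so a zero threshold never triggers.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    for effort, group in found_groups:
        d = loocv_displacement(group, fit=fit)
        if d is not None and d < threshold:
            return int(effort)
    return None


def trigger_knee(curve: EffortLossCurve) -> Optional[int]:
    """Effort of the knee of the (raw) effort/loss curve; None below 3 points."""
    if len(curve.points) < 3:
        return None
    idx = knee_point(curve.points)
    return int(curve.points[idx][0])


def combine_or(events: Sequence[CriterionEvent]) -> CriterionEvent:
    """OR-combination: triggered iff any member triggered, at the earliest effort.

    The returned event carries the config of the member that triggered
    first; losses are not recomputed here (the simulator re-evaluates them
    at the combined effort).
    """
    if not events:
        raise ValueError("combine_or needs at least one event")
    fired = [e for e in events if e.triggered]
    if not fired:
        return CriterionEvent(config=events[0].config, triggered=False)
    winner = min(fired, key=lambda e: e.trigger_effort)
    return CriterionEvent(
        config=winner.config,
        triggered=True,
        trigger_effort=winner.trigger_effort,
        recall_at_trigger=winner.recall_at_trigger,
        estimate_at_trigger=winner.estimate_at_trigger,
        losses=dict(winner.losses),
    )
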