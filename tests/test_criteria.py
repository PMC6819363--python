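"""Stopping criteria, curve utilities, and their independent oracles."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtastop.criteria import (
    DisplacementSeries,
    combine_or,
    displacement,
    knee_point,
    l2_loss,
    loocv_displacement,
    monotone_hull,
    trigger_displacement_loocv,
    trigger_displacement_ma2,
    trigger_found_effort,
    trigger_knee,
    trigger_loss_effort,
    trigger_recall,
    trigger_relevant_found,
)
from dtastop.data_io import (
    CriterionConfig,
    CriterionEvent,
    EffortLossCurve,
    MetaAnalysisGroup,
    SummaryEstimate,
    TwoByTwo,
)
from dtastop.meta_dta import fit_bivariate
from dtastop.synthgen import SyntheticSpec, gen_2x2

from conftest import make_trace


def mk_est(sens, spec):
    return SummaryEstimate(
        sens=sens,
        spec=spec,
        sens_ci=(max(sens - 0.2, 0.0), min(sens + 0.2, 1.0)),
        spec_ci=(max(spec - 0.2, 0.0), min(spec + 0.2, 1.0)),
        logit_means=(0.0, 0.0),
        between_cov=np.zeros((2, 2)),
        n_studies=3,
    )


# ---------------------------------------------------------------------------
# Oracles, written from the definitions
# ---------------------------------------------------------------------------


def hull_oracle(points):
    """Lower convex envelope by greedy minimum-slope selection, then
    truncated once slopes turn positive."""
    pts = [(float(e), float(l)) for e, l in points]
    if len(pts) < 2:
        return pts
    hull = [pts[0]]
    i = 0
    while i < len(pts) - 1:
        slopes = [
            ((pts[j][1] - pts[i][1]) / (pts[j][0] - pts[i][0]), j)
            for j in range(i + 1, len(pts))
        ]
        min_slope = min(s for s, _ in slopes)
        # farthest point attaining the minimal slope (skips collinear interiors)
        j = max(j for s, j in slopes if s == min_slope)
        if min_slope > 0:
            break
        hull.append(pts[j])
        i = j
    return hull


def knee_oracle(points):
    pts = np.asarray(points, dtype=float)
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    q = (pts - pts.min(axis=0)) / span
    p0, p1 = q[0], q[-1]
    L = math.hypot(*(p1 - p0))
    best, best_d = 0, -1.0
    for i, p in enumerate(q):
        if L == 0:
            d = 0.0
        else:
            d = abs((p1[0] - p0[0]) * (p0[1] - p[1]) - (p0[0] - p[0]) * (p1[1] - p0[1])) / L
        if d > best_d + 1e-12:
            best, best_d = i, d
    return best


def found_effort_oracle(positions, n_total, F, E, min_found):
    """Slope formulation: consecutive found-events whose slope 1/gap < F/E."""
    gap = E / F
    events = ([0] if min_found == 0 else []) + list(positions)
    candidates = []
    for j, p in enumerate(events):
        rank = j if min_found == 0 else j + 1
        if rank < min_found:
            continue
        stop = p + math.ceil(gap) if gap != int(gap) else p + int(gap)
        nxt = events[j + 1] if j + 1 < len(events) else None
        if nxt is not None and nxt <= stop:
            continue  # a new relevant arrives before the gap elapses
        if stop > n_total:
            continue  # screening ends first
        candidates.append(stop)
    return min(candidates) if candidates else None


def loocv_oracle(group):
    full = fit_bivariate(group).estimate
    shifts = []
    for i in range(group.n_studies):
        rest = group.studies[:i] + group.studies[i + 1 :]
        sub = fit_bivariate(MetaAnalysisGroup("sub", rest)).estimate
        shifts.append(math.hypot(full.sens - sub.sens, full.spec - sub.spec))
    return statistics.median(shifts)


# ---------------------------------------------------------------------------
# L2 loss and displacement
# ---------------------------------------------------------------------------


class TestLosses:
    @pytest.mark.parametrize(
        "est,truth,expected",
        [
            ((0.8, 0.9), (0.8, 0.9), 0.0),
            ((0.83, 0.86), (0.8, 0.9), 0.05),
            ((0.0, 1.0), (1.0, 0.0), math.sqrt(2)),
        ],
    )
    def test_l2_examples(self, est, truth, expected):
        assert l2_loss(est, truth) == pytest.approx(expected)

    def test_l2_domain_check(self):
        with pytest.raises(ValueError):
            l2_loss((1.2, 0.5), (0.5, 0.5))

    def test_displacement_examples(self):
        assert displacement(mk_est(0.8, 0.9), mk_est(0.8, 0.9)) == 0.0
        assert displacement(mk_est(0.75, 0.80), mk_est(0.72, 0.84)) == pytest.approx(0.05)

    def test_displacement_undefined_without_predecessor(self):
        assert displacement(mk_est(0.8, 0.9), None) is None


class TestLoocvDisplacement:
    def test_identical_studies_zero(self):
        g = MetaAnalysisGroup(
            "M", tuple(TwoByTwo(8, 1, 2, 9, f"s{i}") for i in range(5))
        )
        assert loocv_displacement(g) == pytest.approx(0.0, abs=1e-9)

    def test_below_four_studies_undefined(self, identical_group):
        assert loocv_displacement(identical_group) is None

    def test_matches_naive_oracle_six_studies(self):
        spec = SyntheticSpec(n_candidates=10, n_relevant=6, group_sizes=(6,), seed=17)
        g = gen_2x2(spec)[0]
        assert loocv_displacement(g) == pytest.approx(loocv_oracle(g), abs=1e-9)

    def test_even_count_median_is_midpoint(self):
        spec = SyntheticSpec(n_candidates=10, n_relevant=4, group_sizes=(4,), seed=23)
        g = gen_2x2(spec)[0]
        full = fit_bivariate(g).estimate
        shifts = sorted(
            math.hypot(
                full.sens - fit_bivariate(g.without(i)).estimate.sens,
                full.spec - fit_bivariate(g.without(i)).estimate.spec,
            )
            for i in range(4)
        )
        assert loocv_displacement(g) == pytest.approx((shifts[1] + shifts[2]) / 2, abs=1e-9)


# ---------------------------------------------------------------------------
# Curve utilities
# ---------------------------------------------------------------------------


class TestMonotoneHull:
    def test_convex_decreasing_curve_is_fixed_point(self):
        pts = [(0, 0.5), (100, 0.1), (300, 0.09)]
        assert monotone_hull(pts) == [(0.0, 0.5), (100.0, 0.1), (300.0, 0.09)]

    def test_upward_bump_removed(self):
        assert monotone_hull([(0, 0.5), (1, 0.6), (2, 0.1)]) == [(0.0, 0.5), (2.0, 0.1)]

    def test_short_input_unchanged(self):
        assert monotone_hull([(1, 0.3)]) == [(1.0, 0.3)]

    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=2, max_size=30)
    )
    @settings(deadline=None, derandomize=True)
    def test_slopes_non_decreasing_and_curve_non_increasing(self, losses):
        pts = [(float(i), l) for i, l in enumerate(losses)]
        hull = monotone_hull(pts)
        slopes = [
            (l1 - l0) / (e1 - e0) for (e0, l0), (e1, l1) in zip(hull, hull[1:])
        ]
        assert all(b >= a - 1e-9 for a, b in zip(slopes, slopes[1:]))
        assert all(s <= 1e-9 for s in slopes)
        assert set(hull) <= set(pts)

    def test_matches_oracle_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 25))
            pts = list(zip(np.sort(rng.choice(1000, n, replace=False)), rng.random(n)))
            got, want = monotone_hull(pts), hull_oracle(pts)
            assert len(got) == len(want)
            assert np.allclose(np.asarray(got), np.asarray(want))


class TestKneePoint:
    def test_collinear_returns_first_index(self):
        assert knee_point([(0, 1.0), (1, 0.5), (2, 0.0)]) == 0

    def test_l_curve_knee_at_middle(self):
        assert knee_point([(0, 1.0), (0.1, 0.05), (1.0, 0.0)]) == 1

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            knee_point([(0, 1), (1, 0)])

    def test_matches_oracle_on_random_decreasing_curves(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            e = np.sort(rng.choice(5000, n, replace=False)).astype(float)
            l = np.sort(rng.random(n))[::-1]
            pts = list(zip(e, l))
            assert knee_point(pts) == knee_oracle(pts)


# ---------------------------------------------------------------------------
# Triggers
# ---------------------------------------------------------------------------


class TestTriggerRecall:
    def test_r95_of_twenty_is_nineteenth(self):
        trace = make_trace(range(10, 210, 10), n_total=300)  # 20 relevant
        assert trigger_recall(trace, 0.95) == 190

    def test_full_recall_is_last_relevant(self):
        trace = make_trace([5, 50, 200], n_total=300)
        assert trigger_recall(trace, 1.0) == 200

    def test_single_relevant(self):
        trace = make_trace([42], n_total=100)
        assert trigger_recall(trace, 0.95) == 42

    def test_no_relevant_never_triggers(self):
        trace = make_trace([], n_total=50)
        assert trigger_recall(trace, 0.95) is None

    @given(st.floats(0.05, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_R(self, r):
        trace = make_trace([3, 10, 20, 40, 80], n_total=100)
        assert trigger_recall(trace, r) <= trigger_recall(trace, 1.0)
        if r >= 0.5:
            assert trigger_recall(trace, r) >= trigger_recall(trace, r / 2)


class TestTriggerLossEffort:
    def _curve(self, pts):
        return EffortLossCurve(points=tuple(pts), monotone_hull=tuple(pts))

    def test_printed_toy_hull(self):
        curve = self._curve([(0, 0.5), (100, 0.1), (300, 0.09)])
        assert trigger_loss_effort(curve, loss_delta=0.001, effort_delta=1) == 100

    def test_all_slopes_steep_no_trigger(self):
        curve = self._curve([(0, 0.5), (10, 0.1), (20, 0.0)])
        assert trigger_loss_effort(curve, loss_delta=0.5, effort_delta=1000) is None

    def test_flat_tail_triggers_at_its_start(self):
        curve = self._curve([(0, 0.5), (50, 0.2), (100, 0.2)])
        assert trigger_loss_effort(curve, loss_delta=0.01, effort_delta=1000) == 50

    def test_short_hull_no_trigger(self):
        assert trigger_loss_effort(self._curve([(5, 0.1)]), 0.01, 1000) is None


class TestTriggerRelevantFound:
    def test_trigger_at_nth(self):
        trace = make_trace([2, 5, 9], n_total=20)
        assert trigger_relevant_found(trace, 2) == 5

    def test_not_enough_relevant(self):
        trace = make_trace([1, 2, 3, 4, 5, 6, 7], n_total=20)
        assert trigger_relevant_found(trace, 10) is None

    def test_first_relevant(self):
        trace = make_trace([4], n_total=20)
        assert trigger_relevant_found(trace, 1) == 4


class TestTriggerFoundEffort:
    def test_constant_penalty_after_last_relevant(self):
        trace = make_trace([1, 2, 3], n_total=600)
        assert trigger_found_effort(trace, 1, 500, min_found=3) == 503

    def test_gap_not_reached_then_reached(self):
        trace = make_trace([1, 400], n_total=1000)
        assert trigger_found_effort(trace, 1, 500, min_found=2) == 900

    def test_pool_exhausted_first(self):
        trace = make_trace([550], n_total=600)
        assert trigger_found_effort(trace, 1, 500, min_found=1) is None

    def test_matches_slope_oracle_on_random_traces(self):
        from conftest import make_trace as mk

        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(20, 400))
            n_rel = int(rng.integers(0, max(n // 4, 1)))
            pos = sorted(rng.choice(np.arange(1, n + 1), n_rel, replace=False).tolist())
            trace = mk(pos, n_total=n)
            F, E = 1, float(rng.integers(2, 120))
            mf = int(rng.integers(0, 4))
            got = trigger_found_effort(trace, F, E, min_found=mf)
            assert got == found_effort_oracle(pos, n, F, E, mf)

    @pytest.mark.parametrize("gap_pair", [(500, 1000), (100, 200)])
    def test_larger_gap_never_triggers_earlier(self, gap_pair):
        trace = make_trace([1, 5, 9, 300], n_total=2000)
        small, large = gap_pair
        a = trigger_found_effort(trace, 1, small, min_found=3)
        b = trigger_found_effort(trace, 1, large, min_found=3)
        if b is not None:
            assert a is not None and a <= b


class TestTriggerDisplacement:
    def test_ma2_above_threshold_no_trigger(self):
        series = DisplacementSeries.from_displacements([120, 140], [4, 5], [0.05, 0.019])
        assert trigger_displacement_ma2(series, 0.02) is None

    def test_ma2_triggers_at_second_displacement(self):
        series = DisplacementSeries.from_displacements([120, 140], [4, 5], [0.01, 0.01])
        assert trigger_displacement_ma2(series, 0.02) == 140

    def test_all_zero_displacements_trigger_immediately(self):
        series = DisplacementSeries.from_displacements([10, 20, 30], [4, 5, 6], [0.0, 0.0, 0.0])
        assert trigger_displacement_ma2(series, 1e-9) == 20

    def test_single_displacement_is_not_enough(self):
        # MA2 needs a full window: >= 5 identified relevant studies
        series = DisplacementSeries.from_displacements([120], [4], [0.001])
        assert trigger_displacement_ma2(series, 0.02) is None

    def test_stricter_threshold_never_earlier(self):
        rng = np.random.default_rng(11)
        d = rng.random(12) * 0.05
        series = DisplacementSeries.from_displacements(
            list(range(10, 130, 10)), list(range(4, 16)), d.tolist()
        )
        loose = trigger_displacement_ma2(series, 0.04)
        strict = trigger_displacement_ma2(series, 0.005)
        if strict is not None:
            assert loose is not None and loose <= strict

    def test_loocv_identical_studies_triggers_at_fourth(self):
        studies = tuple(TwoByTwo(8, 1, 2, 9, f"s{i}") for i in range(6))
        found_groups = [
            (10 * k, MetaAnalysisGroup("M", studies[:k])) for k in range(3, 7)
        ]
        assert trigger_displacement_loocv(found_groups, 1e-6) == 40

    def test_loocv_zero_threshold_never_triggers(self):
        # strict inequality: a zero LOOCV displacement does not beat threshold 0
        studies = tuple(TwoByTwo(8, 1, 2, 9, f"s{i}") for i in range(5))
        found_groups = [(50, MetaAnalysisGroup("M", studies))]
        assert trigger_displacement_loocv(found_groups, 0.0) is None


class TestTriggerKnee:
    def test_delegates_to_knee_point(self):
        curve = EffortLossCurve(points=((10, 1.0), (20, 0.05), (200, 0.0)))
        assert trigger_knee(curve) == 20

    def test_collinear_triggers_at_first_point(self):
        curve = EffortLossCurve(points=((10, 1.0), (20, 0.5), (30, 0.0)))
        assert trigger_knee(curve) == 10

    def test_too_short_no_trigger(self):
        curve = EffortLossCurve(points=((10, 1.0), (20, 0.5)))
        assert trigger_knee(curve) is None


class TestCombineOr:
    def _event(self, effort):
        cfg = CriterionConfig("relevant_found", {"n": 3})
        if effort is None:
            return CriterionEvent(config=cfg, triggered=False)
        return CriterionEvent(
            config=cfg, triggered=True, trigger_effort=effort, recall_at_trigger=0.5
        )

    def test_single_trigger_wins(self):
        ev = combine_or([self._event(None), self._event(500)])
        assert ev.triggered and ev.trigger_effort == 500

    def test_earliest_wins(self):
        ev = combine_or([self._event(300), self._event(500)])
        assert ev.trigger_effort == 300

    def test_all_silent(self):
        ev = combine_or([self._event(None), self._event(None)])
        assert not ev.triggered and ev.trigger_effort is None


class TestConservatism:
    """Prospective criteria never fire when too few relevant studies exist."""

    def test_two_relevant_studies_nothing_prospective_triggers(self):
        trace = make_trace([3, 7], n_total=150)
        assert trigger_relevant_found(trace, 3) is None
        assert trigger_found_effort(trace, 1, 50, min_found=3) is None
        empty = DisplacementSeries.from_displacements([], [], [])
        assert trigger_displacement_ma2(empty, 0.02) is None
        assert trigger_displacement_loocv([], 0.02) is None

    def test_ma2_needs_five_relevant(self):
        series = DisplacementSeries.from_displacements([40], [4], [0.0])
        assert trigger_displacement_ma2(series, 0.5) is None
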