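"""Screening replays: incremental meta-analysis, criterion evaluation, reporting.

The simulator walks a screening trace, refits the bivariate model on the
identified studies of each meta-analysis every time one more of them is
screened, records the effort/loss curve and displacement series against the
"truth" (the estimate over all relevant studies), evaluates every configured
stopping criterion, and aggregates Table-style summaries over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from dtastop.criteria import (
    DisplacementSeries,
    combine_or,
    l2_loss,
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
    ReviewDataset,
    ScreeningTrace,
    SummaryEstimate,
)
from dtastop.meta_dta import fit_bivariate
from dtastop.ranking import ActiveLearnerConfig, rank_active, rank_random

__all__ = [
    "TraceAnalysis",
    "SimulationReport",
    "effort_loss_trace",
    "evaluate_criterion",
    "run_simulation",
    "percentile_bands",
    "displacement_loss_correlation",
]


@dataclass(frozen=True)
class TraceAnalysis:
    """Everything the criteria need about one (trace, meta-analysis) pair.

    Iterable as ``curve, series = analysis`` for convenience.
    """

    curve: EffortLossCurve
    series: DisplacementSeries
    truth: SummaryEstimate
    estimates: tuple[tuple[int, int, SummaryEstimate], ...]  # (effort, n found, estimate)
    found_groups: tuple[tuple[int, MetaAnalysisGroup], ...]  # per found event, >= 3 studies
    n_skipped: int = 0  # update points dropped for non-convergence

    def __iter__(self):
        return iter((self.curve, self.series))

    def estimate_at(self, effort: int) -> Optional[SummaryEstimate]:
        """Last summary estimate available at or before the given effort."""
        out = None
        for e, _f, est in self.estimates:
            if e <= effort:
                out = est
            else:
                break
        return out


def effort_loss_trace(trace: ScreeningTrace, group: MetaAnalysisGroup, **fit_kwargs) -> TraceAnalysis:
    """Replay a trace against one meta-analysis group.

    At each newly screened study of the group with at least 3 found so far,
    the bivariate model is refit on the found studies; the effort/loss curve
    records the L2 distance to the truth estimate (full group), and the
    displacement series records the shift between consecutive estimates.
    Non-converged refits are skipped (no curve/series entry) and tallied in
    ``n_skipped``.
    """
    if not group.analyzable:
        raise ValueError(f"meta-analysis {group.ma_id!r} is not analyzable")
    by_ref = {s.study_ref: s for s in group.studies}
    missing = set(by_ref) - set(trace.order)
    if missing:
        raise ValueError(f"group studies absent from trace: {sorted(missing)}")
    truth = fit_bivariate(group, **fit_kwargs).estimate

    found: list = []
    estimates: list[tuple[int, int, SummaryEstimate]] = []
    found_groups: list[tuple[int, MetaAnalysisGroup]] = []
    disp_efforts: list[int] = []
    disp_found: list[int] = []
    disps: list[float] = []
    points: list[tuple[float, float]] = []
    n_skipped = 0
    prev_est: Optional[SummaryEstimate] = None

    for t, ref_id in enumerate(trace.order, start=1):
        study = by_ref.get(ref_id)
        if study is None:
            continue
        found.append(study)
        if len(found) < 3:
            continue
        sub = MetaAnalysisGroup(ma_id=group.ma_id, studies=tuple(found), review_id=group.review_id)
        found_groups.append((t, sub))
        est = fit_bivariate(sub, **fit_kwargs).estimate
        if not est.converged:
            n_skipped += 1
            continue
        estimates.append((t, len(found), est))
        points.append((float(t), l2_loss(est.point, truth.point)))
        if prev_est is not None:
            disp_efforts.append(t)
            disp_found.append(len(found))
            disps.append(math.hypot(est.sens - prev_est.sens, est.spec - prev_est.spec))
        prev_est = est

    curve = EffortLossCurve(points=tuple(points), monotone_hull=tuple(monotone_hull(points)))
    series = DisplacementSeries.from_displacements(disp_efforts, disp_found, disps)
    return TraceAnalysis(
        curve=curve,
        series=series,
        truth=truth,
        estimates=tuple(estimates),
        found_groups=tuple(found_groups),
        n_skipped=n_skipped,
    )


def _losses(est: Optional[SummaryEstimate], truth: SummaryEstimate) -> dict[str, float]:
    if est is None:
        return {}
    return {
        "l2": l2_loss(est.point, truth.point),
        "sens": abs(est.sens - truth.sens),
        "spec": abs(est.spec - truth.spec),
        "sens_lb": abs(est.sens_ci[0] - truth.sens_ci[0]),
        "sens_ub": abs(est.sens_ci[1] - truth.sens_ci[1]),
        "spec_lb": abs(est.spec_ci[0] - truth.spec_ci[0]),
        "spec_ub": abs(est.spec_ci[1] - truth.spec_ci[1]),
    }


def _event_at_effort(
    config: CriterionConfig, effort: Optional[int], trace: ScreeningTrace, analysis: TraceAnalysis
) -> CriterionEvent:
    if effort is None:
        return CriterionEvent(config=config, triggered=False)
    est = analysis.estimate_at(effort)
    recall = trace.found_curve[effort - 1] / trace.f_total if trace.f_total else 0.0
    return CriterionEvent(
        config=config,
        triggered=True,
        trigger_effort=int(effort),
        recall_at_trigger=float(recall),
        estimate_at_trigger=est,
        losses=_losses(est, analysis.truth),
    )


def evaluate_criterion(
    config: CriterionConfig, trace: ScreeningTrace, analysis: TraceAnalysis
) -> CriterionEvent:
    """Evaluate one stopping criterion on a replayed trace."""
    p = config.params
    if config.name == "recall":
        effort = trigger_recall(trace, p["R"])
    elif config.name == "knee":
        effort = trigger_knee(analysis.curve)
    elif config.name == "loss_effort":
        effort = trigger_loss_effort(analysis.curve, p["loss_delta"], p["effort_delta"])
    elif config.name == "relevant_found":
        effort = trigger_relevant_found(trace, int(p["n"]))
    elif config.name == "found_effort":
        effort = trigger_found_effort(
            trace, p["found_delta"], p["effort_delta"], int(p.get("min_found", 3))
        )
    elif config.name == "displacement_ma2":
        effort = trigger_displacement_ma2(analysis.series, p["threshold"])
    elif config.name == "displacement_loocv":
        effort = trigger_displacement_loocv(analysis.found_groups, p["threshold"])
    else:  # pragma: no cover - CriterionConfig already validates
        raise ValueError(config.name)
    return _event_at_effort(config, effort, trace, analysis)


@dataclass
class SimulationReport:
    """Per-event records plus replicate-layer aggregates of a simulation run.

    ``events`` holds one flat record per (order method, replicate,
    meta-analysis, criterion).  Aggregation first averages triggered events
    within each replicate, then across replicates; ``triggered_ma`` counts
    triggered (replicate, meta-analysis) events and ``triggered_sr`` counts
    replicates in which the criterion triggered for every analyzable
    meta-analysis of the review.
    """

    review_id: str
    n_pool: int
    n_relevant: int
    n_groups: int
    base_seed: int
    reps: Mapping[str, int]
    events: list[dict] = field(default_factory=list)
    curves: list[dict] = field(default_factory=list)
    excluded: bool = False

    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)

    def aggregate_frame(self) -> pd.DataFrame:
        """Table-1-shaped aggregates: one row per (order method, criterion)."""
        cols = [
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
        if not self.events:
            return pd.DataFrame(columns=cols)
        df = self.event_frame()
        rows = []
        mean_keys = {
            "effort_abs": "trigger_effort",
            "effort_frac": "effort_frac",
            "recall": "recall_at_trigger",
            "l2_mean": "loss_l2",
            "sens_loss_mean": "loss_sens",
            "sens_lb": "loss_sens_lb",
            "sens_ub": "loss_sens_ub",
            "spec_loss_mean": "loss_spec",
            "spec_lb": "loss_spec_lb",
            "spec_ub": "loss_spec_ub",
        }
        for (method, label), sub in df.groupby(["order_method", "criterion"], sort=True):
            trig = sub[sub["triggered"]]
            per_rep_all = sub.groupby("replicate")["triggered"].all()
            row = {
                "order_method": method,
                "criterion": label,
                "cutoff": sub["cutoff"].iloc[0],
                "triggered_ma": int(sub["triggered"].sum()),
                "triggered_sr": int(per_rep_all.sum()),
            }
            for out_key, col in mean_keys.items():
                if len(trig) and col in trig:
                    rep_means = trig.groupby("replicate")[col].mean()
                    row[out_key] = float(rep_means.mean())
                else:
                    row[out_key] = float("nan")
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)

    def to_dict(self) -> dict:
        agg = self.aggregate_frame()
        return {
            "review_id": self.review_id,
            "n_pool": self.n_pool,
            "n_relevant": self.n_relevant,
            "n_groups": self.n_groups,
            "base_seed": self.base_seed,
            "reps": dict(self.reps),
            "excluded": self.excluded,
            "events": self.events,
            "aggregates": agg.to_dict(orient="records"),
        }


def _derived_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_simulation(
    dataset: ReviewDataset,
    methods: Sequence[str] = ("ranked", "random"),
    criteria: Sequence[CriterionConfig] = (),
    combined: Optional[Mapping[str, Sequence[CriterionConfig]]] = None,
    reps: int | Mapping[str, int] = 1,
    base_seed: int = 0,
    learner_config: Optional[ActiveLearnerConfig] = None,
    keep_curves: bool = True,
    **fit_kwargs,
) -> SimulationReport:
    """Replay screening ``reps`` times per method and evaluate all criteria.

    ``combined`` maps a name to a list of member criteria evaluated as an
    OR-combination (triggered at the earliest member effort, with losses
    recomputed at that effort).  Fully reproducible from ``base_seed``.
    """
    if isinstance(reps, int):
        reps = {m: reps for m in methods}
    groups = [g for g in dataset.groups if g.analyzable]
    report = SimulationReport(
        review_id=dataset.review_id,
        n_pool=len(dataset.pool),
        n_relevant=dataset.n_relevant,
        n_groups=len(groups),
        base_seed=base_seed,
        reps={m: int(reps[m]) for m in methods},
        excluded=not groups,
    )
    if not groups:
        return report

    root = np.random.SeedSequence(base_seed)
    children = root.spawn(len(methods))
    combined = dict(combined or {})

    for method, method_ss in zip(methods, children):
        rep_seeds = method_ss.spawn(int(reps[method]))
        for rep, rep_ss in enumerate(rep_seeds):
            seed = _derived_seed(rep_ss)
            if method == "ranked":
                cfg = learner_config or ActiveLearnerConfig()
                cfg = ActiveLearnerConfig(
                    n_pseudo_negatives=cfg.n_pseudo_negatives,
                    batch_start=cfg.batch_start,
                    feature_mode=cfg.feature_mode,
                    sgd_params=cfg.sgd_params,
                    seed=seed,
                )
                trace = rank_active(dataset, cfg)
            elif method == "random":
                trace = rank_random(dataset, seed=seed)
            else:
                raise ValueError(f"unknown order method {method!r}")

            for group in groups:
                analysis = effort_loss_trace(trace, group, **fit_kwargs)
                if keep_curves:
                    report.curves.append(
                        {
                            "order_method": method,
                            "replicate": rep,
                            "ma_id": group.ma_id,
                            "efforts": [int(e) for e, _f, _est in analysis.estimates],
                            "found": [int(f) for _e, f, _est in analysis.estimates],
                            "sens": [est.sens for _e, _f, est in analysis.estimates],
                            "spec": [est.spec for _e, _f, est in analysis.estimates],
                            "l2": [l for _e, l in analysis.curve.points],
                            "disp_efforts": [int(e) for e, _f, _d in analysis.series.entries],
                            "disp": [d for _e, _f, d in analysis.series.entries],
                            "disp_ma2": list(analysis.series.ma2),
                            "n_skipped": analysis.n_skipped,
                        }
                    )
                events: dict[str, CriterionEvent] = {}
                for config in criteria:
                    events[config.label] = evaluate_criterion(config, trace, analysis)
                for name, members in combined.items():
                    member_events = [
                        events.get(c.label) or evaluate_criterion(c, trace, analysis)
                        for c in members
                    ]
                    merged = combine_or(member_events)
                    events[name] = _event_at_effort(
                        CriterionConfig(name=merged.config.name, params=merged.config.params),
                        merged.trigger_effort,
                        trace,
                        analysis,
                    )
                for label, ev in events.items():
                    rec = {
                        "order_method": method,
                        "replicate": rep,
                        "seed": seed,
                        "ma_id": group.ma_id,
                        "criterion": label,
                        "cutoff": _cutoff_string(ev.config),
                        "triggered": ev.triggered,
                        "trigger_effort": ev.trigger_effort,
                        "effort_frac": (
                            ev.trigger_effort / trace.n_total if ev.triggered else None
                        ),
                        "recall_at_trigger": ev.recall_at_trigger,
                    }
                    for key, val in ev.losses.items():
                        rec[f"loss_{key}"] = val
                    report.events.append(rec)
    return report


def _cutoff_string(config: CriterionConfig) -> str:
    return ",".join(f"{k}={v:g}" for k, v in sorted(config.params.items()))


def percentile_bands(
    curves: Sequence[Mapping], percentiles: Sequence[float] = (25, 50, 75)
) -> dict:
    """Per-effort percentile envelopes of the sens/spec estimates.

    Replicate trajectories are step-interpolated onto the union of their
    update efforts (estimates are constant between updates); efforts before
    a replicate's first update contribute nothing there (NaN-aware
    percentiles).  Returns ``{"efforts": grid, "sens": {p: values},
    "spec": {p: values}}`` with non-crossing bands by construction.
    """
    if len(curves) < 2:
        raise ValueError("percentile bands need at least 2 replicate curves")
    grid = sorted({int(e) for c in curves for e in c["efforts"]})
    mats = {"sens": [], "spec": []}
    for c in curves:
        eff = np.asarray(c["efforts"], dtype=int)
        for key in ("sens", "spec"):
            vals = np.asarray(c[key], dtype=float)
            idx = np.searchsorted(eff, grid, side="right") - 1
            row = np.where(idx >= 0, vals[np.clip(idx, 0, None)], np.nan)
            mats[key].append(row)
    out: dict = {"efforts": list(grid), "sens": {}, "spec": {}}
    for key in ("sens", "spec"):
        arr = np.vstack(mats[key])
        for p in percentiles:
            out[key][p] = np.nanpercentile(arr, p, axis=0).tolist()
    return out


def displacement_loss_correlation(report: SimulationReport, window: int = 1) -> Optional[float]:
    """Pearson correlation between displacement and concurrent L2 loss.

    Pools (displacement, loss) pairs over all stored curves and update
    points; ``window`` sets the moving-average width applied to the
    displacement series (1 = the last displacement itself).  Returns None
    when either variable has zero variance (undefined correlation).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    xs, ys = [], []
    for c in report.curves:
        disp = np.asarray(c["disp"], dtype=float)
        if disp.size == 0:
            continue
        if window > 1:
            kernel = np.ones(window) / window
            smoothed = np.full_like(disp, np.nan)
            if disp.size >= window:
                smoothed[window - 1 :] = np.convolve(disp, kernel, mode="valid")
            disp = smoothed
        loss_by_effort = {int(e): l for e, l in zip(c["efforts"], c["l2"])}
        for e, d in zip(c["disp_efforts"], disp):
            if math.isnan(d):
                continue
            xs.append(d)
            ys.append(loss_by_effort[int(e)])
    if len(xs) < 3:
        raise ValueError("need at least 3 (displacement, loss) pairs")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return None
    return float(np.corrcoef(x, y)[0, 1])
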