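"""Bivariate random-effects meta-analysis of sensitivity and specificity.

Each study contributes observed logit-sensitivity and logit-specificity with
(approximately) known within-study sampling variances; the per-study true
logits are modelled as bivariate normal around the summary means with an
unstructured 2x2 between-study covariance.  Marginally,

    y_i ~ N(mu, Psi + V_i)

with ``y_i`` the observed logit pair, ``V_i`` the diagonal within-study
covariance and ``Psi`` the between-study covariance.  The summary
sensitivity/specificity are the inverse-logits of ``mu``, with Wald 95%
confidence intervals formed on the logit scale and back-transformed.

Estimation profiles ``mu`` out by generalized least squares and maximizes
the restricted (REML, default) or full (ML) marginal likelihood over
``Psi``, parameterized as (log tau_sens, log tau_spec, atanh rho) so that
proposals are always positive semidefinite and the model is symmetric under
exchanging the sensitivity and specificity axes.

Studies with a zero cell receive a continuity correction (default: add 0.5
to all four cells of that study only), the convention of standard DTA
meta-analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from dtastop.data_io import MetaAnalysisGroup, SummaryEstimate, TwoByTwo

__all__ = ["BivariateFit", "logit_transform", "fit_bivariate", "truth_estimate"]

_Z95 = float(norm.ppf(0.975))

# box constraints for (log tau_sens, log tau_spec, atanh rho)
_BOUNDS = [(-6.0, 3.0), (-6.0, 3.0), (-6.0, 6.0)]


@dataclass(frozen=True)
class BivariateFit:
    """Fitted bivariate model: logit-scale means, between-study covariance."""

    mu: np.ndarray
    Psi: np.ndarray
    se_mu: np.ndarray
    loglik: float
    converged: bool
    estimate: SummaryEstimate

    def __post_init__(self) -> None:
        eigvals = np.linalg.eigvalsh(self.Psi)
        if eigvals.min() < -1e-10:
            raise ValueError("Psi must be positive semidefinite")


def logit_transform(study: TwoByTwo, correction: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Observed logit pair and diagonal within-study covariance for one study.

    With continuity correction c: y = (logit((tp+c)/(tp+fn+2c)),
    logit((tn+c)/(tn+fp+2c))) and the variances are the usual inverse-count
    sums 1/(tp+c) + 1/(fn+c) and 1/(tn+c) + 1/(fp+c).  With c = 0 a zero
    cell yields an infinite logit/variance; callers apply the correction
    policy before fitting.
    """
    if correction < 0:
        raise ValueError("correction must be >= 0")
    c = float(correction)
    tp, fp, fn, tn = study.tp + c, study.fp + c, study.fn + c, study.tn + c
    with np.errstate(divide="ignore"):
        y = np.array([logit(tp / (tp + fn)), logit(tn / (tn + fp))])
        v = np.array([1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp])
    return y, np.diag(v)


def _has_zero_cell(s: TwoByTwo) -> bool:
    return min(s.tp, s.fp, s.fn, s.tn) == 0


def _prepare(
    group: MetaAnalysisGroup, correction: float, correction_policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack observed logits y (n x 2) and within-study variances v (n x 2)."""
    ys, vs = [], []
    for s in group.studies:
        if correction_policy == "all":
            c = correction
        elif correction_policy == "only_zero":
            c = correction if _has_zero_cell(s) else 0.0
        else:
            raise ValueError(f"unknown correction policy {correction_policy!r}")
        y, V = logit_transform(s, c)
        ys.append(y)
        vs.append(np.diag(V))
    return np.array(ys), np.array(vs)


def _profile_negloglik(theta: np.ndarray, y: np.ndarray, v: np.ndarray, reml: bool) -> float:
    """Negative profile log-likelihood over Psi; mu profiled out by GLS.

    Works on the stacked arrays; all per-study 2x2 inversions are closed-form.
    """
    t1, t2 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    p11, p22, p12 = t1 * t1, t2 * t2, rho * t1 * t2

    a = p11 + v[:, 0]  # Sigma_i[0,0]
    c = p22 + v[:, 1]  # Sigma_i[1,1]
    b = p12  # Sigma_i[0,1], shared
    det = a * c - b * b
    if np.any(det <= 0) or not np.all(np.isfinite(det)):
        return 1e12

    w11 = c / det
    w22 = a / det
    w12 = -b / det

    # GLS mean: mu = S^{-1} sum_i W_i y_i
    s11, s22, s12 = w11.sum(), w22.sum(), w12.sum()
    b1 = (w11 * y[:, 0] + w12 * y[:, 1]).sum()
    b2 = (w12 * y[:, 0] + w22 * y[:, 1]).sum()
    det_s = s11 * s22 - s12 * s12
    if det_s <= 0:
        return 1e12
    mu1 = (s22 * b1 - s12 * b2) / det_s
    mu2 = (s11 * b2 - s12 * b1) / det_s

    r1 = y[:, 0] - mu1
    r2 = y[:, 1] - mu2
    quad = w11 * r1 * r1 + 2.0 * w12 * r1 * r2 + w22 * r2 * r2
    nll = 0.5 * (np.log(det).sum() + quad.sum()) + y.shape[0] * np.log(2.0 * np.pi)
    if reml:
        nll += 0.5 * np.log(det_s) - np.log(2.0 * np.pi)
    return float(nll)


def _gls_mean(theta: np.ndarray, y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS mean and its covariance at the fitted Psi."""
    t1, t2 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    a = t1 * t1 + v[:, 0]
    c = t2 * t2 + v[:, 1]
    b = rho * t1 * t2
    det = a * c - b * b
    w11, w22, w12 = c / det, a / det, -b / det
    S = np.array([[w11.sum(), w12.sum()], [w12.sum(), w22.sum()]])
    rhs = np.array(
        [(w11 * y[:, 0] + w12 * y[:, 1]).sum(), (w12 * y[:, 0] + w22 * y[:, 1]).sum()]
    )
    cov_mu = np.linalg.inv(S)
    return cov_mu @ rhs, cov_mu


def _start_values(y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Moment start: sample covariance of y minus mean within-study variance."""
    cov_y = np.cov(y.T) if y.shape[0] > 1 else np.zeros((2, 2))
    tau2 = np.maximum(np.diag(cov_y) - v.mean(axis=0), 1e-3)
    tau = np.sqrt(tau2)
    denom = tau[0] * tau[1]
    rho = float(np.clip(cov_y[0, 1] / denom if denom > 0 else 0.0, -0.95, 0.95))
    return np.array([np.log(tau[0]), np.log(tau[1]), np.arctanh(rho)])


def fit_bivariate(
    group: MetaAnalysisGroup,
    method: str = "reml",
    correction: float = 0.5,
    correction_policy: str = "only_zero",
) -> BivariateFit:
    """Fit the bivariate random-effects model to a meta-analysis group.

    Parameters
    ----------
    group
        Analyzable meta-analysis group (>= 3 studies); fewer raise ValueError.
    method
        "reml" (default) or "ml".
    correction, correction_policy
        Continuity correction value and whether it applies to all studies
        ("all") or only studies with a zero cell ("only_zero", default).

    Returns
    -------
    BivariateFit
        Logit-scale means, between-study covariance, standard errors and the
        back-transformed :class:`~dtastop.data_io.SummaryEstimate`.  A fit
        where the optimizer did not report success is returned with
        ``converged=False`` rather than raising.
    """
    if not group.analyzable:
        raise ValueError(
            f"meta-analysis {group.ma_id!r} has {group.n_studies} studies; "
            "summary estimates require at least 3"
        )
    if method not in {"reml", "ml"}:
        raise ValueError(f"unknown method {method!r}")
    reml = method == "reml"
    y, v = _prepare(group, correction, correction_policy)

    starts = [_start_values(y, v), np.array([np.log(0.5), np.log(0.5), 0.0])]
    best = None
    for x0 in starts:
        res = minimize(
            _profile_negloglik,
            np.clip(x0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS]),
            args=(y, v, reml),
            method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    mu, cov_mu = _gls_mean(theta, y, v)
    se_mu = np.sqrt(np.diag(cov_mu))
    t1, t2 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    Psi = np.array([[t1 * t1, rho * t1 * t2], [rho * t1 * t2, t2 * t2]])
    converged = bool(best.success and np.all(np.isfinite(se_mu)))

    sens, spec = float(expit(mu[0])), float(expit(mu[1]))
    sens_ci = (float(expit(mu[0] - _Z95 * se_mu[0])), float(expit(mu[0] + _Z95 * se_mu[0])))
    spec_ci = (float(expit(mu[1] - _Z95 * se_mu[1])), float(expit(mu[1] + _Z95 * se_mu[1])))
    estimate = SummaryEstimate(
        sens=sens,
        spec=spec,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        logit_means=(float(mu[0]), float(mu[1])),
        between_cov=Psi,
        n_studies=group.n_studies,
        converged=converged,
    )
    return BivariateFit(
        mu=mu, Psi=Psi, se_mu=se_mu, loglik=float(-best.fun), converged=converged, estimate=estimate
    )


def truth_estimate(group: MetaAnalysisGroup, **kwargs) -> SummaryEstimate:
    """Summary estimate over the complete group, used as the loss reference.

    The "truth" against which every interim estimate's loss is measured is
    the final estimate over all relevant studies, so the loss of the full
    screening is zero by construction.
    """
    return fit_bivariate(group, **kwargs).estimate
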