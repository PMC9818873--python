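"""Survival statistics and model fits used throughout the pipeline.

Kaplan-Meier estimation, two-group log-rank, vectorized log-rank
screening over many binary pair features, L1-penalized Cox selection
with cross-validated partial-likelihood deviance, unpenalized Cox with
Breslow tie handling and Wald inference, Harrell's C, restricted mean
survival, and a paired-bootstrap C-index comparison.

A survival table is a DataFrame indexed by sample id with columns
``time_months`` (positive, finite) and ``event`` (0/1), plus optional
clinical covariates (age, gender, tnm_stage, cohort, response).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .pairs import PairMatrix, as_pair_frame

__all__ = [
    "KaplanMeierCurve",
    "km_estimate",
    "rms_time",
    "logrank_test",
    "screen_pairs",
    "CoxFit",
    "fit_cox",
    "LassoCoxResult",
    "lasso_cox",
    "c_index",
    "CIndexComparison",
    "compare_cindex_bootstrap",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: right-continuous step function with S(0) = 1."""

    drop_times: np.ndarray   # event times where the curve steps down
    survival: np.ndarray     # S just after each drop time
    n: int
    n_events: int

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.drop_times, t, side="right")
        values = np.concatenate([[1.0], self.survival])[idx]
        return values if values.ndim else float(values)


def _check_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise ValueError("times must be positive and finite")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator."""
    times, events = _check_surv_arrays(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first
    d = np.add.reduceat(e, first)
    has_event = d > 0
    factors = 1.0 - d[has_event] / n_at_risk[has_event]
    surv = np.cumprod(factors)
    return KaplanMeierCurve(uniq[has_event], surv, n=t.size, n_events=int(e.sum()))


def rms_time(times, events, tau: float = 120.0) -> float:
    """Restricted mean survival: area under the KM curve on [0, tau]."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    km = km_estimate(times, events)
    knots = np.concatenate([[0.0], km.drop_times[km.drop_times < tau], [tau]])
    heights = np.concatenate([[1.0], km.survival])[: knots.size - 1]
    return float(np.sum(heights * np.diff(knots)))


# ---------------------------------------------------------------------------
# Log-rank


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times, events = _check_surv_arrays(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    if events.sum() == 0:
        raise ValueError("no events observed")
    mask = group == labels[1]
    res = _ll_logrank(times[mask], times[~mask],
                      event_observed_A=events[mask], event_observed_B=events[~mask])
    return float(res.test_statistic), float(res.p_value)


def _logrank_many(times: np.ndarray, events: np.ndarray,
                  groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square for many binary groupings at once.

    ``groups`` is (m features x n samples) in {0,1}; group 1 is the
    feature-positive stratum. Returns (chi2, p) arrays of length m.
    """
    event_times = np.unique(times[events == 1])
    # risk/death indicators per sample x event time
    at_risk = times[:, None] >= event_times[None, :]           # n x K
    death = (times[:, None] == event_times[None, :]) & (events[:, None] == 1)
    n_k = at_risk.sum(axis=0).astype(float)                    # K
    d_k = death.sum(axis=0).astype(float)
    g = groups.astype(float)
    n1 = g @ at_risk                                            # m x K
    d1 = g @ death
    frac = n1 / n_k
    o_minus_e = (d1 - d_k * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_k = d_k * frac * (1.0 - frac) * (n_k - d_k) / (n_k - 1.0)
    var_k = np.where(n_k > 1, var_k, 0.0)
    v = var_k.sum(axis=1)
    if np.any(v <= 0):
        raise ValueError("constant grouping encountered in log-rank screen")
    chi2 = o_minus_e ** 2 / v
    return chi2, stats.chi2.sf(chi2, df=1)


def _align_features(features, surv: pd.DataFrame) -> pd.DataFrame:
    frame = as_pair_frame(features)
    if set(frame.columns) != set(surv.index):
        raise ValueError("feature matrix and survival table sample ids differ")
    return frame[surv.index]


def screen_pairs(
    pairs: "PairMatrix | pd.DataFrame",
    surv: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Log-rank screen of every pair, grouping samples by pair value.

    Returns a DataFrame (one row per pair) with ``statistic``, ``p_value``,
    ``p_adjusted`` (BH when requested, else the raw p) and ``selected``
    (adjusted p < alpha). Screening alpha and adjustment are recorded in
    ``.attrs``. Constant pairs are not screenable; filter them first.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    frame = _align_features(pairs, surv)
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    if events.sum() == 0:
        raise ValueError("no events observed")
    chi2, p = _logrank_many(times, events, frame.to_numpy())
    p_adj = stats.false_discovery_control(p) if adjust == "BH" else p.copy()
    out = pd.DataFrame(
        {"statistic": chi2, "p_value": p, "p_adjusted": p_adj,
         "selected": p_adj < alpha},
        index=frame.index,
    )
    out.attrs["alpha"] = alpha
    out.attrs["adjust"] = adjust
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)


def _breslow_loglik_parts(beta, x, times, events, need_derivs=True):
    """Breslow partial log-likelihood and (optionally) gradient/Hessian."""
    order = np.argsort(times, kind="stable")
    x, times, events = x[order], times[order], events[order]
    eta = x @ beta
    eta = eta - eta.max()  # guard overflow; constant shift cancels
    w = np.exp(eta)
    n, p = x.shape

    # suffix sums over the risk set {j : t_j >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    uniq, first = np.unique(times, return_index=True)
    d = np.add.reduceat(events, first)
    ev_mask = events == 1
    sum_eta_events = float(eta[ev_mask].sum())
    x_events = x[ev_mask].sum(axis=0)

    has = d > 0
    idx = first[has]
    dk = d[has]
    ll = sum_eta_events - float(np.sum(dk * np.log(s0[idx])))
    if not need_derivs:
        return ll, None, None
    mean = s1[idx] / s0[idx, None]                        # K x p
    grad = x_events - (dk[:, None] * mean).sum(axis=0)
    s2 = np.cumsum((w[:, None, None] * x[:, :, None] * x[:, None, :])[::-1],
                   axis=0)[::-1]
    cov = s2[idx] / s0[idx, None, None] - mean[:, :, None] * mean[:, None, :]
    hess = -(dk[:, None, None] * cov).sum(axis=0)
    return ll, grad, hess


def breslow_partial_loglik(beta, features: pd.DataFrame | np.ndarray,
                           times, events) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector."""
    x = np.asarray(features, dtype=float)
    times, events = _check_surv_arrays(times, events)
    ll, _, _ = _breslow_loglik_parts(np.asarray(beta, float), x, times, events,
                                     need_derivs=False)
    return ll


@dataclass
class CoxFit:
    """Cox proportional-hazards fit with Wald inference."""

    params: pd.Series            # log hazard ratios
    standard_errors: pd.Series
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    n_events: int
    tie_method: str = "breslow"

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.standard_errors
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index,
                         name="p")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = np.exp(self.params - z * self.standard_errors)
        hi = np.exp(self.params + z * self.standard_errors)
        return pd.DataFrame({"HR_lower": lo, "HR_upper": hi})

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "coef": self.params,
            "HR": self.hazard_ratios,
            "se": self.standard_errors,
            "HR_lower_95": ci["HR_lower"],
            "HR_upper_95": ci["HR_upper"],
            "p": self.p_values,
        })


def fit_cox(features: pd.DataFrame, surv: pd.DataFrame,
            tol: float = 1e-9, max_iter: int = 100) -> CoxFit:
    """Maximum partial-likelihood Cox fit (Breslow ties, Newton-Raphson).

    ``features`` is covariates x samples (pair-matrix orientation) or
    samples x covariates; orientation is inferred from the survival index.
    Divergence (|coef| > 50) is flagged as non-convergence — typically
    separation — never silently returned as converged.
    """
    if features.shape[0] == 0 or features.shape[1] == 0:
        raise ValueError("no covariates supplied")
    if set(features.columns) == set(surv.index):
        frame = features[surv.index].T          # -> samples x covariates
    elif set(features.index) == set(surv.index):
        frame = features.loc[surv.index]
    else:
        raise ValueError("features and survival table sample ids differ")
    x = frame.to_numpy(dtype=float)
    names = list(frame.columns)
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events observed")
    if x.shape[1] >= n_events:
        raise ValueError(f"{x.shape[1]} covariates but only {n_events} events")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant covariate supplied to fit_cox")

    beta = np.zeros(x.shape[1])
    ll, grad, hess = _breslow_loglik_parts(beta, x, times, events)
    ll_null = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # damped update: halve until the likelihood does not decrease
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _breslow_loglik_parts(cand, x, times, events)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        improved = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.abs(improved) <= tol * (np.abs(ll) + 1.0):
            converged = True
            break
    if np.any(np.abs(beta) > 50):
        converged = False
        warnings.warn("Cox coefficients diverged; possible separation",
                      RuntimeWarning, stacklevel=2)
    if not converged:
        warnings.warn("Cox fit did not converge", RuntimeWarning, stacklevel=2)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(
        params=pd.Series(beta, index=names, name="coef"),
        standard_errors=pd.Series(se, index=names, name="se"),
        loglik=ll, loglik_null=ll_null, converged=converged,
        n=x.shape[0], n_events=n_events,
    )


# ---------------------------------------------------------------------------
# LASSO-Cox selection


@dataclass
class LassoCoxResult:
    """L1-penalized Cox selection with CV-chosen penalty."""

    selected: list[str]
    coefficients: pd.Series       # at the chosen penalty (zeros included)
    penalty: float
    penalties: np.ndarray = field(repr=False)
    cv_deviance: np.ndarray = field(repr=False)
    n_folds: int = 0
    seed: int = 0


def _draw_folds(n: int, n_folds: int, events: np.ndarray,
                rng: np.random.Generator, max_tries: int = 100) -> list[np.ndarray]:
    """Shuffled K-fold indices; redrawn until every fold holds >= 1 event."""
    for _ in range(max_tries):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        if all(events[f].sum() >= 1 for f in folds):
            return folds
    raise ValueError("could not draw folds with events in every fold")


def lasso_cox(
    features: "PairMatrix | pd.DataFrame",
    surv: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    penalty: float | None = None,
    n_penalties: int = 100,
) -> LassoCoxResult:
    """L1-penalized Cox over a descending penalty grid.

    The penalty is chosen by cross-validated partial-likelihood deviance
    (minimum rule), with held-out deviance computed as
    ``-2 [pl_all(beta_fold) - pl_train(beta_fold)]`` so ties and risk sets
    are handled consistently. Pass ``penalty`` to skip CV and fit at a
    fixed value (a huge penalty yields an empty selection).
    """
    frame = _align_features(features, surv)
    if frame.shape[0] < 2 and penalty is None:
        raise ValueError("need at least 2 features")
    if (frame.to_numpy().std(axis=1) == 0).all():
        raise ValueError("all features are constant")
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    if events.sum() == 0:
        raise ValueError("no events observed")
    x = frame.to_numpy(dtype=float).T              # samples x features
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    if penalty is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[penalty],
                                       fit_baseline_model=False)
        model.fit(x, y)
        coefs = pd.Series(model.coef_[:, 0], index=frame.index, name="coef")
        return LassoCoxResult(list(coefs.index[coefs != 0]), coefs,
                              float(penalty), np.array([penalty]),
                              np.array([np.nan]), 0, seed)

    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_penalties,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    path.fit(x, y)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    folds = _draw_folds(x.shape[0], n_folds, events, rng)
    deviance = np.zeros(alphas.size)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(x.shape[0]), test_idx)
        fold_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas),
                                            fit_baseline_model=False)
        fold_model.fit(x[train], y[train])
        fold_alphas = np.asarray(fold_model.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fold_alphas - a)))
            beta = fold_model.coef_[:, jj]
            pl_all = _breslow_loglik_parts(beta, x, times, events, False)[0]
            pl_train = _breslow_loglik_parts(beta, x[train], times[train],
                                             events[train], False)[0]
            deviance[j] += -2.0 * (pl_all - pl_train)

    best = int(np.argmin(deviance))
    chosen = float(alphas[best])
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[chosen],
                                   fit_baseline_model=False)
    final.fit(x, y)
    coefs = pd.Series(final.coef_[:, 0], index=frame.index, name="coef")
    return LassoCoxResult(list(coefs.index[coefs != 0]), coefs, chosen,
                          alphas, deviance / len(folds), n_folds, seed)


# ---------------------------------------------------------------------------
# Concordance and bootstrap comparison


def c_index(scores, surv: pd.DataFrame) -> float:
    """Harrell's concordance of a risk score (higher = higher risk)."""
    scores = _as_aligned_scores(scores, surv)
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    try:
        return float(_ll_concordance(times, -scores, events))
    except ZeroDivisionError as exc:
        raise ValueError("no usable (comparable) pairs for the C-index") from exc


def _as_aligned_scores(scores, surv: pd.DataFrame) -> np.ndarray:
    if isinstance(scores, pd.Series):
        if set(scores.index) != set(surv.index):
            raise ValueError("scores and survival table sample ids differ")
        return scores[surv.index].to_numpy(dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != surv.shape[0]:
        raise ValueError("scores length does not match survival table")
    return scores


@dataclass
class CIndexComparison:
    """Paired-bootstrap comparison of two risk scores' concordance.

    The resampling procedure is this package's own convention for
    comparing concordance indices; ``method`` records it explicitly.
    """

    c_a: float
    c_b: float
    p_value: float
    n_boot: int
    n_used: int
    seed: int
    method: str = "paired bootstrap"


def compare_cindex_bootstrap(score_a, score_b, surv: pd.DataFrame,
                             n_boot: int = 1000, seed: int = 0) -> CIndexComparison:
    """Two-sided paired-bootstrap test of C(score_a) vs C(score_b)."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a = _as_aligned_scores(score_a, surv)
    b = _as_aligned_scores(score_b, surv)
    times, events = _check_surv_arrays(surv["time_months"], surv["event"])
    rng = np.random.default_rng(seed)
    n = times.size
    diffs, cas, cbs = [], [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ca = float(_ll_concordance(times[idx], -a[idx], events[idx]))
            cb = float(_ll_concordance(times[idx], -b[idx], events[idx]))
        except ZeroDivisionError:
            skipped += 1
            continue
        cas.append(ca)
        cbs.append(cb)
        diffs.append(ca - cb)
    if skipped:
        logger.info("compare_cindex_bootstrap: skipped %d degenerate resamples",
                    skipped)
    if not diffs:
        raise ValueError("all bootstrap resamples were degenerate")
    d = np.asarray(diffs)
    p = 2.0 * min(np.mean(d <= 0.0), np.mean(d >= 0.0))
    return CIndexComparison(float(np.mean(cas)), float(np.mean(cbs)),
                            float(min(p, 1.0)), n_boot, d.size, seed)
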