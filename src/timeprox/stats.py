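"""Biomarker association battery.

Nonparametric two-group (Mann-Whitney U) and k-group (Kruskal-Wallis with
Dunn post-hoc) comparisons, Benjamini-Hochberg FDR control, rank-based
ROC/AUC, Kaplan-Meier / log-rank survival comparison, and Cox
proportional-hazards regression with p < 0.1 univariate screening before a
multivariate fit.

The Cox fitter is a Newton optimisation of the partial likelihood written
here so that both Breslow (default) and Efron tie handling are available
behind one configuration switch; it reports HR = exp(beta) with Wald 95%
confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import StatisticalDegeneracyError

Z_95 = 1.959963984540054  # Phi^-1(0.975)


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    feature_id: str
    test: str
    group_sizes: tuple[int, ...]
    statistic: float
    p_value: float
    direction: str | None = None      # which group has the larger median
    q_value: float | None = None      # BH-adjusted within the declared family
    degenerate: bool = False
    method: str | None = None
    pairwise: pd.DataFrame | None = None   # Dunn results when k > 2


def mann_whitney(x, y, feature_id: str = "", exact_max_n: int = 8,
                 group_names: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when both groups have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise StatisticalDegeneracyError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return ComparisonResult(feature_id, "mann-whitney", (len(x), len(y)),
                                statistic=len(x) * len(y) / 2.0, p_value=1.0,
                                degenerate=True, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if max(len(x), len(y)) <= exact_max_n and not has_ties
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = group_names[0] if np.median(x) > np.median(y) else group_names[1]
    return ComparisonResult(feature_id, "mann-whitney", (len(x), len(y)),
                            statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            direction=direction, method=method)


def _dunn_pairwise(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks, tie-corrected, BH within the family."""
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1 / len(groups[i]) + 1 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "z": float(z), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def kruskal_dunn(groups, feature_id: str = "",
                 names: list[str] | None = None) -> ComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn pairwise post-hoc tests."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise StatisticalDegeneracyError("kruskal_dunn requires k >= 3 groups")
    if any(len(g) == 0 for g in groups):
        raise StatisticalDegeneracyError("kruskal_dunn: empty group")
    names = names or [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return ComparisonResult(feature_id, "kruskal-wallis",
                                tuple(len(g) for g in groups),
                                statistic=0.0, p_value=1.0, degenerate=True)
    h, p = sps.kruskal(*groups)
    medians = [np.median(g) for g in groups]
    return ComparisonResult(feature_id, "kruskal-wallis",
                            tuple(len(g) for g in groups),
                            statistic=float(h), p_value=float(p),
                            direction=names[int(np.argmax(medians))],
                            pairwise=_dunn_pairwise(groups, names))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    feature_id: str
    auc: float
    n_positive: int
    n_negative: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(values, flags, feature_id: str = "") -> ROCResult:
    """AUC with the responder (flag=True) as positive class.

    Orientation is fixed a priori — larger feature value predicts responder —
    so an AUC below 0.5 is reportable.  Computed from the rank statistic with
    half-credit for ties (equals U / (n1*n0)).  Missing feature values are
    dropped pairwise.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    keep = np.isfinite(values)
    values, flags = values[keep], flags[keep]
    n_pos = int(flags.sum())
    n_neg = int((~flags).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticalDegeneracyError("roc_auc: one class is empty")
    ranks = sps.rankdata(values)
    auc = (ranks[flags].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(flags.astype(int), values)
    return ROCResult(feature_id, float(auc), n_pos, n_neg, fpr, tpr, thr)


# --------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# --------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]     # per group: time, at_risk, survival
    statistic: float
    p_value: float
    flagged: bool = False               # True when log-rank is undefined
    note: str | None = None


def km_logrank(times, events, groups) -> KMResult:
    """Product-limit curves per group and the log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise StatisticalDegeneracyError(f"km_logrank: empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        tab = kmf.event_table
        curves[str(g)] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(),
            "censored": tab["censored"].to_numpy(),
        })
    if events.sum() == 0:
        return KMResult(curves, float("nan"), float("nan"), flagged=True,
                        note="no events: log-rank undefined")
    if len(pd.unique(groups)) < 2:
        return KMResult(curves, float("nan"), float("nan"), flagged=True,
                        note="single group: log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    summary: pd.DataFrame       # covariate, coef, se, hr, ci_lower, ci_upper, z, p
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    flagged: bool = False       # non-convergence / monotone likelihood
    note: str | None = None

    def hr(self, covariate: str | None = None) -> float:
        s = self.summary.set_index("covariate")
        return float(s["hr"].iloc[0] if covariate is None else s.loc[covariate, "hr"])

    def p(self, covariate: str | None = None) -> float:
        s = self.summary.set_index("covariate")
        return float(s["p"].iloc[0] if covariate is None else s.loc[covariate, "p"])


def _cox_derivatives(beta, t, e, x, ties):
    """Log partial likelihood, gradient and Hessian (t sorted descending)."""
    eta = x @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * x, axis=0)
    S2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    p = x.shape[1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    ev_times = np.unique(t[e == 1])
    for tj in ev_times:
        risk_end = np.searchsorted(-t, -tj, side="right") - 1
        D = (t == tj) & (e == 1)
        d = int(D.sum())
        s = x[D].sum(axis=0)
        s0, s1, s2 = S0[risk_end], S1[risk_end], S2[risk_end]
        ll += float(eta[D].sum())
        if ties == "breslow":
            ll -= d * (np.log(s0) + shift)
            m = s1 / s0
            grad += s - d * m
            hess -= d * (s2 / s0 - np.outer(m, m))
        else:  # efron
            w_D = w[D].sum()
            s1_D = (w[D, None] * x[D]).sum(axis=0)
            s2_D = (w[D, None, None] * (x[D][:, :, None] * x[D][:, None, :])).sum(axis=0)
            for l in range(d):
                f = l / d
                s0_l = s0 - f * w_D
                s1_l = s1 - f * s1_D
                s2_l = s2 - f * s2_D
                ll -= np.log(s0_l) + shift
                m = s1_l / s0_l
                grad += s / d - m
                hess -= s2_l / s0_l - np.outer(m, m)
    return ll, grad, hess


def cox_fit(times, events, covariates, ties: str = "breslow",
            max_iter: int = 100, tol: float = 1e-9) -> CoxResult:
    """Cox proportional-hazards regression by Newton optimisation of the
    partial likelihood.

    ``covariates`` is a DataFrame or 2-D array; HR = exp(beta) with Wald 95%
    CI exp(beta +/- 1.96 se).  Non-convergence or a monotone likelihood
    (complete separation) yields a flagged result, never a silent estimate.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    n_events = int(events.sum())
    if np.any(X.std(axis=0) == 0):
        const = [names[i] for i in range(p) if X[:, i].std() == 0]
        raise StatisticalDegeneracyError(f"constant covariate(s): {const}")
    if n_events < p + 1:
        raise StatisticalDegeneracyError(
            f"{n_events} events insufficient for {p} covariate(s)")

    # center for numerical stability; beta is unchanged by centering
    means = X.mean(axis=0)
    Xc = X - means
    order = np.argsort(-times, kind="stable")
    t, e, x = times[order], events[order], Xc[order]

    beta = np.zeros(p)
    ll, grad, hess = _cox_derivatives(beta, t, e, x, ties)
    converged = False
    scale = 1.0 + abs(ll)  # tolerances relative to the likelihood magnitude
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # step-halving line search
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_derivatives(new_beta, t, e, x, ties)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-9 * scale:
                break
            step /= 2.0
        delta = abs(new_ll - ll)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if delta < tol * scale:
            converged = True
            break

    flagged = not converged
    note = None if converged else "Newton did not converge"
    if np.abs(beta).max() > 15:
        flagged = True
        note = "monotone partial likelihood (complete separation suspected)"

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flagged = True
        note = note or "singular information matrix"
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        pvals = 2 * sps.norm.sf(np.abs(z))
        summary = pd.DataFrame({
            "covariate": names, "coef": beta, "se": se,
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - Z_95 * se),
            "ci_upper": np.exp(beta + Z_95 * se),
            "z": z, "p": pvals,
        })
    return CoxResult(summary=summary, loglik=float(ll), n=n, n_events=n_events,
                     ties=ties, converged=converged, flagged=flagged, note=note)


@dataclass
class ScreenedCoxResult:
    """Univariate screen (retain p < alpha) followed by a joint Cox fit."""

    univariate: pd.DataFrame
    retained: list[str]
    multivariate: CoxResult | None
    alpha: float
    flagged: bool = False
    note: str | None = None


def screened_multivariate(times, events, covariates: pd.DataFrame,
                          alpha: float = 0.1, ties: str = "breslow") -> ScreenedCoxResult:
    """Fit univariate Cox per candidate, keep p < alpha, fit the joint model.

    Candidates whose univariate fit is degenerate (constant, flagged) are
    excluded from the screen with a warning.  An empty retained set returns
    the univariate stage only, flagged.
    """
    uni_rows = []
    retained = []
    for col in covariates.columns:
        try:
            res = cox_fit(times, events, covariates[[col]], ties=ties)
        except StatisticalDegeneracyError as exc:
            warnings.warn(f"covariate {col!r} excluded from screen: {exc}")
            uni_rows.append({"covariate": col, "coef": np.nan, "se": np.nan,
                             "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
                             "z": np.nan, "p": np.nan})
            continue
        row = res.summary.iloc[0].to_dict()
        uni_rows.append(row)
        if not res.flagged and row["p"] < alpha:
            retained.append(col)
    univariate = pd.DataFrame(uni_rows)
    if not retained:
        return ScreenedCoxResult(univariate, [], None, alpha, flagged=True,
                                 note="no candidate passed the univariate screen")
    multi = cox_fit(times, events, covariates[retained], ties=ties)
    return ScreenedCoxResult(univariate, retained, multi, alpha,
                             flagged=multi.flagged, note=multi.note)
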