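"""Survival analysis from first principles.

Implements the three classical right-censored tools used throughout the
analysis: the Kaplan-Meier product-limit estimator (with Greenwood variance),
the k-group log-rank test (hypergeometric observed/expected accumulation),
and Cox proportional-hazards regression maximizing the Efron (default) or
Breslow partial likelihood by Newton-Raphson with step-halving.

Conventions: ``event = 1`` means the event (death) was observed, times are
strictly positive, and subjects censored at an event time are counted at risk
at that time (right-continuity). Confidence intervals and p-values for Cox
coefficients are Wald-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ValidationError
from .io import ClinicalTable

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "survival_screen",
    "bh_adjust",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit curves, one table per group.

    Each table has columns ``time`` (distinct event times, ascending),
    ``n_at_risk``, ``n_events``, ``survival`` and ``greenwood_var``.
    """

    groups: dict[str, pd.DataFrame]

    def survival_at(self, group: str, t: float) -> float:
        """Step-function value S(t) for one group."""
        tab = self.groups[group]
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def _km_one_group(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    surv = 1.0
    gw_sum = 0.0  # running sum of d / (n (n - d))
    n = len(time)
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            gw_sum += d / (at_risk * (at_risk - d))
        rows.append(
            {
                "time": float(t),
                "n_at_risk": at_risk,
                "n_events": d,
                "survival": surv,
                "greenwood_var": surv**2 * gw_sum if at_risk > d else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "survival", "greenwood_var"]
    )


def km_estimate(clinical: ClinicalTable, group_labels=None) -> KMEstimate:
    """Kaplan-Meier estimate per group (single pooled group when labels=None)."""
    time, event = clinical.time, clinical.event
    if group_labels is None:
        labels = pd.Series("all", index=clinical.data.index)
    else:
        labels = pd.Series(group_labels).reindex(clinical.data.index)
    groups = {}
    for g in labels.dropna().unique():
        mask = (labels == g).to_numpy()
        tab = _km_one_group(time[mask], event[mask])
        if tab.empty:
            warnings.warn(f"group {g!r} has no events; KM curve is flat at 1")
        groups[g] = tab
    if not any(len(t) for t in groups.values()):
        warnings.warn("no events in any group; all KM curves are flat")
    return KMEstimate(groups)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    observed: pd.Series  # per-group observed event counts
    expected: pd.Series  # per-group expected event counts


def logrank_test(clinical: ClinicalTable, group_labels) -> LogRankResult:
    """k-group log-rank test.

    At each distinct event time, expected per-group events come from the
    hypergeometric mean and the covariance from the hypergeometric variance;
    the statistic is the quadratic form over the first k-1 groups.
    """
    labels = pd.Series(group_labels).reindex(clinical.data.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label for log-rank")
    names = sorted(labels.unique())
    k = len(names)
    if k < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    time, event = clinical.time, clinical.event
    if event.sum() == 0:
        raise ValidationError("log-rank needs >= 1 event")
    gidx = labels.map({g: i for i, g in enumerate(names)}).to_numpy()

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = int(at_risk.sum())
        d_j = int(((time == t) & (event == 1)).sum())
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(
            gidx[(time == t) & (event == 1)], minlength=k
        ).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = d_j * (n_j - d_j) / (n_j - 1)
            V += frac * (np.diag(n_gj) * n_j - np.outer(n_gj, n_gj)) / n_j**2
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(
        chi2=chi2,
        df=df,
        p_value=p,
        observed=pd.Series(O, index=names),
        expected=pd.Series(E, index=names),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Newton-Raphson Cox fit with Wald inference.

    ``summary`` columns: coef, se, hr, hr_lower, hr_upper, z, p.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    ties: str
    n: int
    n_events: int
    dropped: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def summary(self) -> pd.DataFrame:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_lower": lo,
                "hr_upper": hi,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def _partial_lik_terms(beta, time, event, X, ties):
    """(loglik, gradient, information) for the Cox partial likelihood.

    Arrays must be pre-sorted by ascending time. Efron handles tied event
    times by averaging the tied subjects out of the denominator; Breslow
    keeps the full risk-set denominator for every tied event.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for wild interim steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix (risk-set) sums: S*_R[i] over subjects with time >= time[i]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        D = np.arange(i, j)[event[i:j] == 1]
        d = len(D)
        if d:
            s0R, s1R, s2R = S0[i], S1[i], S2[i]
            loglik += float(eta[D].sum())
            grad += X[D].sum(axis=0)
            if ties == "efron" and d > 1:
                s0D = w[D].sum()
                s1D = wX[D].sum(axis=0)
                s2D = wXX[D].sum(axis=0)
                for l in range(d):
                    f = l / d
                    den = s0R - f * s0D
                    m1 = (s1R - f * s1D) / den
                    M2 = (s2R - f * s2D) / den
                    loglik -= np.log(den)
                    grad -= m1
                    info += M2 - np.outer(m1, m1)
            else:  # breslow, or a single event (identical under both)
                m1 = s1R / s0R
                M2 = s2R / s0R
                loglik -= d * np.log(s0R)
                grad -= d * m1
                info += d * (M2 - np.outer(m1, m1))
        i = j
    return loglik, grad, info


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    Xc = X - X.mean(axis=0)
    _, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [names[i] for i in range(len(names)) if diag[i] < 1e-10 * scale]
    if bad:
        raise CollinearityError(bad)


def cox_fit(
    clinical: ClinicalTable,
    covariates: pd.DataFrame,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    ``covariates`` is a samples-x-covariates numeric DataFrame aligned with
    the clinical table by sample id. Constant covariates are dropped with a
    warning; a rank-deficient design raises :class:`CollinearityError` naming
    the collinear columns. Non-convergence (monotone likelihood/separation)
    returns a flagged fit with a warning rather than raising.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method: {ties!r}")
    cov = covariates.reindex(clinical.data.index)
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in {bad}")
    names = cov.columns.tolist()
    X = cov.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite covariate values")
    keep, dropped = [], []
    for i, name in enumerate(names):
        (keep if X[:, i].std() > 1e-12 else dropped).append((i, name))
    if dropped:
        warnings.warn(
            f"constant covariates dropped: {[n for _, n in dropped]}"
        )
    if not keep:
        raise ValidationError("no non-constant covariates to fit")
    idx = [i for i, _ in keep]
    names = [n for _, n in keep]
    X = X[:, idx]
    _check_rank(X, names)

    time, event = clinical.time, clinical.event
    if event.sum() == 0:
        raise ValidationError("Cox model needs >= 1 event")
    order = np.argsort(time, kind="mergesort")
    time, event, X = time[order], event[order], X[order]
    # center for numerical stability; partial likelihood is shift-invariant
    center = X.mean(axis=0)
    Xc = X - center

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _partial_lik_terms(beta, time, event, Xc, ties)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError(names, "singular information matrix")
        # step-halving on loglik decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _partial_lik_terms(
                cand, time, event, Xc, ties
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll_prev, ll = cand, ll, ll_new
        grad, info = grad_new, info_new
        if np.max(np.abs(grad)) < tol or abs(ll - ll_prev) < tol * (
            abs(ll_prev) + tol
        ):
            converged = True
            break
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / "
            "separation); estimates are unreliable"
        )
    try:
        cov_beta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise CollinearityError(names, "singular information matrix at optimum")
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return CoxFit(
        names=names,
        beta=beta,
        se=se,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        n_iter=it,
        ties=ties,
        n=len(time),
        n_events=int(event.sum()),
        dropped=[n for _, n in dropped],
    )


def cox_score_test(
    clinical: ClinicalTable, covariates: pd.DataFrame, ties: str = "breslow"
) -> tuple[float, float]:
    """Cox score test at beta = 0: (statistic, p-value).

    With a single binary covariate and untied event times this statistic
    equals the 2-group log-rank chi-square.
    """
    cov = covariates.reindex(clinical.data.index)
    X = cov.to_numpy(float)
    time, event = clinical.time, clinical.event
    order = np.argsort(time, kind="mergesort")
    time, event, X = time[order], event[order], X[order]
    X = X - X.mean(axis=0)
    _, grad, info = _partial_lik_terms(
        np.zeros(X.shape[1]), time, event, X, ties
    )
    stat = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(stat, X.shape[1]))
    return stat, p


# ---------------------------------------------------------------------------
# univariate/multivariate screen


def _expand_categoricals(
    covariates: pd.DataFrame, reference: dict[str, str] | None = None
) -> pd.DataFrame:
    """Reference-code non-numeric columns (reference = first level
    alphabetically unless overridden)."""
    reference = reference or {}
    out = {}
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float)
            continue
        levels = sorted(series.dropna().unique())
        ref = reference.get(col, levels[0] if levels else None)
        for lev in levels:
            if lev == ref:
                continue
            out[f"{col}[{lev}]"] = (series == lev).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def survival_screen(
    clinical: ClinicalTable,
    covariates: pd.DataFrame,
    mode: str = "both",
    reference: dict[str, str] | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Univariate and/or multivariate Cox screens over a covariate table.

    Returns a forest-plot-ready frame with columns mode, covariate, coef,
    se, hr, hr_lower, hr_upper, z, p, q (BH across the univariate screen),
    n, n_events, converged.
    """
    if mode not in ("univariate", "multivariate", "both"):
        raise ValidationError(f"unknown screen mode: {mode!r}")
    design = _expand_categoricals(covariates, reference)
    rows = []
    if mode in ("univariate", "both"):
        for col in design.columns:
            fit = cox_fit(clinical, design[[col]], ties=ties)
            s = fit.summary.iloc[0]
            rows.append(
                {"mode": "univariate", "covariate": col, **s.to_dict(),
                 "n": fit.n, "n_events": fit.n_events,
                 "converged": fit.converged}
            )
    if mode in ("multivariate", "both"):
        fit = cox_fit(clinical, design, ties=ties)
        for col in fit.names:
            s = fit.summary.loc[col]
            rows.append(
                {"mode": "multivariate", "covariate": col, **s.to_dict(),
                 "n": fit.n, "n_events": fit.n_events,
                 "converged": fit.converged}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    uni = out["mode"] == "univariate"
    if uni.any():
        out.loc[uni, "q"] = bh_adjust(out.loc[uni, "p"].to_numpy())
    return out
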