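"""Survival and competing-risks statistics for transplant outcome analysis.

Provides the estimators and tests used in registry outcome studies:

* Kaplan-Meier product-limit estimation with Greenwood variance
  (:func:`km_estimate`) and the log-rank test (:func:`logrank_test`);
* Aalen-Johansen cumulative incidence under competing risks
  (:func:`aalen_johansen`), built from the same product-limit overall
  survival so that ``S(t) + sum_k CIF_k(t) = 1`` holds exactly at every
  event time;
* Gray's K-sample test comparing cumulative incidence functions
  (:func:`gray_test`);
* stratified cause-specific Cox proportional-hazards regression with
  Wald inference (:func:`coxph_cause_specific`), where competing-cause
  events are censored at their time.

Event coding convention: ``cause`` is 0 for censoring and a positive
integer per event type (1 = relapse/progression, 2 = non-relapse death
in the transplant setting).  Times are in months.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "CIFCurve",
    "TestResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "aalen_johansen",
    "gray_test",
    "coxph_cause_specific",
]


@dataclass
class KMCurve:
    """Kaplan-Meier curve: step estimates at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood
    at_risk: np.ndarray
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t): the step-function value at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence curve for one cause."""

    cause: int
    times: np.ndarray
    cif: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[idx])


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


@dataclass
class CoxResult:
    """Cause-specific Cox fit: one row per coefficient plus metadata."""

    summary: pd.DataFrame  # covariate, coef, se, hr, ci_low, ci_high, p
    n: int
    n_events: int
    cause: object
    strata: tuple[str, ...]
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[self.summary["covariate"] == covariate, "hr"].iloc[0])

    def row(self, covariate: str) -> pd.Series:
        return self.summary.loc[self.summary["covariate"] == covariate].iloc[0]


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.size == 0:
        raise ValueError("no records")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and positive")
    return t, e


def _counting(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct times and at-risk counts Y(t) for a sample."""
    ts = np.unique(times)
    # Y(t) = #{i : T_i >= t}
    at_risk = times.size - np.searchsorted(np.sort(times), ts, side="left")
    return ts, at_risk


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    ``event`` is 1/True for an event, 0/False for censoring (for a
    composite endpoint such as event-free survival, code any
    non-censored cause as 1).  Tied failures are handled by the
    simultaneous-failure convention.
    """
    t, e = _as_arrays(time, event)
    e = (np.asarray(e) != 0).astype(int)
    ts = np.unique(t)
    order = np.sort(t)
    y = t.size - np.searchsorted(order, ts, side="left")
    d = np.bincount(np.searchsorted(ts, t[e == 1]), minlength=ts.size)
    surv = np.cumprod(1.0 - d / y)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(y > d, d / (y * (y - d)), 0.0)
    var = surv**2 * np.cumsum(gw_terms)
    return KMCurve(
        times=ts, survival=surv, variance=var, at_risk=y,
        n=t.size, n_events=int(e.sum()),
    )


def aalen_johansen(time, cause, cause_of_interest: int) -> CIFCurve:
    """Aalen-Johansen cumulative incidence for one cause under competing risks.

    ``cause`` is 0 for censoring, positive integers for event types.  The
    CIF increments are S(t-) * d_k(t)/Y(t) with S the all-cause
    product-limit survival, so survival and all CIFs partition 1 exactly.
    The variance is the standard counting-process (delta-method)
    estimator for the Aalen-Johansen functional.
    """
    t, c = _as_arrays(time, cause)
    c = np.asarray(c, dtype=int)
    if np.any(c < 0):
        raise ValueError("negative cause codes are not allowed")
    if cause_of_interest <= 0:
        raise ValueError("cause_of_interest must be a positive event code")
    known = set(np.unique(c))
    if cause_of_interest not in known and len(known - {0}) > 0:
        _warnings.warn(f"no events of cause {cause_of_interest} observed")

    ts = np.unique(t)
    order = np.sort(t)
    y = t.size - np.searchsorted(order, ts, side="left")
    idx_all = np.searchsorted(ts, t)
    d_all = np.bincount(idx_all[c > 0], minlength=ts.size)
    d_k = np.bincount(idx_all[c == cause_of_interest], minlength=ts.size)

    surv_left = np.concatenate([[1.0], np.cumprod(1.0 - d_all / y)[:-1]])
    inc = surv_left * d_k / y
    cif = np.cumsum(inc)
    surv = np.cumprod(1.0 - d_all / y)

    # Delta-method variance (Aalen 1978 form): at each event time s,
    # V(t) = sum_{s<=t} [CIF(t)-CIF(s)]^2 dA(s)
    #      + sum S(s-)^2 (1 - 2[CIF(t)-CIF(s)]/S(s-) ... ) -- expanded below
    # using dA(s) = d.(s)/(Y(s)(Y(s)-d.(s))) for the overall-survival part
    # and binomial-type terms for the cause-specific part.
    with np.errstate(divide="ignore", invalid="ignore"):
        dA = np.where(y > d_all, d_all / (y * (y - d_all)), 0.0)
        term_b = surv_left**2 * np.where(
            y > 0, (y - d_k) / y * d_k / y**2, 0.0
        )
        cross = surv_left * np.where(y > 0, d_k / y**2, 0.0)
    var = np.empty_like(cif)
    for i in range(ts.size):
        diff = cif[i] - cif[: i + 1]
        var[i] = (
            np.sum(diff**2 * dA[: i + 1])
            + np.sum(term_b[: i + 1])
            - 2.0 * np.sum(diff * cross[: i + 1])
        )
    return CIFCurve(
        cause=cause_of_interest, times=ts, cif=cif, variance=np.maximum(var, 0.0),
        at_risk=y, n=t.size, n_events=int(d_k.sum()),
    )


def logrank_test(time, event, group) -> TestResult:
    """K-sample log-rank test (chi-square with K-1 df)."""
    t, e = _as_arrays(time, event)
    g = np.asarray(group)
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(t, g, (e != 0).astype(int))
    return TestResult(
        statistic=float(res.test_statistic),
        df=labels.size - 1,
        p_value=float(res.p_value),
        method="log-rank",
    )


def gray_test(
    time, cause, group, cause_of_interest: int = 1, rho: float = 0.0
) -> TestResult:
    """Gray's (1988) K-sample test for equality of cumulative incidence.

    Compares the improper subdistribution hazards of ``cause_of_interest``
    between groups using the modified risk sets
    ``R_j(t) = Y_j(t) (1 - F_1j(t-)) / S_j(t-)``, with the variance
    estimator assembled from the martingale representation of the score
    (including the correction terms induced by estimating ``F`` and ``S``
    inside the risk sets).  The statistic is chi-square with K-1 df.
    """
    t, c = _as_arrays(time, cause)
    c = np.asarray(c, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    K = labels.size
    if K < 2:
        raise ValueError("Gray's test needs at least two groups")
    for lab in labels:
        if not np.any(g == lab):  # pragma: no cover - unique() precludes this
            raise ValueError(f"group {lab!r} is empty")
    if not np.any(c == cause_of_interest):
        raise ValueError(f"no events of cause {cause_of_interest}")

    ts = np.unique(t)
    m = ts.size
    # per-group counting processes on the pooled time grid
    Y = np.zeros((K, m))
    d1 = np.zeros((K, m))
    do = np.zeros((K, m))
    for j, lab in enumerate(labels):
        sel = g == lab
        tj = t[sel]
        cj = c[sel]
        Y[j] = tj.size - np.searchsorted(np.sort(tj), ts, side="left")
        idx = np.searchsorted(ts, tj)
        d1[j] = np.bincount(idx[cj == cause_of_interest], minlength=m)
        do[j] = np.bincount(idx[(cj != cause_of_interest) & (cj > 0)], minlength=m)

    with np.errstate(divide="ignore", invalid="ignore"):
        # group all-cause survival, and group CIFs (value and left limit)
        frac_all = np.where(Y > 0, (d1 + do) / Y, 0.0)
        S = np.cumprod(1.0 - frac_all, axis=1)
        S_left = np.concatenate([np.ones((K, 1)), S[:, :-1]], axis=1)
        inc1 = S_left * np.where(Y > 0, d1 / Y, 0.0)
        F1 = np.cumsum(inc1, axis=1)
        F1_left = np.concatenate([np.zeros((K, 1)), F1[:, :-1]], axis=1)
        inco = S_left * np.where(Y > 0, do / Y, 0.0)
        Fo = np.cumsum(inco, axis=1)

        # pooled CIF of the cause of interest (for the rho weight)
        Yp = Y.sum(axis=0)
        d1p = d1.sum(axis=0)
        dop = do.sum(axis=0)
        Sp = np.cumprod(1.0 - np.where(Yp > 0, (d1p + dop) / Yp, 0.0))
        Sp_left = np.concatenate([[1.0], Sp[:-1]])
        F1p = np.cumsum(Sp_left * np.where(Yp > 0, d1p / Yp, 0.0))
        F1p_left = np.concatenate([[0.0], F1p[:-1]])
        w = (1.0 - F1p_left) ** rho

        # modified (subdistribution) risk sets
        R = np.where(S_left > 0, Y * (1.0 - F1_left) / S_left, 0.0)
        Rtot = R.sum(axis=0)

        dLam1 = np.where(Rtot > 0, d1.sum(axis=0) / Rtot, 0.0)
        # scores
        zz = np.where(Rtot > 0, R / Rtot, 0.0)
        score = ((d1 - zz * d1.sum(axis=0)) * w).sum(axis=1)

        # e_{jl}(t) = delta_{jl} - R_j/Rtot ; B_{jl}(u) = sum_{t>u} w e_jl (Y_l/S_l(t-)) dLam1
        e = np.eye(K)[:, :, None] - zz[:, None, :]  # axes (j, l, t)
        YoverS = np.where(S_left > 0, Y / S_left, 0.0)  # (l, t)
        integrand = w * e * YoverS[None, :, :] * dLam1[None, None, :]
        # exclusive reverse cumulative sum over time
        B = np.flip(np.cumsum(np.flip(integrand, axis=2), axis=2), axis=2) - integrand

        invY = np.where(Y > 0, 1.0 / Y, 0.0)
        H1 = w[None, None, :] * e - B * Fo[None, :, :] * invY[None, :, :]
        Ho = -B * (1.0 - F1)[None, :, :] * invY[None, :, :]

        # covariance: sum over groups l and times of H H' against dN
        V = np.einsum("jlt,klt,lt->jk", H1, H1, d1) + np.einsum(
            "jlt,klt,lt->jk", Ho, Ho, do
        )

    zv = score[: K - 1]
    Vv = V[: K - 1, : K - 1]
    try:
        chi2 = float(zv @ np.linalg.solve(Vv, zv))
    except np.linalg.LinAlgError:
        chi2 = float(zv @ np.linalg.pinv(Vv) @ zv)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, K - 1)) if chi2 > 0 else 1.0
    return TestResult(statistic=chi2, df=K - 1, p_value=min(p, 1.0), method="Gray")


def coxph_cause_specific(
    df: pd.DataFrame,
    covariates: list[str],
    cause: object = 1,
    duration_col: str = "time_months",
    cause_col: str = "cause",
    strata: list[str] | str | None = None,
    composite: bool = False,
    standardize: bool = False,
) -> CoxResult:
    """Cause-specific Cox proportional-hazards regression (Efron ties).

    Events of competing causes are censored at their event time
    (cause-specific convention).  With ``composite=True`` any
    non-censored cause counts as the event (e.g. event-free survival).
    Categorical covariates are dummy-coded against their first observed
    level, with missing values kept as an explicit ``missing`` category;
    rows with missing continuous covariates are dropped with a logged
    count.  Wald confidence intervals use the normal 1.96 quantile and
    two-sided Wald p-values are reported.
    """
    if isinstance(strata, str):
        strata = [strata]
    strata = list(strata or [])
    warn: list[str] = []

    work = df[[duration_col, cause_col] + covariates + strata].copy()
    if composite:
        work["__event"] = (work[cause_col] > 0).astype(int)
    else:
        work["__event"] = (work[cause_col] == cause).astype(int)
    work = work.drop(columns=[cause_col])

    design_cols: list[str] = []
    for cov in covariates:
        col = work[cov]
        if col.dtype.kind in "biufc" and col.nunique(dropna=True) > 2:
            n_missing = int(col.isna().sum())
            if n_missing:
                warn.append(f"dropped {n_missing} rows with missing {cov}")
                work = work[col.notna()]
                col = work[cov]
            if standardize and col.std() > 0:
                work[cov] = (col - col.mean()) / col.std()
            design_cols.append(cov)
        else:
            filled = col.astype(object).where(col.notna(), "missing").astype(str)
            if isinstance(col.dtype, pd.CategoricalDtype):
                # a Categorical's declared order fixes the reference level
                levels = [str(l) for l in col.cat.categories
                          if (filled == str(l)).any()]
                if (filled == "missing").any() and "missing" not in levels:
                    levels.append("missing")
            else:
                levels = sorted(filled.unique())
            ref = levels[0]
            for level in levels[1:]:
                name = f"{cov}[{level}]"
                work[name] = (filled == level).astype(float)
                design_cols.append(name)
            work = work.drop(columns=[cov])

    # collinearity guard: identical (or constant) design columns
    X = work[design_cols].astype(float)
    const = [c for c in design_cols if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate column(s): {const}")
    corr = X.corr().abs()
    for i, a in enumerate(design_cols):
        for b in design_cols[i + 1:]:
            if corr.loc[a, b] > 0.9999:
                raise ValueError(f"collinear covariates: {a}, {b}")

    n = len(work)
    n_events = int(work["__event"].sum())
    if n_events == 0:
        raise ValueError(f"no events of cause {cause!r}")

    cph = CoxPHFitter()
    converged = True
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cph.fit(
                work,
                duration_col=duration_col,
                event_col="__event",
                strata=strata or None,
                formula=" + ".join(f"Q('{c}')" for c in design_cols),
            )
    except Exception as exc:  # monotone likelihood / separation
        raise_or_flag = str(exc)
        converged = False
        warn.append(f"fit failed: {raise_or_flag}")
        empty = pd.DataFrame(
            columns=["covariate", "coef", "se", "hr", "ci_low", "ci_high", "p"]
        )
        return CoxResult(empty, n, n_events, cause, tuple(strata), False, warn)

    coefs = cph.params_
    ses = cph.standard_errors_
    rows = []
    for name in coefs.index:
        clean = name.replace("Q('", "").replace("')", "")
        b = float(coefs[name])
        se = float(ses[name])
        rows.append(
            {
                "covariate": clean,
                "coef": b,
                "se": se,
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * se)),
                "ci_high": float(np.exp(b + 1.96 * se)),
                "p": float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
            }
        )
    return CoxResult(
        summary=pd.DataFrame(rows),
        n=n,
        n_events=n_events,
        cause="composite" if composite else cause,
        strata=tuple(strata),
        converged=converged,
        warnings=warn,
    )
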