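"""The statistical battery: association tests, survival models, model
comparison.

Standard procedures are delegated to the established implementations
(scipy for contingency/rank tests, lifelines for Kaplan–Meier and Cox,
scikit-survival for IPCW time-dependent AUC); what no installed library
provides is implemented here: the standardized log-rank Z used by cutpoint
selection, the Grambsch–Therneau proportional-hazards test (per-covariate
and global), categorical NRI, and the DeLong AUC confidence interval.

Conventions fixed across the package: Pearson chi-square is uncorrected (no
Yates), Fisher is two-sided by summing less-probable tables, the t-test
pools variances by default, Cox ties use Efron, and Wald CIs use the 1.96
normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats as sps

__all__ = [
    "SurvivalData",
    "CoxFit",
    "KMCurve",
    "pearson_chi2",
    "fisher_exact",
    "t_test",
    "mann_whitney",
    "km_estimate",
    "logrank_test",
    "logrank_z",
    "cox_fit",
    "ph_test",
    "td_roc",
    "c_index",
    "lrt_nested",
    "nri",
    "roc_cutoff",
]


@dataclass
class SurvivalData:
    """Follow-up times (months), event indicators, optional covariates."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event, int)
        if self.time.shape != self.event.shape:
            raise ValueError("time/event length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("events must be 0/1")
        if self.covariates is not None and len(self.covariates) != len(self.time):
            raise ValueError("covariate rows != observations")

    def frame(self, columns: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        if self.covariates is not None:
            cols = columns if columns is not None else list(self.covariates.columns)
            for c in cols:
                df[c] = np.asarray(self.covariates[c])
        return df


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    _fitter: CoxPHFitter = field(repr=False, default=None)
    _frame: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.covariates,
        )


@dataclass
class KMCurve:
    """Product-limit estimate for one group.

    ``median`` is the first time at which S(t) <= 0.5, ``inf`` when the
    curve never reaches 0.5 (rendered as "-" in reports).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int
    n_events: int


# ----------------------------------------------------------- contingency


def pearson_chi2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 (or RxC) count table."""
    table = np.asarray(table)
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p on a 2x2 table (sum of hypergeometric
    probabilities no larger than the observed table's)."""
    table = np.asarray(table)
    return float(sps.fisher_exact(table).pvalue)


def t_test(x, y, pooled: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t; pooled variance by default, Welch otherwise."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction."""
    res = sps.mannwhitneyu(
        np.asarray(x, float), np.asarray(y, float),
        alternative="two-sided", method="asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


# -------------------------------------------------------------- survival


def km_estimate(data: SurvivalData, group=None):
    """Kaplan–Meier per group (dict keyed by group level) or overall."""
    if group is None:
        return _km_one(data.time, data.event)
    group = np.asarray(group)
    return {
        g: _km_one(data.time[group == g], data.event[group == g])
        for g in pd.unique(group)
    }


def _km_one(time: np.ndarray, event: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy()
    at_risk = np.array([np.sum(time >= t) for t in times])
    med = kmf.median_survival_time_
    return KMCurve(
        times=times,
        survival=s,
        at_risk=at_risk,
        median=float(med),
        n=len(time),
        n_events=int(event.sum()),
    )


def logrank_z(time, event, group) -> float:
    """Signed standardized log-rank statistic (O - E)/sqrt(V) for the
    ``group == True`` arm, hypergeometric variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g = np.asarray(group).astype(bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at = time >= t
        n = at.sum()
        n1 = (at & g).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e / math.sqrt(var))


def logrank_test(data: SurvivalData, group) -> tuple[float, float]:
    """Two-group log-rank: chi-square statistic (df 1) and p-value."""
    z = logrank_z(data.time, data.event, group)
    chi2 = z * z
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def cox_fit(
    data: SurvivalData, covariates: list[str], ties: str = "efron"
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties default, Breslow by flag)."""
    if data.event.sum() < 1:
        raise ValueError("no events")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be efron or breslow")
    df = data.frame(covariates)
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    if ties == "breslow":
        # statsmodels PHReg carries the Breslow tie correction; the Efron
        # default goes through lifelines (whose fit also backs ph_test).
        from statsmodels.duration.hazard_regression import PHReg

        model = PHReg(df["time"], df[covariates], status=df["event"], ties="breslow")
        res = model.fit()
        coef = np.asarray(res.params)
        se = np.asarray(res.bse)
        names, llf, fitter = list(covariates), float(res.llf), None
    else:
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event", show_progress=False)
        except Exception as exc:  # monotone likelihood etc.
            raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
        coef = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        names, llf, fitter = list(cph.params_.index), float(cph.log_likelihood_), cph
    return CoxFit(
        covariates=names,
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_low=np.exp(coef - 1.96 * se),
        ci_high=np.exp(coef + 1.96 * se),
        p=np.array([2 * sps.norm.sf(abs(z)) for z in coef / se]),
        log_likelihood=llf,
        n=len(df),
        n_events=int(data.event.sum()),
        _fitter=fitter,
        _frame=df,
    )


def ph_test(fit: CoxFit, data: SurvivalData | None = None) -> pd.DataFrame:
    """Grambsch–Therneau proportional-hazards test, KM-transformed time.

    Correlates (unscaled) Schoenfeld residuals with g(t) = 1 - KM(t); returns
    one chi-square row per covariate plus a GLOBAL row (df = #covariates).
    """
    cph = fit._fitter
    if cph is None:
        raise ValueError("ph_test needs an Efron-ties fit (Schoenfeld residuals)")
    df = fit._frame
    resid = cph.compute_residuals(df, kind="schoenfeld")
    # rows are event subjects; order by event time
    ev_times = df.loc[resid.index, "time"].to_numpy()
    order = np.argsort(ev_times, kind="stable")
    s = resid.to_numpy()[order]
    ev_times = ev_times[order]
    km = _km_one(df["time"].to_numpy(), df["event"].to_numpy())
    g = 1.0 - np.interp(ev_times, km.times, km.survival)
    gt = g - g.mean()
    d = len(gt)
    u = gt @ s  # p-vector
    vinv = fit._fitter.variance_matrix_.to_numpy()  # I^{-1}
    ssg = float(np.sum(gt**2))
    rows = []
    viu = vinv @ u
    for j, name in enumerate(fit.covariates):
        chi2 = d * viu[j] ** 2 / (ssg * vinv[j, j])
        rows.append({"covariate": name, "chi2": chi2, "df": 1, "p": sps.chi2.sf(chi2, 1)})
    chi2_g = d * float(u @ viu) / ssg
    p = len(fit.covariates)
    rows.append({"covariate": "GLOBAL", "chi2": chi2_g, "df": p, "p": sps.chi2.sf(chi2_g, p)})
    return pd.DataFrame(rows).set_index("covariate")


def td_roc(
    marker,
    data: SurvivalData,
    horizons,
    n_boot: int = 500,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Cumulative/dynamic time-dependent AUC with IPCW and bootstrap CI.

    Cases at horizon t are subjects with an event by t, controls those still
    event-free after t; censoring is weighted out by the Kaplan–Meier
    estimate of the censoring distribution.  Returns one row per horizon
    with ``auc, ci_low, ci_high``.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    marker = np.asarray(marker, float)
    horizons = np.atleast_1d(np.asarray(horizons, float))
    tmax = data.time[data.event == 1].max() if data.event.any() else data.time.max()
    if np.any(horizons >= data.time.max()) or np.any(horizons > tmax):
        raise ValueError("horizons must lie within the observed event range")
    y = Surv.from_arrays(event=data.event.astype(bool), time=data.time)
    auc, _ = cumulative_dynamic_auc(y, y, marker, horizons)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(marker)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            yb = Surv.from_arrays(event=data.event[idx].astype(bool), time=data.time[idx])
            ab, _ = cumulative_dynamic_auc(yb, yb, marker[idx], horizons)
            boots.append(ab)
        except (ValueError, ZeroDivisionError):
            continue
    alpha = (1 - ci_level) / 2
    if boots:
        bmat = np.vstack(boots)
        lo = np.nanpercentile(bmat, 100 * alpha, axis=0)
        hi = np.nanpercentile(bmat, 100 * (1 - alpha), axis=0)
    else:
        lo = np.full_like(auc, np.nan)
        hi = np.full_like(auc, np.nan)
    return pd.DataFrame({"horizon": horizons, "auc": auc, "ci_low": lo, "ci_high": hi})


def c_index(marker, data: SurvivalData) -> float:
    """Harrell's concordance of a risk marker (higher marker = higher risk);
    marker ties count 0.5."""
    return float(concordance_index(data.time, -np.asarray(marker, float), data.event))


def lrt_nested(fit_full: CoxFit, fit_reduced: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models fit to the same data."""
    if not set(fit_reduced.covariates) <= set(fit_full.covariates):
        raise ValueError("models are not nested")
    if fit_full.n != fit_reduced.n or fit_full.n_events != fit_reduced.n_events:
        raise ValueError("models were fit to different data")
    chi2 = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    chi2 = max(chi2, 0.0)
    dof = len(fit_full.covariates) - len(fit_reduced.covariates)
    p = float(sps.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return float(chi2), dof, p


def nri(
    risk_old, risk_new, outcome, thresholds
) -> tuple[float, float, float]:
    """Categorical net reclassification improvement.

    Risk categories come from ``thresholds`` (ascending cut points); NRI =
    [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)].
    """
    risk_old = np.asarray(risk_old, float)
    risk_new = np.asarray(risk_new, float)
    outcome = np.asarray(outcome).astype(bool)
    if not (len(risk_old) == len(risk_new) == len(outcome)):
        raise ValueError("inputs must have equal length")
    thresholds = np.atleast_1d(np.asarray(thresholds, float))
    cat_old = np.digitize(risk_old, thresholds)
    cat_new = np.digitize(risk_new, thresholds)
    up = cat_new > cat_old
    down = cat_new < cat_old
    n_ev = outcome.sum()
    n_ne = (~outcome).sum()
    if n_ev == 0 or n_ne == 0:
        raise ValueError("need both events and non-events")
    nri_event = (up[outcome].sum() - down[outcome].sum()) / n_ev
    nri_nonevent = (down[~outcome].sum() - up[~outcome].sum()) / n_ne
    return float(nri_event + nri_nonevent), float(nri_event), float(nri_nonevent)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = sps.rankdata(allv)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (r_all[:m] - r_pos) / n
    v10 = 1.0 - (r_all[m:] - r_neg) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s01 / m + s10 / n)
    zq = sps.norm.ppf(1 - (1 - level) / 2)
    return float(auc), float(max(auc - zq * se, 0.0)), float(min(auc + zq * se, 1.0))


def roc_cutoff(marker, binary_label) -> dict:
    """Empirical ROC AUC with DeLong CI and the Youden-J optimal cutoff.

    Higher marker values indicate the positive class.  On J ties the lower
    cutoff is returned.
    """
    from sklearn.metrics import roc_curve

    marker = np.asarray(marker, float)
    label = np.asarray(binary_label).astype(bool)
    if label.all() or not label.any():
        raise ValueError("need both classes")
    fpr, tpr, thresholds = roc_curve(label, marker)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend -> last = lowest
    auc, lo, hi = _delong_ci(marker[label], marker[~label])
    return {
        "auc": auc,
        "cutoff": float(thresholds[best]),
        "auc_ci": (lo, hi),
        "youden_j": float(j.max()),
    }
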