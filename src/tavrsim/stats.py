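"""Validation statistics: diagnostic accuracy, ROC, regression, survival.

These are the analyses used to validate contact-pressure scores against
clinical outcomes on a cohort: 2x2 diagnostic summaries with odds ratios and
Fisher exact tests, empirical ROC curves with DeLong confidence intervals,
the binormal closed-form AUC, Youden-optimal cutoffs, uni-/multivariate
logistic regression (via statsmodels), Kaplan-Meier / log-rank / Cox
survival comparisons (via lifelines), and the elementary group tests.

Conventions: p-values are two-sided; no multiplicity adjustment; Wald
log-odds CIs; Haldane-Anscombe 0.5 correction (flagged) for zero cells;
Welch correction for the two-sample t-test by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidParameterError

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# 2x2 diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """Diagnostic 2x2 table: test-positive/negative vs event yes/no."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidParameterError("cell counts must be >= 0")
        if self.total == 0:
            raise InvalidParameterError("table must contain observations")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, test_positive, event) -> "TwoByTwo":
        t = np.asarray(test_positive, bool)
        e = np.asarray(event, bool)
        return cls(
            tp=int(np.sum(t & e)),
            fp=int(np.sum(t & ~e)),
            fn=int(np.sum(~t & e)),
            tn=int(np.sum(~t & ~e)),
        )


@dataclass
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    odds_ratio: float
    or_ci: Tuple[float, float]
    fisher_p: float
    continuity_corrected: bool


def two_by_two_metrics(t: TwoByTwo) -> DiagnosticSummary:
    """Standard diagnostic rates, Wald-CI odds ratio and Fisher exact p."""
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan
    acc = (tp + tn) / t.total
    corrected = 0 in (tp, fp, fn, tn)
    a, b, c, d = (tp, fp, fn, tn)
    if corrected:  # Haldane-Anscombe
        a, b, c, d = (x + 0.5 for x in (tp, fp, fn, tn))
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(or_ * np.exp(-Z95 * se)), float(or_ * np.exp(Z95 * se)))
    _, fisher_p = sps.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        odds_ratio=float(or_),
        or_ci=ci,
        fisher_p=float(fisher_p),
        continuity_corrected=corrected,
    )


def reconstruct_from_operating_point(
    n: int, n_events: int, sensitivity: float, specificity: float
) -> TwoByTwo:
    """Integer 2x2 implied by a printed operating point on a known cohort."""
    tp = int(round(sensitivity * n_events))
    tn = int(round(specificity * (n - n_events)))
    return TwoByTwo(tp=tp, fp=(n - n_events) - tn, fn=n_events - tp, tn=tn)


def reconstruct_from_stratum_incidence(
    n: int, n_events: int, incidence_pos: float, incidence_neg: float
) -> TwoByTwo:
    """Brute-force the integer stratum split consistent with printed incidences.

    Searches every split of ``n`` into test-positive/negative strata whose
    rounded event counts total ``n_events`` and returns the split whose
    stratum incidences are closest to the printed ones.
    """
    best = None
    best_err = np.inf
    for n_pos in range(1, n):
        n_neg = n - n_pos
        tp = int(round(incidence_pos * n_pos))
        fn_neg = int(round(incidence_neg * n_neg))
        if tp + fn_neg != n_events:
            continue
        err = abs(tp / n_pos - incidence_pos) + abs(fn_neg / n_neg - incidence_neg)
        if err < best_err:
            best_err = err
            best = TwoByTwo(tp=tp, fp=n_pos - tp, fn=fn_neg, tn=n_neg - fn_neg)
    if best is None:
        raise DegenerateInputError(
            "no integer stratum split is consistent with the printed incidences"
        )
    return best


def pooled_mean(group_means: Sequence[float], group_sizes: Sequence[int]) -> float:
    """Prevalence-weighted combination of group means."""
    return float(np.average(group_means, weights=group_sizes))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    thresholds: pd.DataFrame  # threshold, sensitivity, specificity

    def __post_init__(self):
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise InvalidParameterError("AUC must lie within its CI")


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> Tuple[float, float]:
    """Empirical (midrank) AUC and its DeLong variance."""
    m, n = pos.size, neg.size
    allx = np.concatenate([pos, neg])
    rk_all = _midrank(allx)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(scores, labels) -> RocResult:
    """Empirical Mann-Whitney AUC with DeLong 95% CI and p-value vs 0.5.

    Ties are handled by midranks. Requires both classes present.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if s.shape != y.shape:
        raise InvalidParameterError("scores and labels must align")
    if y.all() or (~y).all():
        raise DegenerateInputError("ROC needs both classes present")
    pos, neg = s[y], s[~y]
    auc, var = _delong_auc_variance(pos, neg)
    se = np.sqrt(max(var, 0.0))
    ci = (auc - Z95 * se, auc + Z95 * se)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = np.nan if auc == 0.5 else 0.0
    thresholds = np.unique(s)
    cuts = np.concatenate([thresholds, [np.inf]])
    sens = [(pos >= c).mean() for c in cuts]
    spec = [(neg < c).mean() for c in cuts]
    table = pd.DataFrame(
        {"threshold": cuts, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(
        auc=auc,
        ci_low=float(min(ci[0], auc)),
        ci_high=float(max(ci[1], auc)),
        p_value=float(p),
        thresholds=table,
    )


def binormal_auc(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """Closed-form ROC area for Gaussian score distributions in each class."""
    denom = np.hypot(sd1, sd0)
    if denom == 0:
        if mu1 == mu0:
            raise DegenerateInputError("binormal AUC undefined for identical point masses")
        return 1.0 if mu1 > mu0 else 0.0
    return float(sps.norm.cdf((mu1 - mu0) / denom))


def simulate_group_auc(
    mu1: float, sd1: float, mu0: float, sd0: float,
    n_per_group: int = 100_000, seed: int = 0,
) -> float:
    """Empirical AUC of Gaussian group-conditional draws (Monte-Carlo check)."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(mu1, sd1, n_per_group)
    neg = rng.normal(mu0, sd0, n_per_group)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_per_group, bool), np.zeros(n_per_group, bool)])
    return roc_auc(scores, labels).auc


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def optimal_cutoff(roc: RocResult) -> CutoffResult:
    """Operating point maximizing Youden's J; ties go to the lowest threshold."""
    t = roc.thresholds
    if len(t) < 2:
        raise InvalidParameterError("need at least two thresholds")
    j = t["sensitivity"] + t["specificity"] - 1.0
    best = t.loc[j.round(12).idxmax()]
    # idxmax returns the first (lowest-threshold) row among ties
    return CutoffResult(
        threshold=float(best["threshold"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        youden_j=float(best["sensitivity"] + best["specificity"] - 1.0),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    table: pd.DataFrame  # index predictor; or, ci_low, ci_high, p
    separation: bool
    converged: bool

    def odds_ratio(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "or"])


def logistic_fit(outcome, predictors: pd.DataFrame) -> LogisticResult:
    """Maximum-likelihood logistic regression with per-predictor Wald ORs.

    ``predictors`` is a DataFrame (one column per predictor). On detected
    complete separation the model is refit with a light L2 penalty and the
    result flagged — ORs are then shrunken and should be read qualitatively.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome must contain both classes")
    X = sm.add_constant(np.asarray(predictors, float), has_constant="add")
    names = ["const"] + list(predictors.columns)
    separation = False
    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        converged = bool(fit.mle_retvals.get("converged", True))
        if np.any(np.abs(params[1:]) > 15) or np.any(~np.isfinite(bse)):
            raise sps.FitError("separation suspected")
    except Exception:
        separation = True
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0)
        params = np.asarray(fit.params)
        try:
            bse = np.asarray(fit.bse)
        except Exception:
            bse = np.full_like(params, np.nan)
    rows = {}
    for i, name in enumerate(names):
        if name == "const":
            continue
        or_ = float(np.exp(params[i]))
        se = bse[i]
        if np.isfinite(se):
            ci = (or_ * np.exp(-Z95 * se), or_ * np.exp(Z95 * se))
            p = 2.0 * sps.norm.sf(abs(params[i] / se)) if se > 0 else np.nan
        else:
            ci, p = (np.nan, np.nan), np.nan
        rows[name] = {"or": or_, "ci_low": ci[0], "ci_high": ci[1], "p": p}
    return LogisticResult(
        table=pd.DataFrame(rows).T, separation=separation, converged=converged
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    km: Dict[object, pd.DataFrame]
    logrank_p: float
    hazard_ratio: float
    hr_ci: Tuple[float, float]
    cox_p: float

    def summary(self) -> str:
        return (
            f"hazard ratio, {self.hazard_ratio:.2f}; 95% CI, "
            f"{self.hr_ci[0]:.2f}-{self.hr_ci[1]:.2f}; p = {self.logrank_p:.2g} "
            "by log-rank test"
        )


def survival_analysis(time, event, group) -> SurvivalResult:
    """Two-group Kaplan-Meier, log-rank test, and single-covariate Cox HR."""
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    g = np.asarray(group)
    if np.any(t <= 0):
        raise InvalidParameterError("survival times must be > 0")
    values = np.unique(g)
    if values.size != 2:
        raise InvalidParameterError("exactly two groups required")
    if e.sum() == 0:
        raise DegenerateInputError("no events: hazard ratio undefined")
    km: Dict[object, pd.DataFrame] = {}
    for v in values:
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == v], e[g == v], label=str(v))
        km[v] = kmf.survival_function_
    lr = logrank_test(t[g == values[0]], t[g == values[1]],
                      e[g == values[0]], e[g == values[1]])
    df = pd.DataFrame({"time": t, "event": e.astype(int),
                       "x": (g == values[1]).astype(float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_
    hr_ci = (float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1])))
    return SurvivalResult(
        km=km,
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=hr_ci,
        cox_p=float(cph.summary["p"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# elementary group tests (caller-explicit choice, never silent)
# ---------------------------------------------------------------------------

def t_test(a, b, welch: bool = True) -> Tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs >= 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> Tuple[float, float]:
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def anova(*groups) -> Tuple[float, float]:
    if len(groups) < 3:
        raise InvalidParameterError("ANOVA here is for > 2 groups")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def chi_squared(table) -> Tuple[float, float]:
    res = sps.chi2_contingency(np.asarray(table))
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> Tuple[float, float]:
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


_GROUP_TESTS = {
    "t": t_test,
    "mannwhitney": mann_whitney,
    "anova": anova,
    "chi2": chi_squared,
    "fisher": fisher_exact,
}


def compare_groups(*data, test: str) -> Tuple[float, float]:
    """Dispatch to an explicitly named group test; the choice is never implicit."""
    if test not in _GROUP_TESTS:
        raise InvalidParameterError(f"unknown test {test!r}; use {sorted(_GROUP_TESTS)}")
    return _GROUP_TESTS[test](*data)


# ---------------------------------------------------------------------------
# results ledger
# ---------------------------------------------------------------------------

def results_ledger(entries: Iterable[Dict]) -> pd.DataFrame:
    """Flat (analysis, estimate, ci_low, ci_high, p) table for serialization."""
    cols = ["analysis", "estimate", "ci_low", "ci_high", "p"]
    df = pd.DataFrame(list(entries))
    for c in cols:
        if c not in df:
            df[c] = np.nan
    return df[cols]
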