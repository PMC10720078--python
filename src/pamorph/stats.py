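"""Diagnostic statistics for two-group imaging-biomarker studies.

Implements the analysis chain used to evaluate CT measurements against
right-heart-catheterization pressures in pulmonary hypertension:

* normality-gated two-group tests (Shapiro-Wilk deciding between Student's
  t and the Wilcoxon rank-sum test);
* Pearson chi-square (no continuity correction) or Fisher's exact test for
  2x2 tables, chosen by the expected-count rule;
* normality-gated Pearson/Spearman correlation;
* ROC analysis with the Mann-Whitney AUC estimator, Youden-optimal cutoffs
  and the confusion metrics at the cutoff, with a DeLong confidence interval;
* DeLong's test for comparing two correlated AUCs measured on the same
  subjects;
* decision-curve analysis (net benefit over a threshold-probability grid);
* forward stepwise linear regression with a p-to-enter gate, used to build
  pressure-prediction equations from the vessel measurements.

Conventions follow the clinical software this mirrors: chi-square is
Pearson's without Yates correction, Fisher's exact is two-sided by the
point-probability rule, and a subject is called positive when its score is
greater than or equal to the cutoff.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class SampleSizeError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


class ClassError(ValueError):
    """Both outcome classes must be present."""


class CollinearityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparisonResult:
    variable: str
    test: str  # 't' | 'wilcoxon' | 'chi-square' | 'fisher'
    statistic: float
    p: float
    summary_a: str = ""
    summary_b: str = ""


def normality_gate(sample_a, sample_b, alpha: float = 0.05) -> str:
    """'t' iff both samples pass Shapiro-Wilk at ``alpha``, else 'wilcoxon'."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise SampleSizeError("Shapiro-Wilk needs at least 3 observations per sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = sps.shapiro(a).pvalue
        pb = sps.shapiro(b).pvalue
    return "t" if (pa > alpha and pb > alpha) else "wilcoxon"


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum Z with tie correction and two-sided normal p."""
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie = ((counts**3 - counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return 0.0, 1.0
    z = (r1 - mu) / math.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def compare_groups(sample_a, sample_b, variable: str = "", alpha: float = 0.05) -> GroupComparisonResult:
    """Two-group comparison with the normality gate.

    The t branch is Student's t with pooled variance; the nonparametric
    branch reports the rank-sum Z statistic.  Summaries are mean +- SD for
    the t branch and median (IQR) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    test = normality_gate(a, b, alpha)
    if test == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        summ = [f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" for x in (a, b)]
        return GroupComparisonResult(variable, "t", float(stat), float(p), *summ)
    z, p = _ranksum_z(a, b)
    summ = [
        f"{np.median(x):.2f} ({np.percentile(x, 25):.2f}~{np.percentile(x, 75):.2f})" for x in (a, b)
    ]
    return GroupComparisonResult(variable, "wilcoxon", z, p, *summ)


def compare_categorical(table, variable: str = "", method: str = "auto") -> GroupComparisonResult:
    """2x2 association test.

    Pearson chi-square without continuity correction when every expected
    count is >= 5, otherwise Fisher's exact test (two-sided by the
    point-probability rule).  ``method`` forces 'chi-square' or 'fisher'.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise DegenerateTableError("expected a 2x2 table of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("table has a zero margin")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    use = method
    if method == "auto":
        use = "chi-square" if np.all(expected >= 5.0) else "fisher"
    rows = [f"{int(t[i, 0])}/{int(t[i].sum())}" for i in (0, 1)]
    if use == "chi-square":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return GroupComparisonResult(variable, "chi-square", float(chi2), float(p), *rows)
    res = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return GroupComparisonResult(variable, "fisher", float(res[0]), float(res[1]), *rows)


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    r: float
    p: float
    method: str  # 'pearson' | 'spearman'


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson when both variables pass Shapiro-Wilk at ``alpha``, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise SampleSizeError("correlation needs at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    if normal:
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(float(r), float(p), "pearson")
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), "spearman")


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong


@dataclass
class ROCResult:
    auc: float
    auc_ci_95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ClassError("both classes must be present")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability P(pos > neg) with ties counted 1/2."""
    pos, neg = _split_scores(scores, labels)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    pos, neg = _split_scores(scores, labels)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # one structural component per positive
    v01 = cmp.mean(axis=0)  # one per negative
    return float(cmp.mean()), v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    _, v10, v01 = _delong_components(np.asarray(scores, dtype=float), labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


@dataclass
class DelongResult:
    z: float
    p: float
    auc_1: float
    auc_2: float


def delong_test(scores_1, scores_2, labels) -> DelongResult:
    """DeLong's test for two correlated AUCs measured on the same subjects."""
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("paired markers must have equal length")
    a1, v10_1, v01_1 = _delong_components(s1, labels)
    a2, v10_2, v01_2 = _delong_components(s2, labels)
    m, n = len(v10_1), len(v01_1)
    if m > 1:
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return DelongResult(0.0, 1.0, a1, a2)
    z = (a1 - a2) / math.sqrt(var)
    return DelongResult(float(z), float(2.0 * sps.norm.sf(abs(z))), a1, a2)


def roc_analysis(scores, labels) -> ROCResult:
    """AUC, Youden-optimal cutoff and the confusion metrics at that cutoff.

    Candidate cutoffs are the observed score values; a subject is positive
    when score >= cutoff; Youden ties are broken toward the lower cutoff
    (higher sensitivity).  The 95% CI uses the DeLong variance, clipped to
    [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _split_scores(s, y)  # validates
    auc = auc_mann_whitney(s, y)
    se = math.sqrt(delong_variance(s, y))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    best = None
    for cut in np.sort(np.unique(s)):
        pred = s >= cut
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, tp, fp)
    _, cutoff, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / len(y)
    return ROCResult(auc, ci, float(cutoff), sens, spec, ppv, npv, acc)


# ---------------------------------------------------------------------------
# decision curve analysis


@dataclass
class DCAResult:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    probabilities: np.ndarray  # per-subject calibrated risk
    calibration: str  # 'logistic' | 'minmax'


def _calibrate_probabilities(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, str]:
    import statsmodels.api as sm

    X = sm.add_constant(scores.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels, X).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and np.abs(fit.params).max() < 1e3:
            return np.asarray(fit.predict(X)), "logistic"
    except Exception:  # perfect separation or failure to converge
        pass
    log.warning("logistic calibration degenerate; falling back to rank-preserving min-max scaling")
    lo, hi = scores.min(), scores.max()
    p = (scores - lo) / (hi - lo) if hi > lo else np.full_like(scores, 0.5)
    return np.clip(p, 1e-6, 1 - 1e-6), "minmax"


def decision_curve(scores, labels, grid=None) -> DCAResult:
    """Net benefit of treating when calibrated risk >= threshold probability.

    nb(pt) = TP/N - (FP/N) * pt / (1 - pt), plus treat-all and treat-none
    reference curves.  Scores are converted to risks by a univariable
    logistic fit (min-max scaling if the fit is degenerate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _split_scores(s, y)
    grid = np.arange(0.01, 1.0, 0.01) if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    prob, how = _calibrate_probabilities(s, y)
    n = len(y)
    prev = y.mean()
    odds = grid / (1.0 - grid)
    pred = prob[None, :] >= grid[:, None]
    tp = (pred & (y == 1)[None, :]).sum(axis=1) / n
    fp = (pred & (y == 0)[None, :]).sum(axis=1) / n
    nb_model = tp - fp * odds
    nb_all = prev - (1.0 - prev) * odds
    return DCAResult(grid, nb_model, nb_all, np.zeros_like(grid), prob, how)


# ---------------------------------------------------------------------------
# forward stepwise regression


@dataclass
class LinearModel:
    """An ordinary least squares model ``response = intercept + X @ coefficients``."""

    response: str
    predictors: list
    intercept: float
    coefficients: list
    r_squared: float | None = None
    r_squared_path: list = field(default_factory=list)

    def predict(self, values) -> float:
        """Evaluate on a mapping (or object with ``as_dict``) of measurement values."""
        if hasattr(values, "as_dict"):
            values = values.as_dict()
        total = self.intercept
        for name, coef in zip(self.predictors, self.coefficients):
            if name not in values or values[name] is None:
                raise KeyError(f"missing predictor {name!r} for the {self.response} model")
            total += coef * float(values[name])
        return float(total)


def forward_stepwise(predictors: pd.DataFrame, response, p_enter: float = 0.05, response_name: str = "y") -> LinearModel:
    """Forward-only stepwise OLS with a partial-F p-to-enter gate.

    Starting from the intercept-only model, the candidate with the smallest
    partial-F p-value is added while that p-value is below ``p_enter``.
    """
    import statsmodels.api as sm

    X_all = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    if len(X_all) != len(y):
        raise ValueError("predictors and response must have equal length")
    if len(y) <= X_all.shape[1] + 2:
        raise SampleSizeError("need n > number of candidates + 2")
    selected: list[str] = []
    path: list[float] = []
    remaining = list(X_all.columns)
    y_scale = float(np.var(y)) * len(y) + 1e-300
    while remaining:
        # stop once the current model fits exactly - further partial-F tests
        # on a zero residual are numerically meaningless
        X_cur = sm.add_constant(X_all[selected]) if selected else np.ones((len(y), 1))
        rss = float(sm.OLS(y, X_cur).fit().ssr)
        if rss <= 1e-12 * y_scale:
            break
        pvals = {}
        for cand in remaining:
            X = sm.add_constant(X_all[selected + [cand]])
            fit = sm.OLS(y, X).fit()
            pvals[cand] = fit.pvalues[cand]
        best = min(pvals, key=pvals.get)
        if not (pvals[best] < p_enter):
            break
        selected.append(best)
        remaining.remove(best)
        X = sm.add_constant(X_all[selected])
        path.append(float(sm.OLS(y, X).fit().rsquared))
    if not selected:
        return LinearModel(response_name, [], float(np.mean(y)), [], 0.0, [])
    X = sm.add_constant(X_all[selected])
    if np.linalg.cond(np.asarray(X)) > 1e8:
        raise CollinearityError(f"selected predictors {selected} are collinear")
    fit = sm.OLS(y, X).fit()
    return LinearModel(
        response_name,
        selected,
        float(fit.params["const"]),
        [float(fit.params[name]) for name in selected],
        float(fit.rsquared),
        path,
    )


def predict_pressure(model: LinearModel, measurements) -> float:
    """Predicted pressure (mmHg) from a fitted or reference linear model."""
    return model.predict(measurements)


#: Reference pressure-prediction equations for the central pulmonary
#: arteries (volumes in mm^3, diameters in mm, pressures in mmHg), as
#: published for a 59-patient CTPA + catheterization study.
REFERENCE_PRESSURE_MODELS = {
    "mPAP": LinearModel("mPAP", ["V_MPA"], 8.178, [0.0006]),
    "DPAP": LinearModel("DPAP", ["V_MPA"], 1.418, [0.0005]),
    "SPAP": LinearModel("SPAP", ["V_RPA", "D_MPA"], -11.137, [0.0006, 1.259]),
}


# ---------------------------------------------------------------------------
# cohort-level drivers (CSV-shaped outputs)


def group_comparison_table(df: pd.DataFrame, variables, group_col: str = "group") -> pd.DataFrame:
    """Continuous two-group comparisons for each variable, one row each."""
    rows = []
    a = df[df[group_col] == "non-PH"]
    b = df[df[group_col] == "PH"]
    for var in variables:
        res = compare_groups(a[var], b[var], variable=var)
        rows.append(
            {
                "variable": var,
                "non_PH": res.summary_a,
                "PH": res.summary_b,
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(df: pd.DataFrame, measurements, pressures=("mPAP", "DPAP", "SPAP")) -> pd.DataFrame:
    """Correlation of each measurement with each pressure (heatmap-shaped)."""
    out = pd.DataFrame(index=list(measurements), columns=list(pressures), dtype=float)
    for m in measurements:
        for p in pressures:
            out.loc[m, p] = correlate(df[m], df[p]).r
    return out


def roc_table(df: pd.DataFrame, markers, group_col: str = "group") -> pd.DataFrame:
    """Per-marker ROC summary shaped like a cutoff/AUC/CI/metrics table."""
    y = (df[group_col] == "PH").astype(int).to_numpy()
    rows = []
    for m in markers:
        r = roc_analysis(df[m].to_numpy(), y)
        rows.append(
            {
                "marker": m,
                "cutoff value": r.cutoff,
                "AUC": r.auc,
                "95% CI": f"{r.auc_ci_95[0]:.3f}~{r.auc_ci_95[1]:.3f}",
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "PPV": r.ppv,
                "NPV": r.npv,
                "Accuracy": r.accuracy,
            }
        )
    return pd.DataFrame(rows)


def delong_pairwise(df: pd.DataFrame, marker_pairs, group_col: str = "group") -> pd.DataFrame:
    """DeLong comparisons for the given (marker_1, marker_2) pairs."""
    y = (df[group_col] == "PH").astype(int).to_numpy()
    rows = []
    for m1, m2 in marker_pairs:
        r = delong_test(df[m1].to_numpy(), df[m2].to_numpy(), y)
        rows.append({"marker_1": m1, "marker_2": m2, "AUC_1": r.auc_1, "AUC_2": r.auc_2, "Z": r.z, "p": r.p})
    return pd.DataFrame(rows)
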