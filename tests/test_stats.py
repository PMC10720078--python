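"""Statistical engine: oracles and invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pamorph import stats as st


# ---------------------------------------------------------------------------
# group comparison


def test_normality_gate_branches():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
    assert st.normality_gate(a, b) == "t"
    skewed = np.exp(rng.normal(0, 1, 200))
    assert st.normality_gate(skewed, b) == "wilcoxon"
    with pytest.raises(st.SampleSizeError):
        st.normality_gate([1.0, 2.0], b)


def test_ranksum_z_matches_scipy():
    rng = np.random.default_rng(1)
    a = np.round(rng.normal(0, 1, 30), 1)  # ties on purpose
    b = np.round(rng.normal(0.5, 1, 40), 1)
    res = st.compare_groups(np.exp(a), np.exp(b))  # lognormal -> wilcoxon branch
    ref = sps.mannwhitneyu(np.exp(a), np.exp(b), method="asymptotic", use_continuity=False)
    assert res.test == "wilcoxon"
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_t_branch_uses_pooled_variance():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 18), rng.normal(0.3, 1, 41)
    res = st.compare_groups(a, b)
    if res.test == "t":
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)


# ---------------------------------------------------------------------------
# 2x2 tables


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[4, 14], [36, 5]], 24.642),  # dyspnea, non-PH 4/18 vs PH 36/41
        ([[12, 6], [10, 31]], 9.560),  # congenital heart disease 12/18 vs 10/41
        ([[7, 11], [10, 31]], 1.282),  # sex (male) 7/18 vs 10/41
    ],
)
def test_pearson_chi_square_reproduces_reported_statistics(table, expected):
    res = st.compare_categorical(table)
    assert res.test == "chi-square"
    assert res.statistic == pytest.approx(expected, abs=5e-4)


def test_chi_square_zero_for_identical_proportions():
    assert st.compare_categorical([[5, 5], [10, 10]]).statistic == pytest.approx(0.0)


def test_small_expected_counts_switch_to_fisher():
    res = st.compare_categorical([[1, 9], [0, 12]])
    assert res.test == "fisher"
    ref = sps.fisher_exact([[1, 9], [0, 12]])
    assert res.p == pytest.approx(ref.pvalue)


def test_zero_margin_rejected():
    with pytest.raises(st.DegenerateTableError):
        st.compare_categorical([[0, 0], [5, 7]])


# ---------------------------------------------------------------------------
# correlation


def test_correlate_linear_is_pearson_one():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 100)
    res = st.correlate(x, 2 * x + 1)
    assert res.method == "pearson"
    assert res.r == pytest.approx(1.0)


def test_correlate_monotone_nonlinear_is_spearman_one():
    rng = np.random.default_rng(4)
    x = np.exp(rng.normal(0, 1, 100))
    res = st.correlate(x, np.log(x) ** 3 + x)
    assert res.method == "spearman"
    assert res.r == pytest.approx(1.0)


def test_spearman_matches_rank_transform_oracle():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 20, 10).astype(float)
    y = rng.integers(0, 20, 10).astype(float)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert sps.spearmanr(x, y).statistic == pytest.approx(oracle)
    # the gated path reports the same coefficient when it chooses spearman
    res = st.correlate(np.exp(x), y)
    if res.method == "spearman":
        assert res.r == pytest.approx(sps.spearmanr(np.exp(x), y).statistic)


def test_correlate_constant_rejected():
    with pytest.raises(ValueError):
        st.correlate(np.ones(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# ROC / Youden


def _brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_examples():
    assert st.auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert st.auc_mann_whitney([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75


def test_auc_matches_pair_counting_exhaustively():
    """All label splits of small score vectors (with ties) agree with the
    brute-force pair-counting estimator."""
    from itertools import combinations

    rng = np.random.default_rng(6)
    for trial in range(6):
        n = int(rng.integers(4, 9))
        scores = rng.integers(0, 4, n).astype(float)  # heavy ties
        for k in range(1, n):
            for pos_idx in combinations(range(n), k):
                labels = np.zeros(n, dtype=int)
                labels[list(pos_idx)] = 1
                assert st.auc_mann_whitney(scores, labels) == pytest.approx(
                    _brute_force_auc(scores, labels)
                )


def test_roc_perfect_separation():
    r = st.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0
    assert r.auc_ci_95[0] <= r.auc <= r.auc_ci_95[1]


def test_roc_invariances():
    rng = np.random.default_rng(7)
    s = rng.normal(0, 1, 60)
    y = (rng.random(60) < 0.5).astype(int)
    if y.sum() in (0, 60):
        y[0] = 1 - y[0]
    a = st.auc_mann_whitney(s, y)
    assert st.auc_mann_whitney(np.exp(s), y) == pytest.approx(a)  # monotone transform
    assert st.auc_mann_whitney(-s, y) == pytest.approx(1.0 - a)  # sign reversal


def test_roc_youden_tie_breaks_low():
    # two cutoffs achieve J = 0.5; the lower one (higher sensitivity) wins
    scores = [1.0, 2.0, 3.0, 4.0]
    r = st.roc_analysis(scores, [0, 1, 0, 1])
    assert r.cutoff == 2.0


def test_roc_single_class_rejected():
    with pytest.raises(st.ClassError):
        st.roc_analysis([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# DeLong


def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(8)
    s = rng.normal(0, 1, 40)
    y = np.r_[np.zeros(15, int), np.ones(25, int)]
    res = st.delong_test(s, s, y)
    assert res.z == 0.0 and res.p == 1.0


def test_delong_rank_invariance():
    rng = np.random.default_rng(9)
    s = rng.normal(0, 1, 40)
    y = np.r_[np.zeros(15, int), np.ones(25, int)]
    res = st.delong_test(s, np.exp(s) + 5, y)
    assert res.z == pytest.approx(0.0, abs=1e-12)


def test_delong_sign_flips_when_markers_swap():
    rng = np.random.default_rng(10)
    base = rng.normal(0, 1, 59)
    y = np.r_[np.zeros(18, int), np.ones(41, int)]
    s1 = base + np.where(y == 1, 1.0, 0.0) + rng.normal(0, 0.5, 59)
    s2 = base + rng.normal(0, 0.5, 59)
    a = st.delong_test(s1, s2, y)
    b = st.delong_test(s2, s1, y)
    assert a.z == pytest.approx(-b.z)
    assert a.p == pytest.approx(b.p)


def test_delong_pairing_mismatch_rejected():
    with pytest.raises(ValueError):
        st.delong_test([1, 2, 3], [1, 2], [0, 1, 1])


# ---------------------------------------------------------------------------
# decision curves


def test_treat_all_curve_closed_form():
    rng = np.random.default_rng(11)
    y = np.r_[np.zeros(18, int), np.ones(41, int)]
    s = rng.normal(0, 1, 59) + y
    dca = st.decision_curve(s, y)
    prev = 41 / 59
    expect = prev - (1 - prev) * dca.thresholds / (1 - dca.thresholds)
    np.testing.assert_allclose(dca.nb_all, expect, atol=1e-12)
    assert np.all(dca.nb_none == 0.0)
    assert np.all(dca.nb_model <= prev + 1e-12)


def test_net_benefit_matches_explicit_confusion_loop():
    rng = np.random.default_rng(12)
    y = (rng.random(30) < 0.4).astype(int)
    y[:2] = [0, 1]
    s = rng.normal(0, 1, 30) + 0.8 * y
    dca = st.decision_curve(s, y, grid=np.array([0.3]))
    p = dca.probabilities
    tp = fp = 0
    for pi, yi in zip(p, y):
        if pi >= 0.3:
            tp += yi
            fp += 1 - yi
    expect = tp / 30 - (fp / 30) * 0.3 / 0.7
    assert dca.nb_model[0] == pytest.approx(expect)


def test_perfect_separation_falls_back_to_minmax():
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    s = np.r_[np.arange(10.0), 100 + np.arange(10.0)]
    dca = st.decision_curve(s, y)
    assert dca.calibration == "minmax"
    assert np.all((dca.probabilities > 0) & (dca.probabilities < 1))


# ---------------------------------------------------------------------------
# stepwise regression


def _stepwise_oracle(X: pd.DataFrame, y: np.ndarray, p_enter: float = 0.05):
    """Exhaustive add-one selection using partial-F tests from raw RSS."""
    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        n = len(y)
        best, best_p = None, None
        for cand in remaining:
            cols = selected + [cand]
            A0 = np.column_stack([np.ones(n)] + [X[c] for c in selected])
            A1 = np.column_stack([np.ones(n)] + [X[c] for c in cols])
            rss0 = np.sum((y - A0 @ np.linalg.lstsq(A0, y, rcond=None)[0]) ** 2)
            rss1 = np.sum((y - A1 @ np.linalg.lstsq(A1, y, rcond=None)[0]) ** 2)
            df2 = n - A1.shape[1]
            f = (rss0 - rss1) / (rss1 / df2) if rss1 > 0 else np.inf
            p = sps.f.sf(f, 1, df2)
            if best_p is None or p < best_p:
                best, best_p = cand, p
        if not (best_p < p_enter):
            break
        selected.append(best)
        remaining.remove(best)
    return selected


def test_stepwise_exact_recovery():
    rng = np.random.default_rng(13)
    x1 = rng.normal(0, 1, 50)
    noise = rng.normal(0, 1, 50)
    model = st.forward_stepwise(pd.DataFrame({"x1": x1, "noise": noise}), 2.0 * x1)
    assert model.predictors == ["x1"]
    assert model.coefficients[0] == pytest.approx(2.0, abs=1e-10)
    assert model.intercept == pytest.approx(0.0, abs=1e-10)
    assert model.r_squared == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_stepwise_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 50
    X = pd.DataFrame(
        {
            "a": rng.normal(0, 1, n),
            "b": rng.normal(0, 1, n),
            "c": rng.normal(0, 1, n),
        }
    )
    y = 1.5 * X["a"] + 0.8 * X["b"] + rng.normal(0, 1.0, n)
    model = st.forward_stepwise(X, y)
    assert model.predictors == _stepwise_oracle(X, y.to_numpy())


def test_stepwise_r_squared_non_decreasing():
    rng = np.random.default_rng(14)
    n = 60
    X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
    y = X["a"] + 0.5 * X["b"] + 0.25 * X["c"] + rng.normal(0, 0.5, n)
    model = st.forward_stepwise(X, y)
    assert all(b >= a - 1e-12 for a, b in zip(model.r_squared_path, model.r_squared_path[1:]))


def test_stepwise_zero_gate_gives_intercept_only():
    rng = np.random.default_rng(15)
    X = pd.DataFrame({"x": rng.normal(0, 1, 30)})
    model = st.forward_stepwise(X, rng.normal(0, 1, 30), p_enter=0.0)
    assert model.predictors == []


def test_stepwise_collinearity_rejected():
    """Two near-duplicate predictors that both enter trip the condition-number
    guard on the selected design matrix."""
    rng = np.random.default_rng(16)
    n = 40
    u = rng.normal(0, 1, n)
    d = rng.normal(0, 1, n)
    v = u + 1e-8 * d  # nearly identical to u
    y = u + 0.5 * d + 0.3 * rng.normal(0, 1, n)  # needs v - u, so both enter
    with pytest.raises(st.CollinearityError):
        st.forward_stepwise(pd.DataFrame({"u": u, "v": v}), y)


# ---------------------------------------------------------------------------
# reference pressure equations


def test_reference_model_intercepts():
    zero = {"V_MPA": 0.0, "V_RPA": 0.0, "D_MPA": 0.0}
    assert st.predict_pressure(st.REFERENCE_PRESSURE_MODELS["mPAP"], zero) == pytest.approx(8.178)
    assert st.predict_pressure(st.REFERENCE_PRESSURE_MODELS["DPAP"], zero) == pytest.approx(1.418)
    assert st.predict_pressure(st.REFERENCE_PRESSURE_MODELS["SPAP"], zero) == pytest.approx(-11.137)


def test_reference_model_linearity():
    m = st.REFERENCE_PRESSURE_MODELS["mPAP"]
    base = st.predict_pressure(m, {"V_MPA": 0.0})
    inc1 = st.predict_pressure(m, {"V_MPA": 10000.0}) - base
    inc2 = st.predict_pressure(m, {"V_MPA": 20000.0}) - base
    assert inc2 == pytest.approx(2 * inc1)


def test_missing_predictor_rejected():
    with pytest.raises(KeyError):
        st.predict_pressure(st.REFERENCE_PRESSURE_MODELS["SPAP"], {"V_RPA": 1000.0})
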