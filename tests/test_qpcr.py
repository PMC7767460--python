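"""ΔΔCt arithmetic, signed convention, test-selection decision table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet import QpcrDataset, QpcrDesign, simulate_qpcr
from cernet.qpcr import (categorical_association, choose_test, correlate_dcts,
                         delta_ct, fold_change, fractionation_percent,
                         signed_fold_change, silencing_efficiency_filter)


def make_dataset(dcts_by_group, ct_ref=20.0, target="T"):
    """Dataset with one replicate per sample and exact ΔCt values."""
    rows = []
    for group, dcts in dcts_by_group.items():
        for i, d in enumerate(dcts):
            rows.append((f"{group}{i}", group, "0h", 0, target,
                         ct_ref + d, ct_ref))
    return QpcrDataset(pd.DataFrame(
        rows, columns=list(QpcrDataset.COLUMNS)))


def test_delta_ct_basics():
    ds = make_dataset({"tumor": [5.0], "normal": [0.0]})
    dct = delta_ct(ds)
    assert set(dct["dct"]) == {5.0, 0.0}


def test_delta_ct_replicates_averaged():
    rows = [("s1", "tumor", "0h", 0, "T", 25.1, 20.0),
            ("s1", "tumor", "0h", 1, "T", 24.9, 20.0)]
    ds = QpcrDataset(pd.DataFrame(rows, columns=list(QpcrDataset.COLUMNS)))
    assert delta_ct(ds)["dct"].iloc[0] == pytest.approx(5.0)


@pytest.mark.parametrize("ddct, expected, tol", [
    (-5.057, 33.3, 0.05),    # strong upregulation, printed to 0.1
    (0.411, -1.33, 0.005),   # downregulation, negative-reciprocal convention
    (0.0, 1.0, 1e-12),
])
def test_signed_convention_at_printed_precision(ddct, expected, tol):
    ds = make_dataset({"tumor": [3.0 + ddct] * 3, "normal": [3.0] * 3})
    fc = fold_change(ds, "tumor", "normal")
    assert fc.mean_ddct == pytest.approx(ddct, abs=1e-12)
    assert fc.fold_change_signed == pytest.approx(expected, abs=tol)
    assert abs(fc.fold_change_signed) >= 1


def test_fold_change_p_unavailable_below_two_samples():
    ds = make_dataset({"tumor": [4.0], "normal": [1.0, 1.2]})
    fc = fold_change(ds, "tumor", "normal")
    assert fc.p is None and fc.test_used is None
    assert fc.fold_change_raw == pytest.approx(2.0 ** -(4.0 - 1.1))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(0.01, 100))
def test_signed_convention_round_trip(raw):
    """The signed convention is invertible back to the raw ratio."""
    s = signed_fold_change(raw)
    assert abs(s) >= 1
    back = s if s >= 1 else -1.0 / s
    assert back == pytest.approx(raw, rel=1e-9)


def test_signed_antisymmetry_between_group_orders():
    """Swapping the groups inverts the raw ratio, which in signed space is
    a sign flip (for values away from +/-1)."""
    ds = make_dataset({"a": [5.0, 5.1, 4.9], "b": [3.0, 3.1, 2.9]})
    f_ab = fold_change(ds, "a", "b")
    f_ba = fold_change(ds, "b", "a")
    assert f_ab.fold_change_raw == pytest.approx(1.0 / f_ba.fold_change_raw)
    assert f_ab.fold_change_signed == pytest.approx(-f_ba.fold_change_signed)


# ---------------------------------------------------------------------------
# decision table
# ---------------------------------------------------------------------------

def test_student_branch_normal_equal_variance():
    rng = np.random.default_rng(0)
    d = choose_test(rng.normal(0, 1, 25), rng.normal(0.5, 1, 25))
    assert d.test_used == "student_t" and d.equal_variance


def test_welch_branch_normal_unequal_variance():
    rng = np.random.default_rng(2)
    d = choose_test(rng.normal(0, 1, 40), rng.normal(0, 6, 40))
    assert d.test_used == "welch_t" and d.equal_variance is False


def test_mann_whitney_branch_non_normal():
    rng = np.random.default_rng(3)
    d = choose_test(rng.lognormal(0, 1.5, 40), rng.normal(0, 1, 40))
    assert d.test_used == "mann_whitney"


def test_small_groups_fall_back_to_mann_whitney():
    d = choose_test([1.0, 2.0], [3.0, 4.0])
    assert d.test_used == "mann_whitney"


def test_identical_vectors_p_one_in_any_branch():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert choose_test(x, x.copy()).p == pytest.approx(1.0)
    const = np.full(5, 2.0)
    d = choose_test(const, const.copy())
    assert d.test_used == "mann_whitney" and d.p == 1.0


def test_majority_branch_selection_under_generating_conditions():
    """Student t wins for Gaussian equal-variance groups; Mann-Whitney wins
    for heavy-tailed groups (majority over 100 seeds each)."""
    student = mw = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        d = choose_test(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        student += d.test_used == "student_t"
        d2 = choose_test(rng.standard_cauchy(25), rng.standard_cauchy(25))
        mw += d2.test_used == "mann_whitney"
    assert student > 50
    assert mw > 50


def test_anova_branch_three_normal_groups():
    rng = np.random.default_rng(4)
    res = categorical_association({
        "a": rng.normal(0, 1, 15), "b": rng.normal(1, 1, 15),
        "c": rng.normal(2, 1, 15)})
    assert res.test_used == "anova"
    # matches a direct scipy evaluation on the same fixed vectors
    from scipy import stats
    rng = np.random.default_rng(4)
    arrays = [rng.normal(0, 1, 15), rng.normal(1, 1, 15), rng.normal(2, 1, 15)]
    assert res.p == pytest.approx(stats.f_oneway(*arrays).pvalue)


def test_kruskal_branch_non_normal_groups():
    rng = np.random.default_rng(5)
    res = categorical_association({
        "a": rng.lognormal(0, 1.5, 20), "b": rng.lognormal(0, 1.5, 20),
        "c": rng.lognormal(0.5, 1.5, 20)})
    assert res.test_used == "kruskal_wallis"


def test_singleton_group_dropped():
    rng = np.random.default_rng(6)
    res = categorical_association({
        "a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10), "c": [1.0]})
    assert res.groups_used == ("a", "b")


def test_two_identical_groups_p_near_one():
    res = categorical_association({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
    assert res.p == pytest.approx(1.0)


def test_planted_shift_detected_with_power():
    """A 2-ΔCt-unit shift at n=20/20 is detected at p<0.01 in >= 95% of
    seeds."""
    hits = 0
    for seed in range(60):
        rng = np.random.default_rng(seed)
        d = choose_test(rng.normal(0, 1, 20), rng.normal(2, 1, 20))
        hits += d.p < 0.01
    assert hits / 60 >= 0.95


# ---------------------------------------------------------------------------
# ΔCt correlations, fractionation, silencing filter
# ---------------------------------------------------------------------------

def test_correlate_dcts_identity_and_antisymmetry():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = correlate_dcts(a, a + np.array([0.01, -0.02, 0.0, 0.01, -0.01]))
    assert res.result.r == pytest.approx(1.0, abs=0.01)
    assert res.r_expression == res.result.r  # both inputs are ΔCts
    res2 = correlate_dcts(a, -a + 0.001 * np.array([1, -1, 2, 0, 1.0]))
    assert res2.result.r == pytest.approx(-1.0, abs=0.01)


def test_correlate_dcts_expression_sign_flip_for_covariate():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    cov = np.array([2.0, 4.0, 6.1, 7.9, 10.0])
    res = correlate_dcts(a, cov, b_is_dct=False)
    assert res.expression_sign_flipped
    assert res.r_expression == pytest.approx(-res.result.r)


def test_correlate_dcts_recovers_simulated_rho():
    """Bivariate normal rho=0.5, n=41: mean r over 200 seeds within 0.05."""
    rs = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=41)
        rs.append(correlate_dcts(z[:, 0], z[:, 1]).result.r)
    assert np.mean(rs) == pytest.approx(0.5, abs=0.05)


def test_fractionation_cases():
    r = fractionation_percent(20.0, 20.0)
    assert r.pct_nuclear == pytest.approx(50.0)
    r = fractionation_percent(21.0, 20.0)  # cytoplasm one cycle brighter
    assert r.pct_cytoplasmic == pytest.approx(100 * 2 / 3, abs=1e-9)
    r = fractionation_percent(30.0, 20.0)
    assert r.pct_cytoplasmic > 99.9
    with pytest.raises(ValueError):
        fractionation_percent(float("nan"), 20.0)


def test_silencing_filter_threshold_inclusive():
    res = silencing_efficiency_filter({"r1": 2.0 ** -2, "r2": 1.0, "r3": 0.3})
    assert set(res.kept) == {"r1"}        # efficiency exactly 0.75 kept
    assert res.kept["r1"] == pytest.approx(0.75)
    assert set(res.removed) == {"r2", "r3"}
    assert res.status == "ok"


def test_silencing_filter_all_removed():
    res = silencing_efficiency_filter({"r1": 0.9, "r2": 1.0})
    assert res.status == "all_removed" and not res.kept


def test_simulated_qpcr_log2_recovery_unbiased():
    """Estimated log2 fold change on noisy simulated plates is unbiased
    within Monte-Carlo error (300 seeds, noise 0.2 Ct, n=3)."""
    true_ratio = 4.0
    est = []
    for seed in range(300):
        ds = simulate_qpcr(QpcrDesign(n_per_group=3), {"T": true_ratio},
                           ct_noise_sd=0.2, seed=seed)
        est.append(np.log2(fold_change(ds, "tumor", "normal").fold_change_raw))
    est = np.asarray(est)
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - np.log2(true_ratio)) <= 3 * se
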