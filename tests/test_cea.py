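"""ICER dominance logic, NMB, bootstrap cloud/CEAC, Rubin pooling, group
tests, and the multiple-imputation engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadcea import (
    AnalysisConfig,
    bootstrap_cloud,
    compare_groups,
    icer,
    incremental,
    multiple_impute,
    nmb,
    pool,
)

FIN = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


# ---------------------------------------------------------------- ICER/NMB

@pytest.mark.parametrize("dc, de, kind", [
    (100.0, 0.01, "ratio"),      # NE: standard ratio
    (100.0, -0.01, "dominated"),  # NW
    (-100.0, 0.01, "dominant"),   # SE
    (-100.0, -0.01, "ratio"),     # SW: positive ratio, annotated
    (0.0, 0.01, "ratio"),         # boundary ΔC = 0
    (0.0, -0.01, "ratio"),        # boundary, SW side
    (100.0, 0.0, "undefined"),
    (0.0, 0.0, "undefined"),
    (-100.0, 0.0, "undefined"),
])
def test_dominance_sign_combinations(dc, de, kind):
    res = icer(dc, de)
    assert res.kind == kind
    if kind == "ratio":
        assert res.value >= 0 or de > 0
        assert (res.annotation == "southwest") == (de < 0)


def test_icer_display():
    assert icer(100.0, -0.01).display() == "Dominated"
    assert icer(-100.0, 0.01).display() == "Dominant"
    assert icer(100.0, 0.0).display() == "Undefined (ΔE = 0)"
    assert icer(-204.0, -0.022).display() == "9,273 (SW)"
    assert icer(468.0, 0.006).display() == "78,000"


def test_nmb_examples():
    assert nmb(468.0, 0.006, 48876.0) == pytest.approx(-174.744)
    assert round(nmb(9.0, -0.015, 48876.0)) == -742
    with pytest.raises(ValueError):
        nmb(0.0, 0.0, -1.0)


@given(FIN, st.floats(min_value=-10, max_value=10, allow_nan=False),
       st.floats(min_value=0, max_value=2e5))
def test_nmb_sign_consistent_with_icer(dc, de, wtp):
    """Positive NMB at λ ⇔ the pair is cost-effective at λ, whatever the
    dominance class says."""
    v = nmb(dc, de, wtp)
    if icer(dc, de).kind == "dominant":
        assert v >= 0 or wtp == 0 and dc == 0
    if icer(dc, de).kind == "dominated" and wtp >= 0:
        assert v < 0


# ---------------------------------------------------------------- bootstrap

def _frame(int_costs, int_effects, ctl_costs, ctl_effects):
    return pd.DataFrame({
        "arm": ["intervention"] * len(int_costs) + ["control"] * len(ctl_costs),
        "cost": list(int_costs) + list(ctl_costs),
        "effect": list(int_effects) + list(ctl_effects),
    })


def test_degenerate_cloud_single_unit_per_arm():
    """With one unit per arm every resample equals the point estimate."""
    fr = _frame([100.0], [1.2], [50.0], [1.0])
    cfg = AnalysisConfig(bootstrap_B=50, seed=0)
    cloud = bootstrap_cloud(fr, cfg)
    assert np.all(cloud.delta_costs == 50.0)
    assert np.allclose(cloud.delta_effects, 0.2)
    assert cloud.quadrant_counts["NE"] == 50


def test_quadrants_sum_to_B(small_trial, toy_tariff):
    from dyadcea import unit_frame

    fr = unit_frame(small_trial, "mci", "qaly", toy_tariff)
    cfg = AnalysisConfig(bootstrap_B=400, seed=5)
    cloud = bootstrap_cloud(fr, cfg)
    assert sum(cloud.quadrant_counts.values()) == cloud.B == 400


def test_ceac_at_zero_is_fraction_of_negative_cost_deltas():
    rng = np.random.default_rng(1)
    fr = _frame(rng.normal(100, 50, 30), rng.normal(1.1, 0.2, 30),
                rng.normal(90, 50, 30), rng.normal(1.0, 0.2, 30))
    cfg = AnalysisConfig(bootstrap_B=800, seed=2)
    cloud = bootstrap_cloud(fr, cfg)
    direct = float(np.mean(cloud.delta_costs < 0))  # strict: −ΔC* > 0
    assert cloud.ceac[0] == pytest.approx(direct)
    assert cloud.ceac[0] == pytest.approx(
        np.sum(cloud.delta_costs < 0) / cloud.B)


def test_ceac_monotone_for_positive_effect_cloud():
    fr = _frame([100.0, 120.0, 90.0], [1.2, 1.3, 1.25],
                [50.0, 60.0, 40.0], [1.0, 0.9, 1.1])
    cloud = bootstrap_cloud(fr, AnalysisConfig(bootstrap_B=300, seed=3))
    if np.all(cloud.delta_effects > 0):
        assert np.all(np.diff(cloud.ceac) >= 0)


def test_bootstrap_bit_reproducible():
    rng = np.random.default_rng(9)
    fr = _frame(rng.normal(100, 40, 25), rng.normal(1.1, 0.2, 25),
                rng.normal(80, 40, 25), rng.normal(1.0, 0.2, 25))
    cfg = AnalysisConfig(bootstrap_B=500, seed=42)
    a, b = bootstrap_cloud(fr, cfg), bootstrap_cloud(fr, cfg)
    np.testing.assert_array_equal(a.delta_costs, b.delta_costs)
    np.testing.assert_array_equal(a.delta_effects, b.delta_effects)
    np.testing.assert_array_equal(a.ceac, b.ceac)
    c = bootstrap_cloud(fr, cfg.model_copy(update={"seed": 43}))
    assert not np.array_equal(a.delta_costs, c.delta_costs)


def test_incremental_handles_missing_effects():
    fr = _frame([100.0, 200.0], [1.2, np.nan], [50.0, 70.0], [1.0, 1.1])
    res = incremental(fr, AnalysisConfig(bootstrap_B=200, seed=0))
    assert res.delta_cost == pytest.approx(150.0 - 60.0)
    assert res.delta_effect == pytest.approx(1.2 - 1.05)
    assert res.n_cost == (2, 2) and res.n_effect == (1, 2)
    assert res.ci_cost[0] <= res.delta_cost <= res.ci_cost[1]


def test_incremental_rejects_empty_arm():
    fr = _frame([100.0], [1.0], [], [])
    with pytest.raises(ValueError, match="empty arm"):
        incremental(fr, AnalysisConfig(bootstrap_B=10))


# ---------------------------------------------------------------- pooling

def _fake_result(dc, de, ci_c=None, ci_e=None):
    from dyadcea import ICERResult, IncrementalResult

    z = 1.959963984540054
    ci_c = ci_c or (dc - z * 10, dc + z * 10)     # within-SD 10
    ci_e = ci_e or (de - z * 0.01, de + z * 0.01)  # within-SD 0.01
    return IncrementalResult(dc, de, ci_c, ci_e, icer(dc, de),
                             nmb(dc, de, 48876.0))


def test_pool_worked_example():
    res = pool([_fake_result(468.0, 0.010), _fake_result(468.0, 0.012)], 48876.0)
    assert res.delta_effect == pytest.approx(0.011)
    assert res.delta_cost == pytest.approx(468.0)
    assert round(res.icer.value) == 42545  # 468 / 0.011
    # Rubin: W̄ + (1 + 1/m)·B with within-var 1e-4, between-var 2e-6 (m = 2)
    assert res.var_effect == pytest.approx(1e-4 + 1.5 * 2e-6)
    lo, hi = res.ci_effect
    assert lo < 0.011 < hi


def test_pool_identical_imputations_have_zero_between_variance():
    res = pool([_fake_result(100.0, 0.01)] * 3, 48876.0)
    assert res.var_effect == pytest.approx(1e-4)
    assert res.var_cost == pytest.approx(100.0)


def test_pool_rejects_mixed_effect_names():
    a = _fake_result(10.0, 0.01)
    b = _fake_result(10.0, 0.01)
    b.effect_name = "MMSE"
    with pytest.raises(ValueError, match="effect_name"):
        pool([a, b], 48876.0)
    with pytest.raises(ValueError, match="m ≥ 2"):
        pool([a], 48876.0)


# ---------------------------------------------------------------- tests

def test_compare_groups_continuous_matches_scipy():
    from scipy import stats

    a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 6.0]
    r = compare_groups(a, b)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    assert r.statistic == pytest.approx(t) and r.pvalue == pytest.approx(p)


def test_compare_groups_categorical_worked_example():
    a = ["m"] * 10 + ["f"] * 20
    b = ["m"] * 20 + ["f"] * 10
    r = compare_groups(a, b, kind="categorical")
    assert r.statistic == pytest.approx(20 / 3)  # chi² on [[10,20],[20,10]]


def test_compare_groups_zero_variance_flagged():
    r = compare_groups([1.0, 1.0], [1.0, 1.0])
    assert r.flag == "zero_variance" and r.pvalue == 1.0
    r2 = compare_groups([1.0, 1.0], [2.0, 2.0])
    assert r2.flag == "zero_variance" and r2.pvalue == 0.0


def test_compare_groups_paired():
    r = compare_groups([1.0, 2.0, 3.0], [1.1, 2.4, 2.9], kind="paired")
    from scipy import stats

    t, p = stats.ttest_rel([1.0, 2.0, 3.0], [1.1, 2.4, 2.9])
    assert r.statistic == pytest.approx(t) and r.pvalue == pytest.approx(p)


# ---------------------------------------------------------------- MI engine

def test_mi_no_missing_returns_copies():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0.1, 0.2, 0.3]})
    out = multiple_impute(df, ["y"], ["x"], m=3, seed=0)
    assert len(out) == 3
    for c in out:
        pd.testing.assert_frame_equal(c, df)


def test_mi_values_stay_on_observed_support():
    rng = np.random.default_rng(4)
    n = 120
    x = rng.normal(0, 1, n)
    y = np.round(1.0 + 0.5 * x + rng.normal(0, 0.3, n), 1)
    miss = rng.random(n) < 0.25
    df = pd.DataFrame({"y": np.where(miss, np.nan, y), "x": x})
    out = multiple_impute(df, ["y"], ["x"], m=2, seed=1, iterations=3)
    support = set(df["y"].dropna())
    for c in out:
        assert not c["y"].isna().any()
        assert set(c.loc[miss, "y"]).issubset(support)  # PMM property


def test_mi_recovers_mean_under_mcar():
    rng = np.random.default_rng(7)
    n = 400
    x = rng.normal(0, 1, n)
    y = 2.0 + 1.5 * x + rng.normal(0, 0.5, n)
    miss = rng.random(n) < 0.3  # MCAR
    df = pd.DataFrame({"y": np.where(miss, np.nan, y), "x": x})
    out = multiple_impute(df, ["y"], ["x"], m=10, seed=2, iterations=5)
    est = np.mean([c["y"].mean() for c in out])
    assert est == pytest.approx(y.mean(), abs=0.1)


def test_mi_reproducible_and_errors():
    df = pd.DataFrame({"y": [1.0, np.nan, 3.0, 2.0], "x": [1, 2, 3, 4.0]})
    a = multiple_impute(df, ["y"], ["x"], m=2, seed=5)
    b = multiple_impute(df, ["y"], ["x"], m=2, seed=5)
    for ca, cb in zip(a, b):
        pd.testing.assert_frame_equal(ca, cb)
    with pytest.raises(ValueError, match="entirely missing"):
        multiple_impute(df.assign(x=np.nan), ["y"], ["x"], m=2, seed=0)
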