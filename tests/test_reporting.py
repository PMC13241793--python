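"""End-to-end analysis populations, sensitivity grid, report invariants,
scenario pooling, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from dyadcea import (
    AnalysisConfig,
    SubgroupSpec,
    builtin_tariff,
    default_sensitivity_specs,
    incremental,
    run_base_case,
    run_scenario,
    run_sensitivity_suite,
    unit_frame,
)
from dyadcea.cli import cli_main

CFG = AnalysisConfig(bootstrap_B=200, seed=0)
K = (360 + 180 / 1.03) / 365.25


# ---------------------------------------------------------------- hand oracle

def test_hand_trial_mci_arithmetic(hand_trial, toy_tariff):
    fr = unit_frame(hand_trial, "mci", "qaly", toy_tariff)
    res = incremental(fr, CFG)
    assert res.delta_cost == pytest.approx(250.0)
    assert res.delta_effect == pytest.approx(0.05 * K)
    assert res.icer.kind == "ratio"
    assert res.icer.value == pytest.approx(250.0 / (0.05 * K))
    assert res.nmb == pytest.approx(0.05 * K * 48876.0 - 250.0)
    assert res.n_cost == (2, 2) and res.n_effect == (2, 2)


def test_hand_trial_caregiver_and_dyad(hand_trial, toy_tariff):
    cg = incremental(unit_frame(hand_trial, "caregiver", "qaly", toy_tariff), CFG)
    assert cg.delta_cost == pytest.approx(0.0)
    assert cg.delta_effect == pytest.approx(0.15 * K)
    dy = incremental(unit_frame(hand_trial, "dyad", "qaly", toy_tariff), CFG)
    assert dy.delta_cost == pytest.approx(250.0)
    assert dy.delta_effect == pytest.approx(0.20 * K)


def test_hand_trial_secondary_outcomes(hand_trial, toy_tariff):
    qolad = incremental(unit_frame(hand_trial, "mci", "qolad", toy_tariff), CFG)
    assert qolad.delta_effect == pytest.approx(2.5)  # composite change, by hand
    mmse = incremental(unit_frame(hand_trial, "mci", "mmse", toy_tariff), CFG)
    assert mmse.delta_effect == pytest.approx(2.0)
    zbi = incremental(unit_frame(hand_trial, "caregiver", "zbi", toy_tariff), CFG)
    assert zbi.delta_effect == pytest.approx(2.5)  # inverted-scale change


def test_intervention_cost_shifts_delta_cost_exactly(hand_trial, toy_tariff):
    from dyadcea import InterventionCostSpec

    base = incremental(unit_frame(hand_trial, "mci", "qaly", toy_tariff), CFG)
    plus = incremental(
        unit_frame(hand_trial, "mci", "qaly", toy_tariff,
                   intervention=InterventionCostSpec()), CFG)
    assert plus.delta_cost - base.delta_cost == pytest.approx(173.0)
    assert plus.delta_effect == pytest.approx(base.delta_effect)


def test_base_case_report(hand_trial, toy_tariff):
    rep = run_base_case(hand_trial, "mci", CFG, tariff=toy_tariff)
    rows = rep.rows
    assert list(rows["effect_name"]) == ["QALY", "QoL-AD", "MMSE"]
    rep.validate()
    md = rep.to_markdown()
    assert "QALY" in md and "base_case" in md


def test_base_case_rejects_unknown_population(hand_trial):
    with pytest.raises(ValueError, match="population"):
        run_base_case(hand_trial, "clinicians", CFG)


# ---------------------------------------------------------------- subgroups

def test_partitioning_splits_preserve_sample_sizes(small_trial, toy_tariff):
    """Sex/age subgroup cost-sample sizes sum to the base case."""
    specs = [s for s in default_sensitivity_specs("mci")
             if s.name in ("base_case", "men_only", "women_only",
                           "age_le_70", "age_gt_70")]
    rep = run_sensitivity_suite(small_trial, specs, CFG, tariff=toy_tariff)
    rows = rep.rows.set_index("scenario")
    for col in ("n_cost_intervention", "n_cost_control"):
        base = rows.loc["base_case", col]
        assert rows.loc["men_only", col] + rows.loc["women_only", col] == base
        assert rows.loc["age_le_70", col] + rows.loc["age_gt_70", col] == base
    rep.validate()


def test_app_use_split_keeps_full_control_arm(small_trial, toy_tariff):
    specs = [s for s in default_sensitivity_specs("mci")
             if s.name in ("base_case", "high_app_use", "low_app_use")]
    rep = run_sensitivity_suite(small_trial, specs, CFG, tariff=toy_tariff)
    rows = rep.rows.set_index("scenario")
    base_ctl = rows.loc["base_case", "n_cost_control"]
    assert rows.loc["high_app_use", "n_cost_control"] == base_ctl
    assert rows.loc["low_app_use", "n_cost_control"] == base_ctl
    assert (rows.loc["high_app_use", "n_cost_intervention"]
            + rows.loc["low_app_use", "n_cost_intervention"]
            == rows.loc["base_case", "n_cost_intervention"])


def test_drop_zero_cost_noop_when_no_zeros(hand_trial, toy_tariff):
    spec = SubgroupSpec("remove_zero_cost", "mci", drop_zero_cost=True)
    rep = run_sensitivity_suite(hand_trial, [spec, SubgroupSpec("base_case", "mci")],
                                CFG, tariff=toy_tariff)
    rows = rep.rows.set_index("scenario")
    assert rows.loc["remove_zero_cost", "delta_cost"] == pytest.approx(
        rows.loc["base_case", "delta_cost"])


def test_empty_filter_yields_flagged_row(hand_trial, toy_tariff):
    spec = SubgroupSpec("nobody", "mci", filter=lambda f: f["age"] > 200)
    rep = run_sensitivity_suite(hand_trial, [spec], CFG, tariff=toy_tariff)
    row = rep.rows.iloc[0]
    assert row["icer_kind"] == "empty" and "n/a" in row["icer"]


def test_imputed_scenario_pools(small_trial, toy_tariff):
    spec = SubgroupSpec("imputed_qalys", "caregiver", impute_qalys=True)
    cfg = AnalysisConfig(bootstrap_B=100, seed=0)
    rep = run_sensitivity_suite(small_trial, [spec], cfg, tariff=toy_tariff,
                                mi_m=3)
    row = rep.rows.iloc[0]
    assert row["icer_kind"] in ("ratio", "dominated", "dominant", "undefined")
    assert np.isfinite(row["delta_effect"])
    assert row["ci_effect_low"] < row["delta_effect"] < row["ci_effect_high"]


def test_suite_bit_reproducible(small_trial, toy_tariff):
    specs = default_sensitivity_specs("mci")
    a = run_sensitivity_suite(small_trial, specs, CFG, tariff=toy_tariff, mi_m=2)
    b = run_sensitivity_suite(small_trial, specs, CFG, tariff=toy_tariff, mi_m=2)
    pd.testing.assert_frame_equal(a.rows, b.rows)


# ---------------------------------------------------------------- scenarios

def test_scenario_substitutes_tariff_and_threshold(small_trial):
    rep = run_scenario(small_trial, builtin_tariff("eu_vas"), 30000.0,
                       AnalysisConfig(bootstrap_B=100, seed=0))
    row = rep.rows.iloc[0]
    assert np.isfinite(row["delta_effect"])
    # NMB recomputable at the substituted threshold
    expected = round(row["delta_effect"] * 30000.0 - row["delta_cost"])
    assert row["nmb"] == expected


def test_scenario_pooling_concatenates_sites(small_trial, toy_tariff):
    from dyadcea import SimulationConfig, generate_trial

    other = generate_trial(
        SimulationConfig(n_dyads_per_arm=30, seed=21, tariff_name="toy_linear"))
    rep = run_scenario(small_trial, toy_tariff, 30000.0,
                       AnalysisConfig(bootstrap_B=100, seed=0),
                       pooled_with=other)
    row = rep.rows.set_index("effect_name").loc["QALY"]
    solo = run_base_case(small_trial, "mci",
                         AnalysisConfig(bootstrap_B=100, seed=0),
                         tariff=toy_tariff).rows.set_index("effect_name").loc["QALY"]
    assert (row["n_cost_intervention"] + row["n_cost_control"]
            > solo["n_cost_intervention"] + solo["n_cost_control"])


# ---------------------------------------------------------------- CLI

def test_cli_end_to_end(tmp_path):
    data = tmp_path / "trial"
    rc = cli_main(["simulate", "--out", str(data), "--seed", "3",
                   "--dyads", "25"])
    assert rc == 0
    assert (data / "visits.csv").exists()

    rc = cli_main(["qaly", str(data), "--tariff", "toy_linear"])
    assert rc == 0
    q = pd.read_csv(data / "qaly.csv")
    assert {"participant_id", "total", "complete"} <= set(q.columns)

    rc = cli_main(["costs", str(data)])
    assert rc == 0

    out = tmp_path / "analysis"
    rc = cli_main(["analyze", str(data), "--tariff", "toy_linear",
                   "--bootstrap-b", "200", "--seed", "1", "--out", str(out)])
    assert rc == 0
    inc = json.loads((out / "incremental.json").read_text())
    assert inc["bootstrap_B"] == 200 and inc["seed"] == 1
    plane = pd.read_csv(out / "ce_plane.csv")
    assert len(plane) == 200

    rc = cli_main(["report", str(out)])
    assert rc == 0
    assert "Cost-effectiveness report" in (out / "report.md").read_text()


def test_cli_deterministic(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    for d in (a, b):
        assert cli_main(["simulate", "--out", str(d), "--seed", "5",
                         "--dyads", "10"]) == 0
    assert (a / "visits.csv").read_text() == (b / "visits.csv").read_text()
    assert (a / "costs.csv").read_text() == (b / "costs.csv").read_text()


def test_cli_report_requires_analyze_outputs(tmp_path):
    assert cli_main(["report", str(tmp_path)]) == 2


def test_cli_rejects_bad_config(tmp_path):
    cfgfile = tmp_path / "cfg.yaml"
    cfgfile.write_text("cost_zero_prob: 2.0\n")
    rc = cli_main(["simulate", "--out", str(tmp_path / "x"), "--seed", "0",
                   "--config", str(cfgfile)])
    assert rc == 2
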