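"""Shared fixtures: the exact toy tariff, a hand-built 4-dyad trial whose
every quantity is computable by hand, and a small generated trial."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dyadcea import SimulationConfig, TrialDataset, builtin_tariff, generate_trial

# discounted-interval weight used in hand oracles: QALY total for a constant
# utility u observed at days 0/180/360/540 equals u * K
K = (180.0 + 180.0 + 180.0 / 1.03) / 365.25


@pytest.fixture(scope="session")
def toy_tariff():
    """utility = 1 − 0.1·Σ(level−1), exact by construction."""
    return builtin_tariff("toy_linear")


def _visit_rows(pid, dyad, role, arm, states, *, mmse=None, qself=None,
                qproxy=None, zbi=None, days=(0, 180, 360, 540)):
    rows = []
    for k, day in enumerate(days):
        rows.append({
            "participant_id": pid, "dyad_id": dyad, "role": role, "arm": arm,
            "visit_index": k, "actual_day": day,
            "eq5d_state": states[k],
            "mmse": mmse[k] if mmse else np.nan,
            "qolad_self": qself[k] if qself else np.nan,
            "qolad_proxy": qproxy[k] if qproxy else np.nan,
            "zbi_raw": zbi[k] if zbi else np.nan,
            "deceased": False, "death_day": np.nan,
        })
    return rows


@pytest.fixture(scope="session")
def hand_trial():
    """Four complete dyads (two per arm) with constant utilities under the
    toy tariff and one observed outpatient episode per person with MCI.

    Hand-computable facts (toy tariff; 3% single-factor discount):
      utilities    A1_m 0.9, A2_m 0.8, B1_m 0.7, B2_m 0.9
                   A1_c 1.0, A2_c 0.9, B1_c 0.8, B2_c 0.8
      QALY totals  u * K with K = (360 + 180/1.03)/365.25
      MCI  ΔE = (0.85 − 0.80)·K = 0.05·K;  ΔC = 750 − 500 = 250
      CG   ΔE = (0.95 − 0.80)·K = 0.15·K;  ΔC = 0
      dyad ΔE = (1.80 − 1.60)·K = 0.20·K;  ΔC = 250
    Costs fall on day 100 (undiscounted interval).
    """
    # constant utility ↔ constant state under toy tariff:
    # 0.9→11112 (Σproblems 1), 0.8→11122, 0.7→11222, 1.0→11111
    st = {1.0: 11111, 0.9: 11112, 0.8: 11122, 0.7: 11222}
    rows = []
    rows += _visit_rows("A1_m", "A1", "person_with_mci", "intervention",
                        [st[0.9]] * 4, mmse=[26, 26, 27, 28],
                        qself=[40, 40, 40, 42], qproxy=[28, 28, 28, 30])
    rows += _visit_rows("A2_m", "A2", "person_with_mci", "intervention",
                        [st[0.8]] * 4, mmse=[24, 24, 24, 24],
                        qself=[34, 34, 34, 34], qproxy=[31, 31, 31, 31])
    rows += _visit_rows("B1_m", "B1", "person_with_mci", "control",
                        [st[0.7]] * 4, mmse=[25, 25, 24, 23],
                        qself=[36, 36, 35, 33], qproxy=[30, 30, 29, 27])
    rows += _visit_rows("B2_m", "B2", "person_with_mci", "control",
                        [st[0.9]] * 4, mmse=[27, 27, 27, 27],
                        qself=[38, 38, 38, 38], qproxy=[32, 32, 32, 32])
    rows += _visit_rows("A1_c", "A1", "caregiver", "intervention",
                        [st[1.0]] * 4, zbi=[8, 8, 7, 6])
    rows += _visit_rows("A2_c", "A2", "caregiver", "intervention",
                        [st[0.9]] * 4, zbi=[17, 17, 17, 17])
    rows += _visit_rows("B1_c", "B1", "caregiver", "control",
                        [st[0.8]] * 4, zbi=[12, 12, 13, 15])
    rows += _visit_rows("B2_c", "B2", "caregiver", "control",
                        [st[0.8]] * 4, zbi=[10, 10, 10, 10])
    visits = pd.DataFrame(rows)
    visits["eq5d_state"] = visits["eq5d_state"].astype("Int64")

    eps = pd.DataFrame({
        "participant_id": ["A1_m", "A2_m", "B1_m", "B2_m"],
        "day": [100, 100, 100, 100],
        "setting": ["outpatient"] * 4,
        "clinic_type": ["primary_care"] * 4,
        "personnel_type": ["physician"] * 4,
        "cost": [1000.0, 500.0, 600.0, 400.0],
        "length_of_stay_days": [np.nan] * 4,
    })
    participants = pd.DataFrame({
        "participant_id": ["A1_m", "A2_m", "B1_m", "B2_m",
                           "A1_c", "A2_c", "B1_c", "B2_c"],
        "dyad_id": ["A1", "A2", "B1", "B2"] * 2,
        "role": ["person_with_mci"] * 4 + ["caregiver"] * 4,
        "arm": ["intervention", "intervention", "control", "control"] * 2,
        "age": [72, 68, 75, 71, 70, 66, 73, 69],
        "sex": ["male", "female", "male", "female"] * 2,
        "education": ["secondary"] * 8,
        "living_arrangement": ["with_partner"] * 8,
        "app_launches": [200.0, 50.0, np.nan, np.nan] * 2,
        "dropout_visit": [np.nan] * 8,
        "death_day": [np.nan] * 8,
    })
    arms = {"A1": "intervention", "A2": "intervention",
            "B1": "control", "B2": "control"}
    return TrialDataset(visits, eps, participants, arms)


@pytest.fixture(scope="session")
def small_trial():
    """A seeded generated trial, 40 dyads/arm, toy tariff, reused across
    tests (read-only)."""
    cfg = SimulationConfig(n_dyads_per_arm=40, seed=11, tariff_name="toy_linear")
    return generate_trial(cfg)
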