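"""End-to-end base-case, sensitivity, subgroup and scenario analyses.

Drives the full pipeline — cost imputation and aggregation, QALY
estimation, incremental analysis with bootstrap uncertainty, multiple
imputation — for the three analysis populations (people with MCI,
caregivers, dyads) and renders table-style reports.

Analysis populations and rules:

* effects are complete-case per outcome, so sample sizes legitimately
  differ across outcomes within one population;
* cost totals enter only for participants with register coverage over
  the whole window (dyad attended the final visit, or the participant
  died during the trial);
* dyad outcomes sum the two members' scores and require both complete;
* app-usage subgroups split only the intervention arm (the control arm
  has no usage) and compare each stratum against the full control arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cea import (
    AnalysisConfig,
    IncrementalResult,
    PooledResult,
    incremental,
    pool,
)
from .costing import InterventionCostSpec, aggregate_costs, impute_costs
from .discounting import DiscountSpec
from .impute import multiple_impute
from .qaly import dyad_qaly_table, qaly_table
from .synthetic import ROLE_CAREGIVER, ROLE_MCI, TrialDataset
from .valuation import TariffModel, builtin_tariff, composite_qolad, invert_zbi

__all__ = [
    "SubgroupSpec",
    "AnalysisReport",
    "run_base_case",
    "run_sensitivity_suite",
    "run_scenario",
    "default_sensitivity_specs",
    "unit_frame",
]

POPULATIONS = ("mci", "caregiver", "dyad")
EFFECTS = {
    "mci": ["qaly", "qolad", "mmse"],
    "caregiver": ["qaly", "zbi"],
    "dyad": ["qaly"],
}
EFFECT_LABELS = {
    "qaly": "QALY",
    "qolad": "QoL-AD",
    "mmse": "MMSE",
    "zbi": "ZBI-12",
}


@dataclass
class SubgroupSpec:
    """One sensitivity/subgroup scenario.

    ``filter`` is a predicate over the enriched unit frame (baseline
    fields such as ``age``, ``sex``, ``baseline_mmse``,
    ``baseline_zbi_inverted``, ``app_launches`` are available).
    """

    name: str
    population: str
    filter: Callable[[pd.DataFrame], pd.Series] | None = None
    filter_intervention_only: bool = False
    impute_qalys: bool = False
    include_intervention_cost: bool = False
    drop_zero_cost: bool = False

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")


# ----------------------------------------------------------------------
# Unit frames
# ----------------------------------------------------------------------

def _baseline_scores(dataset: TrialDataset, tariff: TariffModel) -> pd.DataFrame:
    base = dataset.visits[dataset.visits["visit_index"] == 0].copy()
    base["baseline_utility"] = tariff.value_digits(base["eq5d_state"])
    base["baseline_zbi_inverted"] = invert_zbi(base["zbi_raw"])
    out = base[
        ["participant_id", "baseline_utility", "mmse", "zbi_raw",
         "baseline_zbi_inverted", "qolad_self", "qolad_proxy"]
    ].rename(columns={"mmse": "baseline_mmse", "zbi_raw": "baseline_zbi_raw",
                      "qolad_self": "baseline_qolad_self",
                      "qolad_proxy": "baseline_qolad_proxy"})
    with np.errstate(invalid="ignore"):
        out["baseline_qolad_composite"] = composite_qolad(
            out["baseline_qolad_self"], out["baseline_qolad_proxy"]
        )
    return out


def _change_scores(dataset: TrialDataset) -> pd.DataFrame:
    """Baseline→18-month change per participant for QoL-AD composite,
    MMSE, and inverted ZBI (complete pairs only)."""
    v = dataset.visits
    last = int(v["visit_index"].max())

    def wide(col):
        return v.pivot(index="participant_id", columns="visit_index", values=col)

    qs, qp, mm, zb = (wide(c) for c in
                      ("qolad_self", "qolad_proxy", "mmse", "zbi_raw"))
    for w in (qs, qp, mm, zb):
        for k in (0, last):
            if k not in w.columns:
                w[k] = np.nan
    with np.errstate(invalid="ignore"):
        comp0 = composite_qolad(qs[0], qp[0])
        comp1 = composite_qolad(qs[last], qp[last])
    out = pd.DataFrame(index=qs.index)
    out["qolad_change"] = comp1 - comp0
    out["mmse_change"] = mm[last] - mm[0]
    # inverted-ZBI change: (48−raw_end) − (48−raw_0) = raw_0 − raw_end
    out["zbi_inverted_change"] = zb[0] - zb[last]
    return out.reset_index()


def _cost_complete(dataset: TrialDataset) -> pd.Series:
    """Register coverage over the whole window: dyad attended the final
    visit, or the participant died during the trial."""
    n_visits = int(dataset.visits["visit_index"].max()) + 1
    last = dataset.visits.groupby("dyad_id")["visit_index"].max()
    complete_dyads = set(last[last == n_visits - 1].index)
    parts = dataset.participants
    ok = parts["dyad_id"].isin(complete_dyads)
    if "death_day" in parts.columns:
        ok |= parts["death_day"].notna()
    return pd.Series(ok.to_numpy(), index=parts["participant_id"].to_numpy())


def unit_frame(
    dataset: TrialDataset,
    population: str,
    effect: str,
    tariff: TariffModel,
    discount: DiscountSpec | None = None,
    intervention: InterventionCostSpec | None = None,
) -> pd.DataFrame:
    """One row per resampling unit: ``arm``, ``cost``, ``effect``, plus
    the baseline fields subgroup filters may reference."""
    discount = discount or DiscountSpec()
    parts = dataset.participants
    episodes = impute_costs(dataset.cost_episodes)
    costs = aggregate_costs(episodes, parts, discount=discount,
                            intervention=intervention)
    covered = _cost_complete(dataset)
    costs = costs.set_index("participant_id")
    cost_total = costs["grand_total"].where(
        covered.reindex(costs.index).fillna(False)
    )

    qtab = qaly_table(dataset.visits, tariff, discount).set_index("participant_id")
    changes = _change_scores(dataset).set_index("participant_id")
    base = _baseline_scores(dataset, tariff).set_index("participant_id")

    if population == "dyad":
        if effect != "qaly":
            raise ValueError("dyad analyses support only the QALY outcome")
        dq = dyad_qaly_table(qtab.reset_index(), parts).set_index("dyad_id")
        per_d = parts.drop_duplicates("dyad_id").set_index("dyad_id")
        both_covered = covered.groupby(parts.set_index("participant_id")["dyad_id"]
                                       .reindex(covered.index)).all()
        dyad_cost = costs["grand_total"].groupby(
            parts.set_index("participant_id")["dyad_id"].reindex(costs.index)
        ).sum()
        frame = pd.DataFrame(
            {
                "unit_id": per_d.index,
                "arm": per_d["arm"],
                "cost": dyad_cost.where(both_covered).reindex(per_d.index),
                "effect": dq["total"].reindex(per_d.index),
                "app_launches": per_d["app_launches"],
            }
        ).reset_index(drop=True)
        return frame

    role = ROLE_MCI if population == "mci" else ROLE_CAREGIVER
    sub = parts[parts["role"] == role].set_index("participant_id")
    eff = {
        "qaly": qtab["total"],
        "qolad": changes["qolad_change"],
        "mmse": changes["mmse_change"],
        "zbi": changes["zbi_inverted_change"],
    }[effect]
    frame = pd.DataFrame(
        {
            "unit_id": sub.index,
            "arm": sub["arm"],
            "cost": cost_total.reindex(sub.index),
            "effect": eff.reindex(sub.index),
            "age": sub["age"],
            "sex": sub["sex"],
            "app_launches": sub["app_launches"],
        }
    )
    frame = frame.join(base[["baseline_utility", "baseline_mmse",
                             "baseline_zbi_inverted"]], how="left")
    return frame.reset_index(drop=True)


def _apply_spec_filters(frame: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    out = frame
    if spec.filter is not None:
        mask = spec.filter(out).fillna(False).astype(bool)
        if spec.filter_intervention_only:
            mask = mask | (out["arm"] == "control")
        out = out[mask]
        if len(out) == 0 or out["arm"].nunique() < 2:
            return out.iloc[0:0]
    if spec.drop_zero_cost:
        out = out[~(out["cost"] == 0)]
    return out


# ----------------------------------------------------------------------
# Multiple imputation of QALYs
# ----------------------------------------------------------------------

MI_PREDICTORS = ["age", "sex", "education", "living_arrangement", "arm",
                 "baseline_mmse", "baseline_zbi_raw", "baseline_qolad_composite",
                 "partner_baseline_utility"]


def _mi_wide_table(dataset: TrialDataset, tariff: TariffModel) -> pd.DataFrame:
    """Per-participant wide table of utilities u0..u3 and visit days,
    joined with the baseline imputation predictors."""
    v = dataset.visits.copy()
    v["utility"] = tariff.value_digits(v["eq5d_state"])
    wu = v.pivot(index="participant_id", columns="visit_index", values="utility")
    wd = v.pivot(index="participant_id", columns="visit_index", values="actual_day")
    nominal = (0, 180, 360, 540)
    parts = dataset.participants.set_index("participant_id")
    wide = pd.DataFrame(index=parts.index)
    for k in range(4):
        wide[f"u{k}"] = wu[k].reindex(wide.index) if k in wu.columns else np.nan
        dk = wd[k].reindex(wide.index) if k in wd.columns else pd.Series(np.nan, wide.index)
        wide[f"d{k}"] = dk.fillna(float(nominal[k]))
    base = _baseline_scores(dataset, tariff).set_index("participant_id")
    # dyad-level baseline instruments broadcast to both members
    dyad_of = parts["dyad_id"]
    for col in ("baseline_mmse", "baseline_zbi_raw", "baseline_qolad_composite"):
        dyad_val = base[col].groupby(dyad_of.reindex(base.index)).mean()
        wide[col] = dyad_of.map(dyad_val)
    partner_u = base["baseline_utility"].groupby(
        dyad_of.reindex(base.index)).transform(
        lambda s: s.iloc[::-1].to_numpy())
    wide["partner_baseline_utility"] = partner_u.reindex(wide.index)
    for c in ("age", "sex", "education", "living_arrangement", "arm", "role",
              "dyad_id"):
        wide[c] = parts[c]
    return wide.reset_index()


def _mi_qaly_totals(completed: pd.DataFrame, discount: DiscountSpec) -> pd.Series:
    """Trapezoid totals from an imputed wide table (third interval
    discounted)."""
    t = completed
    from .discounting import YEAR_DAYS

    total = np.zeros(len(t))
    for k in range(3):
        u0, u1 = t[f"u{k}"].to_numpy(float), t[f"u{k+1}"].to_numpy(float)
        d0, d1 = t[f"d{k}"].to_numpy(float), t[f"d{k+1}"].to_numpy(float)
        total += (u0 + u1) / 2 * (d1 - d0) / YEAR_DAYS * discount.factor(k)
    return pd.Series(total, index=t["participant_id"].to_numpy())


def _run_imputed(
    dataset: TrialDataset,
    spec: SubgroupSpec,
    base_frame: pd.DataFrame,
    config: AnalysisConfig,
    tariff: TariffModel,
    discount: DiscountSpec,
    m: int = 20,
) -> PooledResult:
    """Pooled incremental result with MI-completed QALYs (costs stay
    complete-case, as in the trial's sensitivity analysis)."""
    wide = _mi_wide_table(dataset, tariff)
    impute_cols = [c for c in ("u0", "u1", "u2", "u3") if wide[c].isna().any()]
    completed = multiple_impute(
        wide, impute_cols, MI_PREDICTORS, m=m,
        seed=np.random.default_rng(config.seed + 1),
    )
    results = []
    cost_by_unit = base_frame.set_index("unit_id")["cost"]
    parts = dataset.participants.set_index("participant_id")
    for i, comp in enumerate(completed):
        totals = _mi_qaly_totals(comp, discount)
        if spec.population == "dyad":
            eff = totals.groupby(parts["dyad_id"].reindex(totals.index)).sum()
            units = parts.drop_duplicates("dyad_id").reset_index().set_index("dyad_id")
            fr = pd.DataFrame({
                "arm": units["arm"],
                "cost": cost_by_unit.reindex(units.index),
                "effect": eff.reindex(units.index),
            }).reset_index(drop=True)
        else:
            role = ROLE_MCI if spec.population == "mci" else ROLE_CAREGIVER
            sel = parts[parts["role"] == role].index
            fr = pd.DataFrame({
                "arm": parts.loc[sel, "arm"].to_numpy(),
                "cost": cost_by_unit.reindex(sel).to_numpy(),
                "effect": totals.reindex(sel).to_numpy(),
            })
        cfg_i = config.model_copy(update={"seed": config.seed + 100 + i})
        results.append(incremental(fr, cfg_i, effect_name="QALY"))
    return pool(results, config.wtp_threshold)


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------

REPORT_COLUMNS = [
    "scenario", "population", "effect_name",
    "n_cost_intervention", "n_cost_control",
    "n_effect_intervention", "n_effect_control",
    "delta_cost", "ci_cost_low", "ci_cost_high",
    "delta_effect", "ci_effect_low", "ci_effect_high",
    "icer", "icer_kind", "icer_value", "nmb",
]


class AnalysisReport:
    """Rows of incremental results mirroring a trial CEA results table."""

    def __init__(self, rows: pd.DataFrame | None = None) -> None:
        self._rows: list[dict] = (
            [] if rows is None else rows.to_dict("records")
        )

    @property
    def rows(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=REPORT_COLUMNS)

    @rows.setter
    def rows(self, df: pd.DataFrame) -> None:
        self._rows = df.to_dict("records")

    def add(self, scenario: str, population: str, res: IncrementalResult | PooledResult,
            effect_name: str, rounded: bool = True) -> None:
        if isinstance(res, PooledResult):
            n_cost = n_eff = (np.nan, np.nan)
            ci_c, ci_e = res.ci_cost, res.ci_effect
        else:
            n_cost, n_eff = res.n_cost, res.n_effect
            ci_c, ci_e = res.ci_cost, res.ci_effect
        row = {
            "scenario": scenario,
            "population": population,
            "effect_name": effect_name,
            "n_cost_intervention": n_cost[0],
            "n_cost_control": n_cost[1],
            "n_effect_intervention": n_eff[0],
            "n_effect_control": n_eff[1],
            "delta_cost": res.delta_cost,
            "ci_cost_low": ci_c[0],
            "ci_cost_high": ci_c[1],
            "delta_effect": res.delta_effect,
            "ci_effect_low": ci_e[0],
            "ci_effect_high": ci_e[1],
            "icer": res.icer.display(rounded),
            "icer_kind": res.icer.kind,
            "icer_value": res.icer.value,
            "nmb": round(res.nmb) if rounded else res.nmb,
        }
        self._rows.append(row)

    def add_empty(self, scenario: str, population: str, effect_name: str,
                  reason: str) -> None:
        row = dict.fromkeys(REPORT_COLUMNS, np.nan)
        row.update(scenario=scenario, population=population,
                   effect_name=effect_name, icer=f"n/a ({reason})",
                   icer_kind="empty")
        self._rows.append(row)

    def validate(self, tol: float = 1.0) -> None:
        """Every row's label/ratio must be consistent with its own ΔC/ΔE."""
        for _, r in self.rows.iterrows():
            if r["icer_kind"] == "empty":
                continue
            dc, de = r["delta_cost"], r["delta_effect"]
            if r["icer_kind"] == "dominated":
                assert dc > 0 and de < 0, f"{r['scenario']}: dominated label inconsistent"
            elif r["icer_kind"] == "dominant":
                assert dc < 0 and de > 0, f"{r['scenario']}: dominant label inconsistent"
            elif r["icer_kind"] == "ratio":
                assert abs(abs(dc / de) - abs(r["icer_value"])) <= tol

    def to_markdown(self) -> str:
        cols = ["scenario", "population", "effect_name", "delta_cost",
                "delta_effect", "icer", "nmb"]
        df = self.rows[cols].copy()
        return df.to_markdown(index=False, floatfmt=".3f")


def run_base_case(
    dataset: TrialDataset,
    population: str,
    config: AnalysisConfig | None = None,
    tariff: TariffModel | None = None,
    discount: DiscountSpec | None = None,
) -> AnalysisReport:
    """Base-case rows for one population: a QALY row with NMB plus the
    population's secondary outcomes, each complete-case."""
    config = config or AnalysisConfig()
    tariff = tariff or builtin_tariff("toy_linear")
    discount = discount or DiscountSpec(annual_rate=config.discount_rate)
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    report = AnalysisReport()
    for effect in EFFECTS[population]:
        frame = unit_frame(dataset, population, effect, tariff, discount)
        label = EFFECT_LABELS[effect]
        try:
            res = incremental(frame, config, effect_name=label)
        except ValueError as err:
            report.add_empty("base_case", population, label, str(err))
            continue
        report.add("base_case", population, res, label,
                   rounded=config.round_reported)
    return report


def default_sensitivity_specs(population: str) -> list[SubgroupSpec]:
    """The trial's sensitivity/subgroup grid for one population."""
    P = population
    specs = [SubgroupSpec("base_case", P)]
    specs.append(SubgroupSpec("imputed_qalys", P, impute_qalys=True))
    if P in ("mci", "dyad"):
        specs.append(SubgroupSpec("with_intervention_cost", P,
                                  include_intervention_cost=True))
    specs.append(SubgroupSpec("remove_zero_cost", P, drop_zero_cost=True))
    if P in ("mci", "caregiver"):
        specs += [
            SubgroupSpec("men_only", P, filter=lambda f: f["sex"] == "male"),
            SubgroupSpec("women_only", P, filter=lambda f: f["sex"] == "female"),
            SubgroupSpec("age_le_70", P, filter=lambda f: f["age"] <= 70),
            SubgroupSpec("age_gt_70", P, filter=lambda f: f["age"] > 70),
        ]
    if P == "mci":
        specs += [
            SubgroupSpec("mmse_le_26", P,
                         filter=lambda f: f["baseline_mmse"] <= 26),
            SubgroupSpec("mmse_gt_26", P,
                         filter=lambda f: f["baseline_mmse"] > 26),
        ]
    if P == "caregiver":
        specs += [
            SubgroupSpec("zbi_no_burden", P,
                         filter=lambda f: f["baseline_zbi_inverted"] > 31),
            SubgroupSpec("zbi_some_burden", P,
                         filter=lambda f: f["baseline_zbi_inverted"] <= 31),
        ]
    if P in ("mci", "caregiver"):
        specs += [
            SubgroupSpec("high_app_use", P,
                         filter=lambda f: f["app_launches"] > 125,
                         filter_intervention_only=True),
            SubgroupSpec("low_app_use", P,
                         filter=lambda f: f["app_launches"] <= 125,
                         filter_intervention_only=True),
        ]
    return specs


def run_sensitivity_suite(
    dataset: TrialDataset,
    specs: list[SubgroupSpec],
    config: AnalysisConfig | None = None,
    tariff: TariffModel | None = None,
    discount: DiscountSpec | None = None,
    mi_m: int = 20,
) -> AnalysisReport:
    """One QALY row per spec, with variant flags altering the pipeline
    (MI replaces complete-case effects; intervention delivery costs
    added; zero-cost units dropped; filters restrict the population)."""
    config = config or AnalysisConfig()
    tariff = tariff or builtin_tariff("toy_linear")
    discount = discount or DiscountSpec(annual_rate=config.discount_rate)
    report = AnalysisReport()
    for spec in specs:
        intervention = InterventionCostSpec() if spec.include_intervention_cost else None
        frame = unit_frame(dataset, spec.population, "qaly", tariff, discount,
                           intervention=intervention)
        frame = _apply_spec_filters(frame, spec)
        if len(frame) == 0:
            report.add_empty(spec.name, spec.population, "QALY",
                             "filter matched no participants")
            continue
        if spec.impute_qalys:
            res = _run_imputed(dataset, spec, frame, config, tariff, discount,
                               m=mi_m)
            report.add(spec.name, spec.population, res, "QALY",
                       rounded=config.round_reported)
            continue
        try:
            res = incremental(frame, config, effect_name="QALY")
        except ValueError as err:
            report.add_empty(spec.name, spec.population, "QALY", str(err))
            continue
        report.add(spec.name, spec.population, res, "QALY",
                   rounded=config.round_reported)
    return report


def run_scenario(
    dataset_b: TrialDataset,
    tariff_b: TariffModel,
    threshold_b: float,
    config: AnalysisConfig | None = None,
    population: str = "mci",
    pooled_with: TrialDataset | None = None,
) -> AnalysisReport:
    """Same pipeline under a substituted tariff and WTP threshold (e.g. a
    second trial site); optionally pooled with another dataset."""
    config = (config or AnalysisConfig()).model_copy(
        update={"wtp_threshold": threshold_b}
    )
    dataset = dataset_b
    if pooled_with is not None:
        dataset = _concat_datasets(dataset_b, pooled_with)
    return run_base_case(dataset, population, config, tariff=tariff_b)


def _concat_datasets(a: TrialDataset, b: TrialDataset) -> TrialDataset:
    """Pool two sites sharing the visit/cost schema (ids prefixed)."""
    for col in ("participant_id", "dyad_id"):
        sa = set(a.visits.columns)
        if sa != set(b.visits.columns):
            raise ValueError("site datasets do not share the visit schema")

    def prefix(df: pd.DataFrame, p: str) -> pd.DataFrame:
        df = df.copy()
        for col in ("participant_id", "dyad_id"):
            if col in df.columns:
                df[col] = p + df[col].astype(str)
        return df

    arms = {f"a_{k}": v for k, v in a.arms.items()}
    arms.update({f"b_{k}": v for k, v in b.arms.items()})
    return TrialDataset(
        pd.concat([prefix(a.visits, "a_"), prefix(b.visits, "b_")],
                  ignore_index=True),
        pd.concat([prefix(a.cost_episodes, "a_"), prefix(b.cost_episodes, "b_")],
                  ignore_index=True),
        pd.concat([prefix(a.participants, "a_"), prefix(b.participants, "b_")],
                  ignore_index=True),
        arms,
        truth=None,
    )
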