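"""Episode-level health care costs → per-participant totals.

Episodes arrive with a cost attached (register data) or with the cost
missing; missing costs are imputed from stratified reference means with
a three-level fallback hierarchy:

1. mean observed cost by (setting, clinic type, personnel type);
2. mean observed cost by (setting, clinic type) — used when personnel
   type is itself missing;
3. for inpatient episodes, mean observed cost *per day* × length of stay.

Totals are aggregated over the 18-month window [0, 540) days, the final
6 months discounted with the same factor as QALYs, and intervention
delivery costs (tablet, mobile data, nurse training time) optionally
added to intervention-arm participants for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .discounting import DiscountSpec

__all__ = [
    "CostReferenceTable",
    "InterventionCostSpec",
    "impute_episode_cost",
    "impute_costs",
    "aggregate_costs",
    "group_cost_summary",
]

WINDOW = (0, 540)  # half-open [0, 540): day 540 itself is excluded


class InterventionCostSpec(BaseModel):
    """Delivery costs of the tablet intervention, per recipient.

    Defaults total 173 per intervention-arm person with MCI: tablet
    purchase, 18 months of mobile data, and the research nurse's time
    for the 1.5-hour training session.
    """

    tablet_unit_cost: float = Field(default=100.0, ge=0)
    mobile_data_cost: float = Field(default=43.0, ge=0)
    nurse_training_cost: float = Field(default=30.0, ge=0)

    @property
    def total(self) -> float:
        return self.tablet_unit_cost + self.mobile_data_cost + self.nurse_training_cost


@dataclass
class CostReferenceTable:
    """Stratified mean costs used to impute missing episode costs."""

    by_setting_clinic_personnel: pd.Series  # index (setting, clinic, personnel)
    by_setting_clinic: pd.Series            # index (setting, clinic)
    inpatient_per_day: float

    @classmethod
    def from_episodes(cls, episodes: pd.DataFrame) -> "CostReferenceTable":
        """Build reference means from observed (non-missing) costs, pooled
        across arms so imputation is not arm-informative."""
        obs = episodes.dropna(subset=["cost"])
        lvl1 = obs.groupby(["setting", "clinic_type", "personnel_type"],
                           dropna=True)["cost"].mean()
        lvl2 = obs.groupby(["setting", "clinic_type"])["cost"].mean()
        inp = obs[obs["setting"] == "inpatient"]
        if len(inp):
            per_day = float((inp["cost"] / inp["length_of_stay_days"]).mean())
        else:
            per_day = float("nan")
        return cls(lvl1, lvl2, per_day)


class UnresolvableEpisodeError(ValueError):
    """No reference mean available at any hierarchy level."""


def impute_episode_cost(episode: pd.Series, ref: CostReferenceTable) -> pd.Series:
    """Fill one episode's missing cost; records imputation provenance.

    Episodes with an observed cost are returned untouched (provenance
    ``observed``).
    """
    ep = episode.copy()
    if not pd.isna(ep["cost"]):
        ep["cost_provenance"] = "observed"
        return ep
    key3 = (ep["setting"], ep["clinic_type"], ep.get("personnel_type"))
    if not pd.isna(key3[2]) and key3 in ref.by_setting_clinic_personnel.index:
        ep["cost"] = float(ref.by_setting_clinic_personnel[key3])
        ep["cost_provenance"] = "setting_clinic_personnel_mean"
        return ep
    key2 = (ep["setting"], ep["clinic_type"])
    if key2 in ref.by_setting_clinic.index:
        ep["cost"] = float(ref.by_setting_clinic[key2])
        ep["cost_provenance"] = "setting_clinic_mean"
        return ep
    if ep["setting"] == "inpatient" and np.isfinite(ref.inpatient_per_day):
        ep["cost"] = float(ref.inpatient_per_day) * float(ep["length_of_stay_days"])
        ep["cost_provenance"] = "inpatient_per_day_mean"
        return ep
    raise UnresolvableEpisodeError(
        f"no reference mean for episode {ep.get('participant_id')!r} "
        f"(setting={ep['setting']!r}, clinic={ep['clinic_type']!r}, "
        f"personnel={ep.get('personnel_type')!r})"
    )


def impute_costs(episodes: pd.DataFrame,
                 ref: CostReferenceTable | None = None) -> pd.DataFrame:
    """Impute every missing episode cost (reference table built from the
    observed episodes themselves when not supplied)."""
    if ref is None:
        ref = CostReferenceTable.from_episodes(episodes)
    out = episodes.copy()
    out["cost_provenance"] = "observed"
    missing = out["cost"].isna()
    if not missing.any():
        return out
    filled = out.loc[missing].apply(lambda r: impute_episode_cost(r, ref), axis=1)
    out.loc[missing, ["cost", "cost_provenance"]] = filled[["cost", "cost_provenance"]]
    return out


def aggregate_costs(
    episodes: pd.DataFrame,
    participants: pd.DataFrame,
    window: tuple[int, int] = WINDOW,
    discount: DiscountSpec | None = None,
    intervention: InterventionCostSpec | None = None,
    intervention_role: str = "person_with_mci",
) -> pd.DataFrame:
    """Per-participant cost totals over the trial window.

    All episode costs must be present (run :func:`impute_costs` first).
    Episodes on or after day 360 are discounted by the same factor as the
    third QALY interval; episodes outside the half-open window are
    excluded (their count is reported in the frame's ``attrs``).
    Intervention delivery costs are added to intervention-arm
    participants of ``intervention_role`` when a spec is given.

    Every participant in ``participants`` gets a row (zero totals when
    they have no episodes).
    """
    discount = discount or DiscountSpec()
    ep = episodes.copy()
    if ep["cost"].isna().any():
        raise ValueError("episodes contain missing costs; impute first")
    in_window = (ep["day"] >= window[0]) & (ep["day"] < window[1])
    excluded = int((~in_window).sum())
    ep = ep[in_window].copy()
    ep["disc_cost"] = ep["cost"] * ep["day"].map(discount.cost_factor)

    by = ep.groupby(["participant_id", "setting"])["disc_cost"].sum().unstack(
        fill_value=0.0
    )
    out = participants[["participant_id", "dyad_id", "role", "arm"]].copy()
    out["inpatient_total"] = out["participant_id"].map(
        by.get("inpatient", pd.Series(dtype=float))).fillna(0.0)
    out["outpatient_total"] = out["participant_id"].map(
        by.get("outpatient", pd.Series(dtype=float))).fillna(0.0)
    out["intervention_total"] = 0.0
    if intervention is not None:
        mask = (out["arm"] == "intervention") & (out["role"] == intervention_role)
        out.loc[mask, "intervention_total"] = intervention.total
    out["grand_total"] = (
        out["inpatient_total"] + out["outpatient_total"] + out["intervention_total"]
    )
    out.attrs["episodes_excluded_outside_window"] = excluded
    return out


def group_cost_summary(
    costs_a: np.ndarray | pd.Series,
    costs_b: np.ndarray | pd.Series,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Arm means/SDs and the between-arm difference ΔC = mean(a) − mean(b)
    with a percentile bootstrap 95% CI."""
    a = pd.Series(costs_a).dropna().to_numpy(dtype=float)
    b = pd.Series(costs_b).dropna().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty arm in cost summary")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = (
        a[rng.integers(0, a.size, (n_boot, a.size))].mean(axis=1)
        - b[rng.integers(0, b.size, (n_boot, b.size))].mean(axis=1)
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(np.std(a, ddof=1)) if a.size > 1 else float("nan"),
        "n_a": int(a.size),
        "mean_b": float(b.mean()),
        "sd_b": float(np.std(b, ddof=1)) if b.size > 1 else float("nan"),
        "n_b": int(b.size),
        "delta_cost": float(a.mean() - b.mean()),
        "ci_cost": (float(lo), float(hi)),
    }
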