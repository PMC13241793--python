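"""Incremental cost-effectiveness estimation.

Point estimates are simple mean differences (intervention − control) of
per-participant costs and effects.  Uncertainty comes from a
nonparametric bootstrap: participants (dyads, in dyad analyses) are
resampled with replacement *within arm*, preserving arm sizes; each
resample yields a (ΔC*, ΔE*) pair.  The same resamples drive the
percentile confidence intervals, the four-quadrant cost-effectiveness
plane, and the acceptability curve

    CEAC(λ) = fraction of resamples with ΔE*·λ − ΔC* > 0.

The ICER carries a dominance classification instead of a bare ratio when
the ratio would be meaningless, and south-west ratios (cheaper but less
effective) are annotated, since the bare number inverts its decision
meaning there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from pydantic import BaseModel, Field

from .impute import multiple_impute  # re-exported as part of the engine surface

__all__ = [
    "AnalysisConfig",
    "ICERResult",
    "IncrementalResult",
    "BootstrapCloud",
    "PooledResult",
    "TestResult",
    "icer",
    "nmb",
    "incremental",
    "bootstrap_cloud",
    "pool",
    "compare_groups",
    "multiple_impute",
]


class AnalysisConfig(BaseModel):
    """Estimation settings: WTP threshold, bootstrap size, discounting."""

    wtp_threshold: float = Field(default=48876.0, ge=0)   # Swedish analysis default
    wtp_grid_max: float = Field(default=200_000.0, ge=0)  # CEAC grid 0..max
    wtp_grid_step: float = Field(default=1000.0, gt=0)
    bootstrap_B: int = Field(default=5000, ge=1)
    discount_rate: float = Field(default=0.03, ge=0)
    seed: int = 0
    round_reported: bool = True  # ICER/NMB to nearest currency unit in reports

    @property
    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_grid_max + self.wtp_grid_step / 2,
                         self.wtp_grid_step)


# ----------------------------------------------------------------------
# ICER / NMB
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ICERResult:
    """Ratio-or-dominance classification of an incremental pair."""

    kind: str                      # ratio | dominated | dominant | undefined
    value: float | None = None     # the (positive, for SW) ratio when kind == ratio
    annotation: str | None = None  # "southwest" when ΔC<0 and ΔE<0

    def display(self, rounded: bool = True) -> str:
        if self.kind == "dominated":
            return "Dominated"
        if self.kind == "dominant":
            return "Dominant"
        if self.kind == "undefined":
            return "Undefined (ΔE = 0)"
        v = round(self.value) if rounded else self.value
        txt = f"{v:,.0f}" if rounded else f"{v}"
        return f"{txt} (SW)" if self.annotation == "southwest" else txt

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display()


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Classify ΔC/ΔE.

    dominated ⇔ ΔC > 0 and ΔE < 0; dominant ⇔ ΔC < 0 and ΔE > 0;
    ΔE = 0 → undefined ratio; ΔC ≤ 0 with ΔE < 0 → the positive ratio
    with a south-west annotation.  Total function: never raises.
    """
    if delta_effect == 0:
        return ICERResult("undefined")
    if delta_cost > 0 and delta_effect < 0:
        return ICERResult("dominated")
    if delta_cost < 0 and delta_effect > 0:
        return ICERResult("dominant")
    ratio = delta_cost / delta_effect
    if delta_effect < 0:  # ΔC ≤ 0 too: south-west quadrant (or its boundary)
        return ICERResult("ratio", value=abs(ratio), annotation="southwest")
    return ICERResult("ratio", value=ratio)


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Net monetary benefit ΔE·λ − ΔC (λ = willingness to pay ≥ 0)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return delta_effect * wtp - delta_cost


# ----------------------------------------------------------------------
# Bootstrap
# ----------------------------------------------------------------------

@dataclass
class BootstrapCloud:
    """B resampled (ΔC*, ΔE*) pairs with quadrant counts and the CEAC."""

    delta_costs: np.ndarray
    delta_effects: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray = field(init=False)
    quadrant_counts: dict = field(init=False)

    def __post_init__(self) -> None:
        dc, de = self.delta_costs, self.delta_effects
        # boundary zeros assigned to the positive side deterministically
        east, north = de >= 0, dc >= 0
        self.quadrant_counts = {
            "NE": int(np.sum(east & north)),
            "NW": int(np.sum(~east & north)),
            "SE": int(np.sum(east & ~north)),
            "SW": int(np.sum(~east & ~north)),
        }
        ok = np.isfinite(de) & np.isfinite(dc)
        self.ceac = np.array([
            float(np.mean(de[ok] * lam - dc[ok] > 0)) for lam in self.wtp_grid
        ])

    @property
    def B(self) -> int:
        return int(self.delta_costs.size)

    def probability_cost_effective(self, wtp: float) -> float:
        return float(np.mean(self.delta_effects * wtp - self.delta_costs > 0))

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})

    def plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_effect": self.delta_effects, "delta_cost": self.delta_costs}
        )


def bootstrap_cloud(frame: pd.DataFrame, config: AnalysisConfig) -> BootstrapCloud:
    """Stratified participant bootstrap of the incremental pair.

    ``frame`` has one row per resampling unit with columns ``arm``,
    ``cost``, ``effect`` (effect may be missing for some units; a
    resample's ΔE* then averages the non-missing effects drawn, which
    preserves the differing cost/effect sample sizes while keeping the
    cost–effect correlation).
    """
    if config.bootstrap_B < 1:
        raise ValueError("bootstrap_B must be ≥ 1")
    rng = np.random.default_rng(config.seed)
    arm_stats = {}
    for arm in ("intervention", "control"):
        sub = frame[frame["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"empty arm: {arm}")
        costs = sub["cost"].to_numpy(dtype=float)
        effects = sub["effect"].to_numpy(dtype=float)
        idx = rng.integers(0, len(sub), (config.bootstrap_B, len(sub)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN resamples
            arm_stats[arm] = (
                np.nanmean(costs[idx], axis=1),
                np.nanmean(effects[idx], axis=1),
            )
    dc = arm_stats["intervention"][0] - arm_stats["control"][0]
    de = arm_stats["intervention"][1] - arm_stats["control"][1]
    return BootstrapCloud(dc, de, config.wtp_grid)


# ----------------------------------------------------------------------
# Incremental analysis
# ----------------------------------------------------------------------

@dataclass
class IncrementalResult:
    """ΔC, ΔE with bootstrap CIs, ICER-or-dominance, and NMB."""

    delta_cost: float
    delta_effect: float
    ci_cost: tuple[float, float]
    ci_effect: tuple[float, float]
    icer: ICERResult
    nmb: float
    effect_name: str = "QALY"
    n_cost: tuple[int, int] = (0, 0)    # (intervention, control)
    n_effect: tuple[int, int] = (0, 0)
    cloud: BootstrapCloud | None = None

    def nmb_rounded(self) -> int:
        return int(round(self.nmb))


def incremental(
    frame: pd.DataFrame,
    config: AnalysisConfig,
    effect_name: str = "QALY",
    with_cloud: bool = True,
) -> IncrementalResult:
    """Mean-difference incremental analysis with percentile bootstrap CIs.

    ``frame``: one row per resampling unit, columns ``arm``, ``cost``,
    ``effect``.  Point estimates use all non-missing values per column;
    CIs use the same resamples as the CE plane/CEAC.
    """
    means = {}
    for arm in ("intervention", "control"):
        sub = frame[frame["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"empty arm: {arm}")
        if sub["effect"].notna().sum() == 0:
            raise ValueError(f"all effects missing in arm {arm!r}")
        means[arm] = (
            float(sub["cost"].mean()),
            float(sub["effect"].mean()),
            int(sub["cost"].notna().sum()),
            int(sub["effect"].notna().sum()),
        )
    dc = means["intervention"][0] - means["control"][0]
    de = means["intervention"][1] - means["control"][1]
    cloud = bootstrap_cloud(frame, config) if with_cloud else None
    if cloud is not None:
        ci_c = tuple(np.percentile(cloud.delta_costs, [2.5, 97.5]))
        dok = cloud.delta_effects[np.isfinite(cloud.delta_effects)]
        ci_e = tuple(np.percentile(dok, [2.5, 97.5]))
    else:
        ci_c = ci_e = (float("nan"), float("nan"))
    return IncrementalResult(
        delta_cost=dc,
        delta_effect=de,
        ci_cost=(float(ci_c[0]), float(ci_c[1])),
        ci_effect=(float(ci_e[0]), float(ci_e[1])),
        icer=icer(dc, de),
        nmb=nmb(dc, de, config.wtp_threshold),
        effect_name=effect_name,
        n_cost=(means["intervention"][2], means["control"][2]),
        n_effect=(means["intervention"][3], means["control"][3]),
        cloud=cloud,
    )


# ----------------------------------------------------------------------
# Pooling of multiply imputed analyses (Rubin's rules)
# ----------------------------------------------------------------------

@dataclass
class PooledResult:
    """Pooled estimates over m imputations.

    Point estimates are the mean of per-imputation estimates; total
    variance = within + (1 + 1/m) × between.
    """

    m: int
    per_imputation: list[IncrementalResult]
    delta_cost: float
    delta_effect: float
    icer: ICERResult
    nmb: float
    var_effect: float
    var_cost: float

    @property
    def ci_effect(self) -> tuple[float, float]:
        half = 1.959963984540054 * math.sqrt(self.var_effect)
        return (self.delta_effect - half, self.delta_effect + half)

    @property
    def ci_cost(self) -> tuple[float, float]:
        half = 1.959963984540054 * math.sqrt(self.var_cost)
        return (self.delta_cost - half, self.delta_cost + half)


def _ci_to_var(ci: tuple[float, float]) -> float:
    return ((ci[1] - ci[0]) / (2 * 1.959963984540054)) ** 2


def pool(results: list[IncrementalResult], wtp: float) -> PooledResult:
    """Rubin's-rules pooling of per-imputation incremental results."""
    if len(results) < 2:
        raise ValueError("variance pooling needs m ≥ 2 imputations")
    names = {r.effect_name for r in results}
    if len(names) != 1:
        raise ValueError(f"inconsistent effect_name across imputations: {names}")
    m = len(results)
    de = np.array([r.delta_effect for r in results])
    dc = np.array([r.delta_cost for r in results])
    w_e = np.array([_ci_to_var(r.ci_effect) for r in results])
    w_c = np.array([_ci_to_var(r.ci_cost) for r in results])
    between_e = float(np.var(de, ddof=1))
    between_c = float(np.var(dc, ddof=1))
    pooled_de, pooled_dc = float(de.mean()), float(dc.mean())
    return PooledResult(
        m=m,
        per_imputation=list(results),
        delta_cost=pooled_dc,
        delta_effect=pooled_de,
        icer=icer(pooled_dc, pooled_de),
        nmb=nmb(pooled_dc, pooled_de, wtp),
        var_effect=float(np.nanmean(w_e)) + (1 + 1 / m) * between_e,
        var_cost=float(np.nanmean(w_c)) + (1 + 1 / m) * between_c,
    )


# ----------------------------------------------------------------------
# Group comparison tests
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    kind: str
    flag: str | None = None  # e.g. "zero_variance"


def compare_groups(values_a, values_b, kind: str = "continuous") -> TestResult:
    """Two-sided comparison between groups.

    ``continuous``: independent two-sample t test (equal variances);
    ``categorical``: chi-square without continuity correction, on the
    2×n table of label counts; ``paired``: paired t test.  Degenerate
    zero-variance continuous input is signalled via ``flag`` with the
    limiting p-value (1 for equal means, 0 otherwise).
    """
    if kind == "continuous":
        a = pd.Series(values_a).dropna().to_numpy(dtype=float)
        b = pd.Series(values_b).dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("t test needs at least two values per group")
        if np.std(a) == 0 and np.std(b) == 0:
            same = a.mean() == b.mean()
            return TestResult(0.0 if same else math.inf,
                              1.0 if same else 0.0, kind, flag="zero_variance")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return TestResult(float(t), float(p), kind)
    if kind == "categorical":
        a = pd.Series(values_a).dropna()
        b = pd.Series(values_b).dropna()
        tab = pd.crosstab(
            np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
            pd.concat([a, b], ignore_index=True),
        ).to_numpy()
        if tab.shape[1] < 2:
            raise ValueError("chi-square needs at least two categories")
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return TestResult(float(chi2), float(p), kind)
    if kind == "paired":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length samples")
        d = a - b
        if np.std(d) == 0:
            same = float(d.mean()) == 0.0
            return TestResult(0.0 if same else math.inf,
                              1.0 if same else 0.0, kind, flag="zero_variance")
        t, p = stats.ttest_rel(a, b)
        return TestResult(float(t), float(p), kind)
    raise ValueError(f"unknown test kind {kind!r}")
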