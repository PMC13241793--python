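"""QALY estimation by the area-under-the-curve (trapezoid) method.

Utilities observed at the four assessments (baseline, ~6, ~12, ~18
months) are joined linearly over the *actual* days between visits, so
out-of-window visits contribute their true elapsed time.  The base-case
analysis is complete-case: a participant missing any follow-up utility
has no total QALY, unless they died — then utility is fixed at 0 from
the day of death to the end of the window and the trajectory counts as
complete.  The final 6-month interval is discounted (see
:mod:`dyadcea.discounting`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discounting import DiscountSpec, YEAR_DAYS
from .valuation import TariffModel

__all__ = [
    "interval_qaly",
    "participant_qaly",
    "qaly_table",
    "dyad_qaly_table",
    "group_qaly_summary",
    "QalyTrajectory",
    "GroupSummary",
]

TRIAL_END_DAY = 540


def interval_qaly(u_start: float, u_end: float, days: float,
                  year_length: float = YEAR_DAYS) -> float:
    """Trapezoid QALY for one inter-visit interval: mean utility × years.

    Exact for a linearly interpolated utility path.
    """
    if days < 0:
        raise ValueError(f"interval length must be non-negative; got {days}")
    return (u_start + u_end) / 2.0 * days / year_length


@dataclass
class QalyTrajectory:
    """Per-participant utility path and its (discounted) QALY integrals."""

    participant_id: object
    points: list[tuple[float, float]]           # (actual_day, utility)
    interval_qalys: list[float]                 # discounted, one per point pair
    total_qaly: float                           # NaN when not complete
    complete: bool


def _interval_index(mid_day: float) -> int:
    """Which 6-month block a segment midpoint falls in (for discounting)."""
    return 2 if mid_day >= 360 else (1 if mid_day >= 180 else 0)


def participant_qaly(
    visits: pd.DataFrame,
    tariff: TariffModel,
    discount: DiscountSpec | None = None,
) -> QalyTrajectory:
    """QALY trajectory for one participant's visit records.

    ``visits`` needs columns ``participant_id, visit_index, actual_day,
    eq5d_state`` and optionally ``deceased``/``death_day``.  Visit days
    must be strictly increasing with baseline at day 0.
    """
    discount = discount or DiscountSpec()
    v = visits.sort_values("visit_index")
    pid = v["participant_id"].iloc[0]
    days = v["actual_day"].to_numpy(dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError(f"participant {pid}: visit days not strictly increasing")
    if v["visit_index"].iloc[0] != 0 or days[0] != 0:
        raise ValueError(f"participant {pid}: baseline visit (day 0) required")
    utils = tariff.value_digits(v["eq5d_state"])

    death_day = None
    if "deceased" in v.columns and bool(v["deceased"].any()):
        dd = v.loc[v["deceased"].astype(bool), "death_day"]
        death_day = float(dd.dropna().iloc[0])

    if death_day is not None:
        alive = days < death_day
        pts = [(float(d), float(u)) for d, u in zip(days[alive], utils[alive])
               if not np.isnan(u)]
        pts.append((death_day, 0.0))
        if death_day < TRIAL_END_DAY:
            pts.append((float(TRIAL_END_DAY), 0.0))
        complete = all(not np.isnan(u) for u in utils[alive])
    else:
        pts = [(float(d), float(u)) for d, u in zip(days, utils)]
        complete = len(pts) == 4 and not any(np.isnan(u) for _, u in pts)

    iq: list[float] = []
    for k, ((d0, u0), (d1, u1)) in enumerate(zip(pts[:-1], pts[1:])):
        if np.isnan(u0) or np.isnan(u1):
            iq.append(float("nan"))
            continue
        raw = interval_qaly(u0, u1, d1 - d0)
        mid = (d0 + d1) / 2.0
        idx = _interval_index(mid) if death_day is not None else k
        iq.append(raw * discount.factor(idx, mid_day=mid))
    total = float(np.sum(iq)) if complete and iq and not np.any(np.isnan(iq)) else float("nan")
    return QalyTrajectory(pid, pts, iq, total, bool(complete and not np.isnan(total)))


def qaly_table(
    visits: pd.DataFrame,
    tariff: TariffModel,
    discount: DiscountSpec | None = None,
) -> pd.DataFrame:
    """Vectorized QALY totals for every participant in a long visit table.

    Returns one row per participant: ``interval_1..interval_3``, ``total``,
    ``complete``.  Row order of the input never affects the result.
    """
    discount = discount or DiscountSpec()
    v = visits.copy()
    v["utility"] = tariff.value_digits(v["eq5d_state"])
    dup = v.duplicated(subset=["participant_id", "visit_index"])
    if dup.any():
        raise ValueError("duplicated (participant, visit_index) records")

    deceased_ids: set = set()
    if "deceased" in v.columns:
        deceased_ids = set(v.loc[v["deceased"].astype(bool).fillna(False),
                                 "participant_id"].unique())

    wide_u = v.pivot(index="participant_id", columns="visit_index", values="utility")
    wide_d = v.pivot(index="participant_id", columns="visit_index", values="actual_day")
    for k in range(4):
        if k not in wide_u.columns:
            wide_u[k] = np.nan
            wide_d[k] = np.nan
    wide_u = wide_u[[0, 1, 2, 3]]
    wide_d = wide_d[[0, 1, 2, 3]].astype(float)

    rows = {}
    regular = [p for p in wide_u.index if p not in deceased_ids]
    U = wide_u.loc[regular].to_numpy()
    D = wide_d.loc[regular].to_numpy()
    with np.errstate(invalid="ignore"):
        bad = np.nansum(np.diff(D, axis=1) <= 0, axis=1) > 0
    if bad.any():
        raise ValueError("visit days not strictly increasing for some participants")
    intervals = np.empty((len(regular), 3))
    for k in range(3):
        mids = (D[:, k] + D[:, k + 1]) / 2.0
        # discount factor depends only on interval index in the default
        # single-factor scheme; mid-interval uses per-row midpoints
        if discount.method == "single_factor":
            f = discount.factor(k)
            intervals[:, k] = (U[:, k] + U[:, k + 1]) / 2.0 * (D[:, k + 1] - D[:, k]) / YEAR_DAYS * f
        else:
            f = np.array([discount.factor(k, mid_day=m) if np.isfinite(m) else np.nan
                          for m in mids])
            intervals[:, k] = (U[:, k] + U[:, k + 1]) / 2.0 * (D[:, k + 1] - D[:, k]) / YEAR_DAYS * f
    complete = ~np.isnan(intervals).any(axis=1)
    totals = np.where(complete, np.nansum(intervals, axis=1), np.nan)
    out = pd.DataFrame(
        {
            "participant_id": regular,
            "interval_1": intervals[:, 0],
            "interval_2": intervals[:, 1],
            "interval_3": intervals[:, 2],
            "total": totals,
            "complete": complete,
        }
    )

    # deceased participants: small loop, death overrides the interval grid
    extra = []
    for pid in deceased_ids:
        traj = participant_qaly(v[v["participant_id"] == pid], tariff, discount)
        iq = traj.interval_qalys + [np.nan] * 3
        extra.append(
            {
                "participant_id": pid,
                "interval_1": iq[0],
                "interval_2": iq[1],
                "interval_3": iq[2],
                "total": traj.total_qaly,
                "complete": traj.complete,
            }
        )
    if extra:
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out.sort_values("participant_id").reset_index(drop=True)


def dyad_qaly_table(qalys: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Dyad QALY = sum of both members' totals, defined only when both
    members are complete."""
    merged = qalys.merge(
        participants[["participant_id", "dyad_id"]], on="participant_id"
    )
    g = merged.groupby("dyad_id").agg(
        total=("total", "sum"),
        complete=("complete", "all"),
        n=("participant_id", "count"),
    )
    g.loc[~g["complete"] | (g["n"] != 2), "total"] = np.nan
    g["complete"] &= g["n"] == 2
    return g.drop(columns="n").reset_index()


@dataclass
class GroupSummary:
    mean: float
    sd: float          # NaN (flagged) when n == 1
    n: int


def group_qaly_summary(totals: pd.Series | np.ndarray) -> GroupSummary:
    """Mean/SD/n of complete QALY totals; raises on an empty group."""
    x = pd.Series(totals).dropna().to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty group: no complete QALY totals")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return GroupSummary(mean=float(np.mean(x)), sd=sd, n=int(x.size))
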