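"""Discounting of outcomes and costs accruing beyond the first trial year.

The trial window is 18 months; national guidelines prescribe a 3% annual
rate, applied here to the final 6 months (the third inter-visit interval
and cost episodes falling in it).  Two readings are supported:

``single_factor`` (default)
    multiply the third interval by 1/(1+r) — the whole interval lies in
    trial year two;
``mid_interval``
    multiply by (1+r)^-(t_mid/365.25 − 1) with t_mid the interval's
    midpoint in days, i.e. continuous-time discounting from month 12.

With rate 0 both are the identity.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

YEAR_DAYS = 365.25


class DiscountSpec(BaseModel):
    """Annual discount rate and which 6-month intervals it applies to."""

    annual_rate: float = Field(default=0.03, ge=0.0)
    applies_to: tuple[int, ...] = (2,)  # interval indices (0-based); 2 = months 12-18
    method: str = "single_factor"

    def factor(self, interval_index: int, mid_day: float | None = None) -> float:
        """Multiplicative discount factor for one inter-visit interval."""
        if self.annual_rate == 0.0 or interval_index not in self.applies_to:
            return 1.0
        if self.method == "single_factor":
            return 1.0 / (1.0 + self.annual_rate)
        if self.method == "mid_interval":
            if mid_day is None:
                raise ValueError("mid_interval discounting needs the interval midpoint")
            years_beyond = max(mid_day / YEAR_DAYS - 1.0, 0.0)
            return (1.0 + self.annual_rate) ** (-years_beyond)
        raise ValueError(f"unknown discounting method {self.method!r}")

    def cost_factor(self, day: float) -> float:
        """Factor for a cost episode at ``day`` (same rule as outcomes)."""
        if self.annual_rate == 0.0:
            return 1.0
        interval = 2 if day >= 360 else (1 if day >= 180 else 0)
        return self.factor(interval, mid_day=day)
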