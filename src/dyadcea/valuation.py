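"""Valuation of raw instrument responses onto analysis outcome scales.

EQ-5D-3L responses (five dimensions, three levels each, 243 possible
health states) are mapped to utilities through a pluggable country
*tariff* (value set).  Two tariff forms are supported:

``additive_decrement``
    utility = intercept − Σ decrement(dimension, level), the common
    published regression form;
``lookup_table_243``
    an explicit utility for each of the 243 states.

The module also provides the composite quality-of-life score for
person-with-MCI/caregiver dyads (self rating weighted twice the proxy
rating, kept on the instrument's 13–52 scale) and the inversion of the
12-item Zarit Burden Interview so that higher always means better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "HealthState",
    "TariffModel",
    "TariffError",
    "load_tariff",
    "builtin_tariff",
    "value_state",
    "composite_qolad",
    "invert_zbi",
    "all_states",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

N_STATES = 243  # 3 ** 5


class TariffError(ValueError):
    """Raised when a tariff file is malformed or incomplete."""


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-3L response: a level in {1, 2, 3} for each dimension."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            lv = getattr(self, dim)
            if lv not in (1, 2, 3):
                raise ValueError(f"{dim} level must be 1, 2 or 3; got {lv!r}")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in DIMENSIONS)  # type: ignore[return-value]

    @property
    def digits(self) -> str:
        """Five-digit string form, e.g. ``'21232'``."""
        return "".join(str(l) for l in self.levels)

    @property
    def index(self) -> int:
        """Lexicographic index in 0..242 (mobility most significant)."""
        idx = 0
        for l in self.levels:
            idx = idx * 3 + (l - 1)
        return idx

    @property
    def n_problems(self) -> int:
        """Total excess over full health, Σ(level − 1); 0 for 11111."""
        return sum(self.levels) - 5

    @classmethod
    def from_digits(cls, digits: str | int) -> "HealthState":
        s = str(int(digits)).zfill(5)
        if len(s) != 5:
            raise ValueError(f"EQ-5D-3L state must have 5 digits; got {digits!r}")
        return cls(*(int(c) for c in s))

    @classmethod
    def from_index(cls, index: int) -> "HealthState":
        if not 0 <= index < N_STATES:
            raise ValueError(f"state index out of range: {index}")
        levels = []
        for _ in range(5):
            levels.append(index % 3 + 1)
            index //= 3
        return cls(*levels[::-1])


def all_states() -> list[HealthState]:
    """All 243 EQ-5D-3L states in lexicographic order."""
    return [HealthState.from_index(i) for i in range(N_STATES)]


def _state_level_matrix() -> np.ndarray:
    """243×5 matrix of levels, row i = state with index i."""
    idx = np.arange(N_STATES)
    cols = []
    for d in range(5):
        cols.append((idx // 3 ** (4 - d)) % 3 + 1)
    return np.stack(cols, axis=1)


@dataclass
class TariffModel:
    """A value set mapping each EQ-5D-3L state to a utility.

    Parameters
    ----------
    name : str
        Label, e.g. ``"swedish_experience_based"`` or ``"toy_linear"``.
    form : str
        ``"additive_decrement"`` or ``"lookup_table_243"``.
    coefficients : mapping
        As loaded from file: for the additive form, ``"intercept"`` plus
        ``"<dimension>:<level>"`` decrements for levels 2 and 3; for the
        lookup form, ``"<digits>"`` → utility for all 243 states.
    """

    name: str
    form: str
    coefficients: Mapping[str, float]
    utility_range: tuple[float, float] = field(init=False)
    _utilities: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        levels = _state_level_matrix()
        if self.form == "additive_decrement":
            missing = [
                f"{dim}:{lv}"
                for dim in DIMENSIONS
                for lv in (2, 3)
                if f"{dim}:{lv}" not in self.coefficients
            ]
            if "intercept" not in self.coefficients:
                missing.insert(0, "intercept")
            if missing:
                raise TariffError(
                    f"tariff {self.name!r} missing coefficient(s): {', '.join(missing)}"
                )
            dec = np.zeros((5, 4))
            for d, dim in enumerate(DIMENSIONS):
                for lv in (2, 3):
                    dec[d, lv] = float(self.coefficients[f"{dim}:{lv}"])
            u = float(self.coefficients["intercept"]) - dec[
                np.arange(5)[None, :], levels
            ].sum(axis=1)
        elif self.form == "lookup_table_243":
            digits = [
                "".join(str(l) for l in row) for row in levels
            ]
            missing = [d for d in digits if d not in self.coefficients]
            if missing:
                raise TariffError(
                    f"tariff {self.name!r} missing {len(missing)} state(s), "
                    f"first: {missing[0]}"
                )
            u = np.array([float(self.coefficients[d]) for d in digits])
        else:
            raise TariffError(f"unknown tariff form {self.form!r}")

        if not np.all(np.isfinite(u)):
            raise TariffError(f"tariff {self.name!r} produces non-finite utilities")
        if u[0] < u.max():
            raise TariffError(
                f"tariff {self.name!r}: full health (11111) must attain the maximum"
            )
        self._utilities = u
        self.utility_range = (float(u.min()), float(u.max()))
        # Nearest-state inversion table: sorted utilities with, per distinct
        # utility, the representative state having fewest problems (ties on
        # problem count broken toward the lexicographically smallest digits).
        n_problems = levels.sum(axis=1) - 5
        order = np.lexsort((np.arange(N_STATES), n_problems, u))
        u_sorted = u[order]
        keep = np.concatenate(([True], np.diff(u_sorted) > 0))
        self._inv_utilities = u_sorted[keep]
        self._inv_states = order[keep]
        self._inv_problems = n_problems[order[keep]]

    # -- valuation -----------------------------------------------------

    def value(self, state: HealthState) -> float:
        """Utility of a single state (pure function of state + tariff)."""
        return float(self._utilities[state.index])

    def value_indices(self, indices: np.ndarray) -> np.ndarray:
        """Vectorized valuation of state indices (NaN passes through)."""
        indices = np.asarray(indices)
        if np.issubdtype(indices.dtype, np.floating):
            out = np.full(indices.shape, np.nan)
            ok = ~np.isnan(indices)
            out[ok] = self._utilities[indices[ok].astype(int)]
            return out
        return self._utilities[indices.astype(int)]

    def value_digits(self, digits: Iterable) -> np.ndarray:
        """Vectorized valuation of five-digit state codes (NaN-safe)."""
        idx = np.array(
            [
                np.nan if pd.isna(d) else HealthState.from_digits(d).index
                for d in digits
            ],
            dtype=float,
        )
        return self.value_indices(idx)

    # -- inversion -----------------------------------------------------

    def nearest_state_indices(self, utilities: np.ndarray) -> np.ndarray:
        """State indices whose utility is nearest each latent value.

        Equidistant neighbours are resolved toward the state with fewer
        problems, so that simulation and valuation stay consistent under
        any tariff.
        """
        u = np.asarray(utilities, dtype=float)
        grid = self._inv_utilities
        pos = np.searchsorted(grid, u)
        lo = np.clip(pos - 1, 0, grid.size - 1)
        hi = np.clip(pos, 0, grid.size - 1)
        d_lo = np.abs(u - grid[lo])
        d_hi = np.abs(grid[hi] - u)
        take_hi = d_hi < d_lo
        tie = d_hi == d_lo
        take_hi |= tie & (self._inv_problems[hi] < self._inv_problems[lo])
        choice = np.where(take_hi, hi, lo)
        return self._inv_states[choice]

    def nearest_state(self, utility: float) -> HealthState:
        return HealthState.from_index(int(self.nearest_state_indices([utility])[0]))


def value_state(state: HealthState, tariff: TariffModel) -> float:
    """Utility of ``state`` under ``tariff`` (deterministic, within range)."""
    return tariff.value(state)


# ---------------------------------------------------------------------
# Tariff files
# ---------------------------------------------------------------------

def load_tariff(path: str | Path, name: str | None = None) -> TariffModel:
    """Load and validate a tariff coefficient CSV.

    The file has columns ``form, term, level, coefficient``: additive
    rows use ``term`` = dimension name (or ``intercept``) with level 2/3,
    lookup rows use ``term`` = the five-digit state code.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"term": str}, comment="#")
    required = {"form", "term", "level", "coefficient"}
    if not required.issubset(df.columns):
        raise TariffError(
            f"tariff file {path.name} must have columns {sorted(required)}"
        )
    forms = df["form"].unique()
    if len(forms) != 1:
        raise TariffError(f"tariff file {path.name} mixes forms: {list(forms)}")
    form = str(forms[0])
    coeffs: dict[str, float] = {}
    for _, row in df.iterrows():
        term = str(row["term"]).strip()
        if form == "additive_decrement" and term != "intercept":
            key = f"{term}:{int(row['level'])}"
        elif form == "lookup_table_243":
            key = str(int(term)).zfill(5)
        else:
            key = term
        coeffs[key] = float(row["coefficient"])
    return TariffModel(name=name or path.stem, form=form, coefficients=coeffs)


def builtin_tariff(name: str) -> TariffModel:
    """Load one of the tariffs shipped with the package.

    ``toy_linear`` is exact by construction (utility = 1 − 0.1·Σ(level−1))
    and is the tariff used throughout the test-suite.  The named country
    value sets are *synthetic stand-ins* with realistic structure and
    range, shipped as replaceable data assets — substitute the licensed
    coefficient files before any real-data use.
    """
    from importlib import resources

    fname = {
        "toy_linear": "toy_linear.csv",
        "swedish_experience_based": "swedish_experience_based_synthetic.csv",
        "spanish_tto": "spanish_tto_synthetic.csv",
        "eu_vas": "eu_vas_synthetic.csv",
    }.get(name)
    if fname is None:
        raise TariffError(f"unknown built-in tariff {name!r}")
    ref = resources.files("dyadcea") / "tariffs" / fname
    with resources.as_file(ref) as p:
        return load_tariff(p, name=name)


# ---------------------------------------------------------------------
# Other outcome scales
# ---------------------------------------------------------------------

def composite_qolad(self_score, proxy_score):
    """Weighted composite QoL-AD: (2·self + proxy) / 3, on the 13–52 scale.

    The person with MCI's self rating carries twice the weight of the
    caregiver's proxy rating.  Either score missing yields a missing
    composite (complete-pair rule — the weighting needs both inputs).
    Accepts scalars or array-likes.
    """
    s = np.asarray(self_score, dtype=float)
    p = np.asarray(proxy_score, dtype=float)
    for arr, label in ((s, "self"), (p, "proxy")):
        bad = ~np.isnan(arr) & ((arr < 13) | (arr > 52))
        if np.any(bad):
            raise ValueError(f"QoL-AD {label} score outside 13..52")
    out = (2.0 * s + p) / 3.0
    if out.ndim == 0:
        return float(out) if not np.isnan(out) else float("nan")
    return out


def invert_zbi(raw):
    """Invert the ZBI-12 so higher means less burden: 48 − raw.

    Raw < 17 ("no burden") maps to inverted > 31; the boundary raw = 17
    maps to exactly 31.  An involution about 24.
    """
    r = np.asarray(raw, dtype=float)
    bad = ~np.isnan(r) & ((r < 0) | (r > 48))
    if np.any(bad):
        raise ValueError("ZBI-12 raw score outside 0..48")
    out = 48.0 - r
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class OutcomeScores:
    """Per-visit outcome bundle on analysis scales."""

    utility: float
    qolad_composite: float
    zbi_inverted: float
    mmse: float
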