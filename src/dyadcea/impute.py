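"""Multiple imputation by chained equations with predictive mean matching.

Missingness in this pipeline sits almost entirely in follow-up EQ-5D
utilities (monotone dropout plus sparse item missingness), assumed MAR
given baseline covariates and arm.  Each incomplete column is imputed by
type-1 PMM: a Bayesian linear regression draw produces predicted means,
and each missing row receives the *observed* value of one of its k
nearest donors by predicted mean — imputations therefore stay on the
support of the data (here, the tariff's representable utilities).

The sampler is driven by a passed ``numpy`` Generator, so a fixed seed
gives bit-identical imputations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["multiple_impute", "pmm_impute_once"]


def _design_matrix(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Numeric design matrix with intercept; categoricals one-hot encoded,
    stray NaNs in predictors mean-filled."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        s = df[c]
        if s.isna().all():
            raise ValueError(f"predictor {c!r} is entirely missing")
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            if np.isnan(x).any():
                x = np.where(np.isnan(x), np.nanmean(x), x)
            parts.append(x[:, None])
        else:
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            parts.append(d.to_numpy())
    return np.concatenate(parts, axis=1)


def _bayes_pmm_column(
    y: np.ndarray, X: np.ndarray, miss: np.ndarray,
    rng: np.random.Generator, k_donors: int,
) -> np.ndarray:
    """One PMM draw for one column; returns y with missing entries filled."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n_obs, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n_obs - p, 1)
    sigma2_star = resid @ resid / rng.chisquare(dof)
    cov = sigma2_star * XtX_inv
    beta_star = beta_hat + np.linalg.cholesky(
        cov + 1e-12 * np.eye(p)
    ) @ rng.standard_normal(p)

    yhat_obs = Xo @ beta_hat
    yhat_mis = X[miss] @ beta_star
    # k nearest donors by predicted mean, one drawn at random per row
    dist = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
    kk = min(k_donors, n_obs)
    donors = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = donors[np.arange(donors.shape[0]), rng.integers(0, kk, donors.shape[0])]
    out = y.copy()
    out[miss] = yo[pick]
    return out


def pmm_impute_once(
    df: pd.DataFrame,
    impute_cols: list[str],
    predictor_cols: list[str],
    rng: np.random.Generator,
    iterations: int = 10,
    k_donors: int = 5,
) -> pd.DataFrame:
    """One completed copy of ``df`` (chained equations, fixed iteration
    count)."""
    work = df.copy()
    masks = {c: work[c].isna().to_numpy() for c in impute_cols}
    todo = [c for c in impute_cols if masks[c].any()]
    if not todo:
        return work
    for c in todo:
        if masks[c].all():
            raise ValueError(f"column {c!r} has no observed values to impute from")
        obs_vals = work[c].dropna().to_numpy(dtype=float)
        fill = rng.choice(obs_vals, size=int(masks[c].sum()))
        work.loc[masks[c], c] = fill
    for _ in range(iterations):
        for c in todo:
            others = [o for o in impute_cols if o != c]
            X = _design_matrix(work, predictor_cols + others)
            y = work[c].to_numpy(dtype=float)
            work[c] = _bayes_pmm_column(y, X, masks[c], rng, k_donors)
    return work


def multiple_impute(
    df: pd.DataFrame,
    impute_cols: list[str],
    predictor_cols: list[str],
    m: int = 20,
    seed: int | np.random.Generator = 0,
    iterations: int = 10,
    k_donors: int = 5,
) -> list[pd.DataFrame]:
    """``m`` completed copies of ``df``.

    With no missing values in ``impute_cols`` all copies equal the input.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for c in predictor_cols:
        if df[c].isna().all():
            raise ValueError(f"predictor {c!r} is entirely missing")
    return [
        pmm_impute_once(df, impute_cols, predictor_cols, rng, iterations, k_donors)
        for _ in range(m)
    ]
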