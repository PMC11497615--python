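"""Multiple imputation by chained equations with predictive mean matching (PMM),
and Rubin's-rules pooling of downstream estimates.

Missing covariates (in this study chiefly the household traditional-economy
score) are filled m times by independent chained-equations chains.  Each
incomplete column is regressed on the other covariates, and every missing
cell receives the *observed* value of one of the k donors whose predicted
means lie closest — so imputed values are always real observed values, never
model fantasies.  The conditional models are linear regressions for numeric
columns (logistic predicted probabilities serve as the matching metric for a
binary column): PMM semantics, the number of imputations and the iteration
count are the analysis-visible contract, and this engine is deterministic
and dependency-light.  Note this deliberately differs from random-forest
engines such as missRanger that share the same PMM contract.

Downstream model estimates fitted on each completed dataset are combined by
Rubin's rules into one estimate, standard error and degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cycle_data import Dataset

__all__ = [
    "ImputationSet",
    "PooledEstimate",
    "DEFAULT_IMPUTABLE",
    "DEFAULT_PREDICTORS",
    "impute_chained_pmm",
    "pool_rubin",
]

DEFAULT_IMPUTABLE = ("trad_econ", "body_fat")
# auxiliary predictors available in the cycle schema; richer auxiliary data
# (weight, height, age at first birth, ...) can be appended by the caller
DEFAULT_PREDICTORS = ("hb", "age", "breastfeeding")


@dataclass
class ImputationSet:
    """m completed datasets from independent chained-equations chains."""

    datasets: list[Dataset]
    m: int
    seed: int
    iterations: int
    columns: tuple[str, ...] = DEFAULT_IMPUTABLE


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination across m imputed-data analyses.

    t_total = w + (1 + 1/m) * b;  df = (m-1) * (1 + w / ((1 + 1/m) * b))^2,
    with df = inf when the between-imputation variance b is zero.
    """

    qbar: float
    w: float
    b: float
    t_total: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.t_total)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return u.size <= 2 and set(u).issubset({0.0, 1.0})


def _predicted_means(Xobs, yobs, Xall) -> np.ndarray:
    """OLS (or logistic, for 0/1 targets) predictions used as the PMM metric."""
    if _is_binary(yobs):
        from .mixed_models import _irls_logistic
        from scipy.special import expit

        beta = _irls_logistic(Xobs, yobs)
        return expit(Xall @ beta)
    beta, *_ = np.linalg.lstsq(Xobs, yobs, rcond=None)
    return Xall @ beta


def _impute_once(
    frame: pd.DataFrame,
    columns: tuple[str, ...],
    predictors: tuple[str, ...],
    max_iter: int,
    k_donors: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    df = frame.copy()
    obs_masks = {c: df[c].notna().to_numpy() for c in columns}
    incomplete = [c for c in columns if not obs_masks[c].all()]

    # initialize missing cells with random draws from the observed values
    for c in incomplete:
        obs = df.loc[obs_masks[c], c].to_numpy(dtype=float)
        n_mis = int((~obs_masks[c]).sum())
        df.loc[~obs_masks[c], c] = rng.choice(obs, size=n_mis, replace=True)

    for _ in range(max_iter if incomplete else 0):
        for c in incomplete:
            others = [p for p in predictors if p != c] + [
                o for o in columns if o != c and o not in predictors
            ]
            X = np.column_stack(
                [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in others]
            )
            obs = obs_masks[c]
            yobs = frame.loc[obs, c].to_numpy(dtype=float)
            yhat = _predicted_means(X[obs], yobs, X)
            yhat_obs, yhat_mis = yhat[obs], yhat[~obs]
            k = min(k_donors, len(yobs))
            # k nearest observed donors by predicted mean, drawn uniformly
            dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
            donor_idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = rng.integers(0, k, size=len(yhat_mis))
            df.loc[~obs, c] = yobs[donor_idx[np.arange(len(yhat_mis)), pick]]
    return df


def impute_chained_pmm(
    ds: Dataset,
    m: int = 5,
    max_iter: int = 10,
    k_donors: int = 5,
    seed: int = 0,
    columns: tuple[str, ...] = DEFAULT_IMPUTABLE,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> ImputationSet:
    """Impute ``columns`` m times by chained equations with PMM.

    Chains are seeded ``seed + chain_index`` so the whole set reproduces from
    one integer.  Observed cells are never altered; a dataset with no missing
    cells returns m identical copies.
    """
    if k_donors < 1:
        raise ValueError("k_donors must be >= 1")
    if m < 2:
        raise ValueError("m must be >= 2 for pooling")
    cycles, _ = ds.to_frames()
    for c in columns:
        if cycles[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing; inestimable")
    for p in predictors:
        if cycles[p].isna().any():
            raise ValueError(f"predictor column {p!r} has missing values")

    completed = []
    for chain in range(m):
        rng = np.random.default_rng(seed + chain)
        filled = _impute_once(cycles, columns, predictors, max_iter, k_donors, rng)
        out = ds.copy()
        for rec, (_, row) in zip(out.records, filled.iterrows()):
            for c in columns:
                setattr(rec, c, float(row[c]))
        out.provenance = (
            f"{ds.provenance} [imputed chain {chain}, seed {seed + chain}]".strip()
        )
        completed.append(out)
    return ImputationSet(
        datasets=completed, m=m, seed=seed, iterations=max_iter, columns=columns
    )


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine m point estimates and squared SEs by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and the same length")
    m = q.size
    if m < 2:
        raise ValueError("pooling requires m >= 2 estimates")
    if not (np.isfinite(q).all() and np.isfinite(v).all()):
        raise ValueError("estimates and variances must be finite")
    qbar = float(np.mean(q))
    w = float(np.mean(v))
    b = float(np.var(q, ddof=1))
    if b <= 1e-14 * max(1.0, qbar**2, w):  # identical estimates up to fp noise
        b = 0.0
    t_total = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = math.inf
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    return PooledEstimate(qbar=qbar, w=w, b=b, t_total=t_total, df=df, m=m)
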