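"""Derived harvest traits and fixed-effect design matrices.

Phenotype tables are pandas DataFrames with one row per animal and the
columns ``sample_id``, ``generation``, ``sex``, ``age`` plus raw
measurements (whole weight, soft tissue weight, shell weight, shell
depth/width/length, CIELab colour channels).  Derived traits:

* condition index  = soft tissue weight * 100 / (whole weight - shell weight)
* cup ratio        = shell width / shell depth
* fan ratio        = shell length / shell depth

The mixed models downstream adjust for generation, sex, their interaction
and a linear age covariate nested within generation; :func:`build_design`
constructs the corresponding full-rank incidence matrix with treatment
(reference-level) coding.  Heritabilities, genetic correlations and BLUP
predictions are invariant to the coding choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def condition_index(soft, whole, shell):
    """Meat-yield index: soft * 100 / (whole - shell).

    Undefined when whole <= shell; those entries return NaN with a warning.
    Accepts scalars or arrays.
    """
    soft = np.asarray(soft, float)
    whole = np.asarray(whole, float)
    shell = np.asarray(shell, float)
    denom = whole - shell
    bad = denom <= 0
    if np.any(bad & ~np.isnan(denom)):
        warnings.warn("condition_index undefined where whole weight <= shell "
                      "weight; returning missing", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, soft * 100.0 / denom)
    return float(out) if out.ndim == 0 else out


def cup_ratio(width, depth):
    """Shell width / shell depth; NaN (with a warning) for depth <= 0."""
    return _shape_ratio(width, depth, "cup_ratio")


def fan_ratio(length, depth):
    """Shell length / shell depth; NaN (with a warning) for depth <= 0."""
    return _shape_ratio(length, depth, "fan_ratio")


def _shape_ratio(num, depth, name):
    num = np.asarray(num, float)
    depth = np.asarray(depth, float)
    bad = depth <= 0
    if np.any(bad & ~np.isnan(depth)):
        warnings.warn(f"{name} undefined where shell depth <= 0; "
                      "returning missing", stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / depth)
    return float(out) if out.ndim == 0 else out


def derive_traits(pt: pd.DataFrame) -> pd.DataFrame:
    """Add condition_index / cup_ratio / fan_ratio columns where inputs exist."""
    out = pt.copy()
    if {"soft_tissue_weight", "whole_weight", "shell_weight"}.issubset(out.columns):
        out["condition_index"] = condition_index(
            out["soft_tissue_weight"], out["whole_weight"], out["shell_weight"])
    if {"shell_width", "shell_depth"}.issubset(out.columns):
        out["cup_ratio"] = cup_ratio(out["shell_width"], out["shell_depth"])
    if {"shell_length", "shell_depth"}.issubset(out.columns):
        out["fan_ratio"] = fan_ratio(out["shell_length"], out["shell_depth"])
    return out


@dataclass
class DesignMatrix:
    """Response vector and full-rank fixed-effects matrix for one trait."""

    y: np.ndarray
    X: np.ndarray
    columns: list
    sample_ids: list
    trait: str = ""

    def __post_init__(self):
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("X shape inconsistent with y / column labels")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, rows) -> "DesignMatrix":
        rows = np.asarray(rows)
        return DesignMatrix(self.y[rows], self.X[rows, :], list(self.columns),
                            [self.sample_ids[i] for i in rows], self.trait)


def build_design(pt: pd.DataFrame, trait: str,
                 full_interactions: bool = False) -> DesignMatrix:
    """Fixed-effect design for an animal-model fit of one trait.

    Rows are restricted to animals with the trait observed.  Columns:
    intercept (the model's overall mean), treatment-coded generation and
    sex factors, generation x sex interaction, and one age column per
    generation (age centered within generation, i.e. nested).  With
    ``full_interactions`` the sex x age interaction is added as well.
    Rank-deficient columns are dropped (QR with pivoting) and logged.
    """
    if trait not in pt.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    obs = pt[pt[trait].notna()].reset_index(drop=True)
    if len(obs) == 0:
        raise ValueError(f"trait {trait!r} is entirely missing")
    if len(obs) < 2:
        raise ValueError(f"trait {trait!r} has fewer than 2 observations")

    y = obs[trait].to_numpy(float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(obs))}

    gen_dummies = _factor_dummies(obs, "generation", "gen")
    sex_dummies = _factor_dummies(obs, "sex", "sex")
    cols.update(gen_dummies)
    cols.update(sex_dummies)
    for gname, gcol in gen_dummies.items():
        for sname, scol in sex_dummies.items():
            cols[f"{gname}:{sname}"] = gcol * scol

    if "age" in obs.columns and obs["age"].notna().all():
        # age centered within generation, one slope per generation
        gen_levels = sorted(obs["generation"].unique()) if "generation" in obs.columns else [None]
        for lev in gen_levels:
            mask = np.ones(len(obs), bool) if lev is None else (obs["generation"] == lev).to_numpy()
            centered = np.zeros(len(obs))
            centered[mask] = obs.loc[mask, "age"].to_numpy(float) - obs.loc[mask, "age"].mean()
            cols[f"age:gen{lev}" if lev is not None else "age"] = centered
        if full_interactions:
            for sname, scol in sex_dummies.items():
                age_all = obs["age"].to_numpy(float) - obs["age"].mean()
                cols[f"age:{sname}"] = age_all * scol

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    X, names = _drop_rank_deficient(X, names)
    return DesignMatrix(y, X, names, [str(s) for s in obs["sample_id"]], trait)


def _factor_dummies(obs: pd.DataFrame, col: str, prefix: str) -> dict:
    if col not in obs.columns:
        return {}
    levels = sorted(obs[col].astype(str).unique())
    if len(levels) < 2:
        warnings.warn(f"factor {col!r} has a single level and is absorbed "
                      "into the intercept", stacklevel=3)
        return {}
    vals = obs[col].astype(str).to_numpy()
    return {f"{prefix}{lev}": (vals == lev).astype(float) for lev in levels[1:]}


def _drop_rank_deficient(X: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    _, R, piv = _qr_pivot(X)
    tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps if R.size else 0.0
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        logger.info("build_design dropped rank-deficient columns: %s", dropped)
        X = X[:, keep]
        names = [names[i] for i in keep]
    return X, names


def _qr_pivot(X):
    from scipy.linalg import qr
    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, np.atleast_2d(R), piv
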