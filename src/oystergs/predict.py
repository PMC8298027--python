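"""GBLUP / pedigree BLUP: mixed-model equations, allele substitution
effects, phenotype prediction and replicated k-fold cross-validation.

Henderson's mixed-model equations for y = X b + Z g + e with
g ~ N(0, K sa2), e ~ N(0, I se2) and lambda = se2/sa2:

    [ X'X      X'Z          ] [ b ]   [ X'y ]
    [ Z'X   Z'Z + K^-1 λ    ] [ g ] = [ Z'y ]

Every sample present in K receives a genetic value, including animals whose
phenotype is masked (their rows are simply absent from y/Z) — this is how
cross-validation predicts held-out animals while keeping their genotypes in
the relationship matrix.

For a genomic K the marker effects (allele substitution effects, ASE) are
recovered by back-solving alpha = D M' G^-1 g_hat, where D is the marker
weight used to build G, so that M alpha reproduces g_hat exactly when G is
full rank; predictions for new genotypes follow y_hat = X b_hat + M alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve

from .kinship import (RelationshipMatrix, centered_genotypes, grm_vanraden,
                      nrm)
from .pedigree import Pedigree
from .qc import GenotypeMatrix
from .reml import REMLOptions, VarianceComponents, reml_univariate
from .traits import DesignMatrix

logger = logging.getLogger(__name__)


@dataclass
class BreedingValueSet:
    """Solutions of one mixed-model fit."""

    beta: np.ndarray               # fixed-effect solutions
    beta_labels: list
    g_hat: pd.Series               # genetic value per sample id in K
    kinship_kind: str
    vc: VarianceComponents
    ase: np.ndarray | None = None  # per-marker allele substitution effects
    ase_offset: float = 0.0        # mean genetic value carried by no marker
    marker_ids: list | None = None
    freqs: np.ndarray | None = None  # frequencies used to center M


@dataclass
class CVResult:
    method: str
    k: int
    replicates: int
    seed: int
    records: pd.DataFrame          # replicate, fold, sample_id, y_obs, y_pred
    r2_per_replicate: np.ndarray
    r_per_replicate: np.ndarray
    r2_per_fold: pd.DataFrame      # replicate, fold, r2, r

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_replicate))

    @property
    def r_mean(self) -> float:
        return float(np.mean(self.r_per_replicate))

    @property
    def r2_best_fold(self) -> float:
        return float(self.r2_per_fold["r2"].max())


def solve_mme(dm: DesignMatrix, K: RelationshipMatrix,
              vc: VarianceComponents) -> BreedingValueSet:
    """Solve Henderson's MME; genetic values for every sample in K."""
    if vc.sigma2_a[0] <= 0 or vc.sigma2_e[0] <= 0:
        raise ValueError("variance components must be positive")
    lam = vc.lambda_
    Kb = K.bent()
    try:
        cf = cho_factor(Kb.values, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("relationship matrix singular after bending") from exc
    Kinv = cho_solve(cf, np.eye(Kb.n))

    X, y = dm.X, dm.y
    n, p = X.shape
    cols = Kb.align(dm.sample_ids)
    Z = np.zeros((n, Kb.n))
    Z[np.arange(n), cols] = 1.0

    nk = Kb.n
    lhs = np.empty((p + nk, p + nk))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Z
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = Z.T @ Z + Kinv * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = solve(lhs, rhs, assume_a="sym")
    beta, g = sol[:p], sol[p:]
    return BreedingValueSet(beta=beta, beta_labels=list(dm.columns),
                            g_hat=pd.Series(g, index=list(Kb.sample_ids)),
                            kinship_kind=K.kind, vc=vc)


def backsolve_ase(bvs: BreedingValueSet, gm: GenotypeMatrix,
                  G: RelationshipMatrix) -> np.ndarray:
    """Back-solve per-marker allele substitution effects from genetic values.

    ``G`` must be the genomic matrix used in the fit and ``gm`` the imputed
    genotypes it was built from.  Centering M by the sample frequencies
    makes G singular along the all-ones direction, so the mean genetic
    value cannot be carried by any marker: it is returned separately as
    ``bvs.ase_offset`` (to be added to the fixed part at prediction time),
    and alpha satisfies M alpha + offset = g_hat up to the rank of G (any
    further reconstruction error is logged).
    """
    if not G.kind.startswith("G"):
        raise ValueError("ASE back-solving requires a genomic relationship matrix")
    if list(gm.sample_ids) != list(G.sample_ids):
        raise ValueError("genotype samples do not match the G matrix")
    M, p = centered_genotypes(gm, G.freqs)
    if G.kind == "G_vanraden":
        weights = np.full(gm.n_markers, 1.0 / G.scale)
    else:  # per-marker standardized G: G = M diag(w) M'
        het = 2.0 * p * (1.0 - p)
        m_poly = int(np.sum(het > 0))
        with np.errstate(divide="ignore"):
            weights = np.where(het > 0, 1.0 / (m_poly * het), 0.0)
    ghat = bvs.g_hat.loc[list(G.sample_ids)].to_numpy()
    offset = float(ghat.mean())
    Ginv = np.linalg.pinv(G.values, hermitian=True, rcond=1e-10)
    alpha = weights * (M.T @ (Ginv @ (ghat - offset)))
    recon = np.linalg.norm(M @ alpha + offset - ghat)
    scale = np.linalg.norm(ghat) + 1e-30
    if recon / scale > 1e-6:
        logger.info("ASE reconstruction error %.2e (relative) — G is rank "
                    "deficient beyond the centering null space", recon / scale)
    bvs.ase = alpha
    bvs.ase_offset = offset
    bvs.marker_ids = list(gm.marker_ids)
    bvs.freqs = p
    return alpha


def predict_phenotypes(X_new: np.ndarray, beta: np.ndarray,
                       M_new: np.ndarray, alpha: np.ndarray,
                       offset: float = 0.0) -> np.ndarray:
    """y_hat = X_new beta + M_new alpha + offset.

    ``M_new`` must be centered with the *training* allele frequencies
    (see :func:`oystergs.kinship.centered_genotypes`); ``offset`` is the
    mean genetic value returned by :func:`backsolve_ase`.
    """
    M_new = np.atleast_2d(M_new)
    if M_new.shape[1] != len(alpha):
        raise ValueError(f"marker mismatch: M_new has {M_new.shape[1]} "
                         f"markers, alpha has {len(alpha)}")
    return (np.asarray(X_new) @ np.asarray(beta)
            + M_new @ np.asarray(alpha) + offset)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(n: int, k: int, rng: np.random.Generator) -> list:
    """Random partition of range(n) into k near-equal folds.

    Fold sizes differ by at most one (e.g. 647 into 5 gives
    130/130/129/129/129).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 3:
        raise ValueError(f"fold with fewer than 3 samples (n={n}, k={k}); "
                         "use a smaller k")
    return folds


def _resolve_kinship(source, method: str) -> RelationshipMatrix:
    if isinstance(source, RelationshipMatrix):
        return source
    if isinstance(source, GenotypeMatrix):
        if method != "gblup":
            raise ValueError("genotypes supplied but method is not gblup")
        return grm_vanraden(source)
    if isinstance(source, Pedigree):
        if method != "ablup":
            raise ValueError("pedigree supplied but method is not ablup")
        return nrm(source)
    raise TypeError(f"cannot build a relationship matrix from {type(source)}")


def _fit_fold(dm, train_rows, val_rows, K, reml_options, strict_exclusion):
    """One CV fold: re-estimate variances on training, predict validation."""
    train_dm = dm.subset(train_rows)
    # drop fixed-effect columns unobserved in training (level only in the fold)
    active = np.ptp(train_dm.X, axis=0) > 0
    active[np.array(train_dm.columns) == "intercept"] = True
    if not active.all():
        warnings.warn("fixed-effect level absent from the training fold; "
                      "predicted at the reference level", stacklevel=2)
    train_fit = DesignMatrix(train_dm.y, train_dm.X[:, active],
                             [c for c, a in zip(train_dm.columns, active) if a],
                             train_dm.sample_ids, train_dm.trait)
    K_fit = K.subset(sorted(set(train_fit.sample_ids),
                            key=list(K.sample_ids).index)) if strict_exclusion else K
    vc = reml_univariate(train_fit, K_fit, reml_options)
    bvs = solve_mme(train_fit, K_fit, vc)

    val_ids = [dm.sample_ids[i] for i in val_rows]
    if strict_exclusion:
        # conditional expectation of validation genetic values given training
        idx_t = K.align(list(K_fit.sample_ids))
        idx_v = K.align(val_ids)
        Ktt = K.values[np.ix_(idx_t, idx_t)]
        Kvt = K.values[np.ix_(idx_v, idx_t)]
        gt = bvs.g_hat.loc[list(K_fit.sample_ids)].to_numpy()
        g_val = Kvt @ np.linalg.solve(Ktt + 1e-8 * np.eye(len(idx_t)), gt)
    else:
        g_val = bvs.g_hat.loc[val_ids].to_numpy()

    beta_full = np.zeros(len(dm.columns))
    beta_full[active] = bvs.beta
    y_pred = dm.X[val_rows, :] @ beta_full + g_val
    return val_ids, dm.y[val_rows], y_pred


def cross_validate(dm: DesignMatrix, source, method: str = "gblup",
                   k: int = 5, replicates: int = 5, seed: int = 0,
                   reml_options: REMLOptions | None = None,
                   strict_exclusion: bool = False) -> CVResult:
    """Replicated k-fold cross-validated predictive ability.

    ``source`` is a genotype matrix (gblup), a pedigree (ablup) or a
    pre-built relationship matrix.  Per replicate the phenotyped samples
    are randomly partitioned into k folds; per fold the variance components
    are re-estimated on the training records, the MME solved with the
    held-out phenotypes removed (held-out animals stay in the relationship
    matrix unless ``strict_exclusion``), and the fold predicted.  The
    headline metric is the coefficient of determination R^2 of the
    regression of observed on predicted phenotypes, pooled per replicate
    and averaged; per-fold values support a best-fold summary.
    """
    K = _resolve_kinship(source, method)
    n = dm.n
    rows_rec, rows_fold = [], []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        for fold_i, fold in enumerate(make_folds(n, k, rng)):
            train_rows = np.setdiff1d(np.arange(n), fold)
            ids, y_obs, y_pred = _fit_fold(dm, train_rows, fold, K,
                                           reml_options, strict_exclusion)
            for s, yo, yp in zip(ids, y_obs, y_pred):
                rows_rec.append((rep, fold_i, s, yo, yp))
            rows_fold.append((rep, fold_i, *_r2(y_obs, y_pred)))
    records = pd.DataFrame(rows_rec, columns=["replicate", "fold", "sample_id",
                                              "y_obs", "y_pred"])
    per_fold = pd.DataFrame(rows_fold, columns=["replicate", "fold", "r2", "r"])
    r2_rep, r_rep = [], []
    for rep, grp in records.groupby("replicate"):
        r2, r = _r2(grp["y_obs"].to_numpy(), grp["y_pred"].to_numpy())
        r2_rep.append(r2)
        r_rep.append(r)
    return CVResult(method=method, k=k, replicates=replicates, seed=seed,
                    records=records, r2_per_replicate=np.array(r2_rep),
                    r_per_replicate=np.array(r_rep), r2_per_fold=per_fold)


def _r2(y_obs, y_pred):
    """(R^2, r) of the regression of observed on predicted.

    For simple linear regression the coefficient of determination equals
    the squared Pearson correlation.
    """
    if np.std(y_pred) == 0 or np.std(y_obs) == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(y_obs, y_pred)[0, 1])
    return r * r, r
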