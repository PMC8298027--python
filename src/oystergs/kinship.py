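"""Genomic and pedigree relationship matrices.

Two genomic relationship matrices (GRMs) are provided:

* VanRaden: G = M M' / sum_j 2 p_j q_j, with M the genotype matrix
  column-centered by twice the allele frequency.  A single scaling constant
  is shared by all markers.
* GCTA-style: the per-marker standardized average
  G_ik = mean_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j q_j),
  which weights every marker equally regardless of frequency.

The pedigree numerator relationship matrix A is computed by the tabular
(recursive) method: A_ii = 1 + 0.5 A_{sire,dam}, A_ij = 0.5 (A_{j,sire(i)}
+ A_{j,dam(i)}), so the diagonal is 1 + F with F the inbreeding coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .qc import GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)

#: eigenvalue threshold below which a relationship matrix gets bent
PSD_TOL = 1e-8
#: ridge added to the diagonal when bending
PSD_RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    kind: str                      # "G_vanraden" | "G_gcta" | "A"
    values: np.ndarray             # n x n symmetric
    sample_ids: list
    scale: float | None = None     # sum_j 2 p_j q_j for G_vanraden
    freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def align(self, sample_ids) -> np.ndarray:
        """Row/column indices of the given sample ids in this matrix."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in relationship matrix: {missing[:5]}")
        return np.array([pos[s] for s in sample_ids])

    def subset(self, sample_ids) -> "RelationshipMatrix":
        idx = self.align(sample_ids)
        return RelationshipMatrix(self.kind, self.values[np.ix_(idx, idx)],
                                  list(sample_ids), self.scale, self.freqs)

    def bent(self) -> "RelationshipMatrix":
        """Return a positive-definite copy (small diagonal ridge if needed)."""
        w = np.linalg.eigvalsh(self.values)
        if w.min() >= PSD_TOL:
            return self
        ridge = PSD_RIDGE + max(0.0, -w.min())
        logger.info("bending %s matrix: min eigenvalue %.3g, adding %.3g to "
                    "the diagonal", self.kind, w.min(), ridge)
        return RelationshipMatrix(self.kind, self.values + ridge * np.eye(self.n),
                                  list(self.sample_ids), self.scale, self.freqs)

    def write(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path)

    @classmethod
    def read(cls, path, kind: str = "G_vanraden") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(kind, df.to_numpy(float), [str(s) for s in df.index])


def centered_genotypes(gm: GenotypeMatrix, freqs: np.ndarray | None = None):
    """(M, p): genotype matrix column-centered by 2p and the frequencies used.

    Frequencies default to the observed sample frequencies; pass training
    frequencies explicitly when centering validation animals.
    """
    p = allele_frequencies(gm) if freqs is None else np.asarray(freqs, float)
    return gm.calls - 2.0 * p, p


def grm_vanraden(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden GRM: G = MM' / sum(2 p q) with M centered by 2p."""
    if np.isnan(gm.calls).any():
        raise ValueError("GRM requires imputed (no-missing) genotypes")
    M, p = centered_genotypes(gm, freqs)
    scale = float(np.sum(2.0 * p * (1.0 - p)))
    if scale == 0:
        raise ValueError("all markers monomorphic: sum(2pq) = 0")
    G = (M @ M.T) / scale
    return RelationshipMatrix("G_vanraden", G, list(gm.sample_ids), scale, p)


def grm_gcta(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """Per-marker standardized GRM (equal marker weights).

    Monomorphic markers (p in {0,1}) cannot be standardized and are
    excluded with a log entry.
    """
    if np.isnan(gm.calls).any():
        raise ValueError("GRM requires imputed (no-missing) genotypes")
    M, p = centered_genotypes(gm, freqs)
    het = 2.0 * p * (1.0 - p)
    keep = het > 0
    if not keep.all():
        logger.info("grm_gcta: excluding %d monomorphic markers",
                    int(np.sum(~keep)))
    if not keep.any():
        raise ValueError("all markers monomorphic")
    Z = M[:, keep] / np.sqrt(het[keep])
    G = (Z @ Z.T) / int(keep.sum())
    return RelationshipMatrix("G_gcta", G, list(gm.sample_ids), None, p)


def nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    The pedigree is topologically sorted internally; the output rows follow
    the original pedigree order.  Unknown parents (0) contribute nothing.
    """
    ped = pedigree.sorted()
    ids = list(ped.ids)
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = ped.df["sire"].to_numpy()
    dams = ped.df["dam"].to_numpy()
    for k in range(n):
        s = pos.get(sires[k], -1)
        d = pos.get(dams[k], -1)
        if s >= 0 and d >= 0:
            A[k, k] = 1.0 + 0.5 * A[s, d]
            A[k, :k] = A[:k, k] = 0.5 * (A[:k, s] + A[:k, d])
        elif s >= 0 or d >= 0:
            par = max(s, d)
            A[k, k] = 1.0
            A[k, :k] = A[:k, k] = 0.5 * A[:k, par]
        else:
            A[k, k] = 1.0
    # restore the caller's ordering
    order = [pos[i] for i in pedigree.ids]
    A = A[np.ix_(order, order)]
    return RelationshipMatrix("A", A, [str(i) for i in pedigree.ids])
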