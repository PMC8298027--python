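"""Genotype matrices, quality control and format conversion.

Genotypes are stored as counts of the alternate allele (0, 1, 2) with
``numpy.nan`` marking missing calls.  The quality-control pipeline applied
here mirrors standard SNP-array practice for reduced-representation
genotyping: drop markers whose call rate falls below a threshold, then
replace the remaining missing calls with the per-marker mean ("mean
imputation"), which preserves marker means and hence allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens in CSV matrices interpreted as a missing call
MISSING_TOKENS = {"NA", "na", "-", "", "nan", "NaN", "./.", "."}


@dataclass
class GenotypeMatrix:
    """Samples x markers table of alternate-allele counts.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered labels for rows and columns of ``calls``.
    calls
        Float array of shape ``(n_samples, n_markers)`` with values in
        ``[0, 2]`` or ``nan`` for missing.  After mean imputation calls
        may be fractional.
    imputed
        True once missing calls have been replaced by marker means.
    """

    sample_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)
    calls: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    imputed: bool = False

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def call_rates(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return np.mean(~np.isnan(self.calls), axis=0)

    def copy(self) -> "GenotypeMatrix":
        return replace(self, calls=self.calls.copy(),
                       sample_ids=list(self.sample_ids),
                       marker_ids=list(self.marker_ids))

    def subset(self, sample_ids=None, markers=None) -> "GenotypeMatrix":
        """Restrict to the given sample ids (by label) and/or marker indices."""
        gm = self
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(gm.sample_ids)}
            rows = [pos[s] for s in sample_ids]
            gm = GenotypeMatrix(list(sample_ids), list(gm.marker_ids),
                                gm.calls[rows, :], gm.imputed)
        if markers is not None:
            markers = np.asarray(markers)
            gm = GenotypeMatrix(list(gm.sample_ids),
                                [gm.marker_ids[j] for j in markers],
                                gm.calls[:, markers], gm.imputed)
        return gm


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker alternate-allele frequency p_j from non-missing calls.

    p_j = (sum of calls at marker j) / (2 x number of non-missing calls).
    Mean imputation does not change p_j because the imputed value is the
    marker mean.
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(gm.calls, axis=0) / 2.0


def call_rate_filter(gm: GenotypeMatrix, threshold: float = 0.5) -> GenotypeMatrix:
    """Retain markers whose call rate is >= ``threshold`` (inclusive).

    The inclusive boundary means a marker genotyped in exactly half of the
    samples survives a 0.5 threshold.  Marker order is preserved.  Removing
    every marker returns an empty matrix with a warning rather than raising.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    keep = gm.call_rates() >= threshold
    n_out = int(np.sum(~keep))
    logger.info("call_rate_filter: %d markers in, %d removed, %d retained",
                gm.n_markers, n_out, gm.n_markers - n_out)
    if not keep.any():
        logger.warning("call_rate_filter removed every marker")
    return GenotypeMatrix(list(gm.sample_ids),
                          [m for m, k in zip(gm.marker_ids, keep) if k],
                          gm.calls[:, keep], gm.imputed)


def sample_call_rate_filter(gm: GenotypeMatrix, threshold: float = 0.5) -> GenotypeMatrix:
    """Optional per-sample analogue of :func:`call_rate_filter`."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rates = np.mean(~np.isnan(gm.calls), axis=1) if gm.n_markers else np.zeros(gm.n_samples)
    keep = rates >= threshold
    return GenotypeMatrix([s for s, k in zip(gm.sample_ids, keep) if k],
                          list(gm.marker_ids), gm.calls[keep, :], gm.imputed)


def impute_mean(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by that marker's mean of observed calls.

    Raises if any marker has no observed calls (run
    :func:`call_rate_filter` first).
    """
    calls = gm.calls.copy()
    n_obs = np.sum(~np.isnan(calls), axis=0)
    if np.any(n_obs == 0):
        bad = [gm.marker_ids[j] for j in np.flatnonzero(n_obs == 0)[:5]]
        raise ValueError(
            f"markers with zero non-missing calls (e.g. {bad}); "
            "apply call_rate_filter before imputation"
        )
    means = np.nanmean(calls, axis=0)
    miss = np.isnan(calls)
    calls[miss] = np.broadcast_to(means, calls.shape)[miss]
    return GenotypeMatrix(list(gm.sample_ids), list(gm.marker_ids), calls, imputed=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "csv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix from a CSV table or a VCF.

    CSV dialect: first column holds sample ids, the header row holds marker
    ids.  Tokens in :data:`MISSING_TOKENS` (and anything unparseable) map to
    missing; unrecognized tokens are counted and logged.

    VCF dialect: diploid GT fields 0/0, 0/1, 1/1 and ./. map to 0, 1, 2 and
    missing; samples are VCF columns, markers are records.
    """
    if dialect == "csv_matrix":
        return _read_csv_matrix(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty genotype file: {path}")
    stripped = df.apply(lambda c: c.str.strip())
    numeric = stripped.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    calls = numeric.to_numpy(float)
    known_missing = stripped.isin(MISSING_TOKENS).to_numpy()
    n_bad = int((np.isnan(calls) & ~known_missing).sum())
    if n_bad:
        logger.warning("read_genotypes: %d unrecognized tokens mapped to missing", n_bad)
    imputed = bool(np.any((calls % 1 != 0) & ~np.isnan(calls)))
    return GenotypeMatrix([str(s) for s in df.index],
                          [str(m) for m in df.columns], calls, imputed=imputed)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF has no samples: {path}")
    marker_ids, cols = [], []
    for var in vcf:
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        col = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        cols.append(col)
    vcf.close()
    if not marker_ids:
        raise ValueError(f"empty VCF: {path}")
    return GenotypeMatrix(samples, marker_ids, np.column_stack(cols))


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the sample x marker CSV dialect read by :func:`read_genotypes`."""
    df = pd.DataFrame(gm.calls, index=gm.sample_ids, columns=gm.marker_ids)
    df.to_csv(path, na_rep="NA")


def to_vcf(gm: GenotypeMatrix, path) -> None:
    """Write hard calls as a minimal VCF 4.2 (GT-only FORMAT).

    DArT-style tags are unplaced, so each marker gets a synthetic contig
    named after the marker with POS=1.  Imputed (fractional) calls cannot be
    represented as hard genotypes and raise an error.
    """
    calls = gm.calls
    frac = (calls % 1 != 0) & ~np.isnan(calls)
    if gm.imputed or np.any(frac):
        raise ValueError("to_vcf requires un-imputed hard calls in {0,1,2,missing}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for mk in gm.marker_ids:
            fh.write(f"##contig=<ID={mk}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.sample_ids) + "\n")
        for j, mk in enumerate(gm.marker_ids):
            gts = ["./." if np.isnan(c) else gt_map[int(c)] for c in calls[:, j]]
            fh.write(f"{mk}\t1\t{mk}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
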