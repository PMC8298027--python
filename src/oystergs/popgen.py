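"""Population structure: pairwise divergence, nucleotide diversity,
neighbor-joining trees and diversity-partitioned F_ST.

Divergence between two genotyped individuals is the allele-sharing
distance averaged over markers non-missing in both: 0 for identical
homozygotes, 0.5 for homozygote vs heterozygote, 1 for opposite
homozygotes.  Nucleotide diversity pi is the mean pairwise divergence per
assayed site (Nei-Li), and the fixation index partitions it:
F_ST = (pi_T - pi_S) / pi_T with pi_S the size-weighted mean within-cluster
diversity.

The neighbor-joining implementation is the Saitou-Nei agglomeration with
deterministic tie-breaking (smallest row/column index) and negative branch
lengths clamped to zero with the deficit transferred to the sister branch.
NJ is consistent on additive distance matrices: it returns the generating
tree exactly, which the tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .qc import GenotypeMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def write(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path)


@dataclass
class TreeNode:
    """Node of an (unrooted) NJ tree; the root is a trifurcation."""

    name: str | None = None
    length: float = 0.0            # branch to the parent
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"


def pairwise_divergence(gm: GenotypeMatrix, mode: str = "allele_share") -> DistanceMatrix:
    """All-pairs divergence over markers non-missing in both individuals.

    ``allele_share`` (default): mean of |x_i - x_j| / 2 per shared site.
    ``site_diff_count``: raw count of sites with differing genotypes.
    Raises if any pair shares no genotyped marker.
    """
    X = gm.calls
    n = gm.n_samples
    D = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(X[i + 1:] - X[i])           # nan where either missing
        shared = np.sum(~np.isnan(diff), axis=1)
        if np.any(shared == 0):
            j = i + 1 + int(np.argmax(shared == 0))
            raise ValueError(f"samples {gm.sample_ids[i]!r} and "
                             f"{gm.sample_ids[j]!r} share no genotyped marker")
        if mode == "allele_share":
            d = np.nanmean(diff, axis=1) / 2.0
        elif mode == "site_diff_count":
            d = np.nansum(diff > 0, axis=1).astype(float)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        D[i, i + 1:] = D[i + 1:, i] = d
    return DistanceMatrix(D, list(gm.sample_ids))


def nucleotide_diversity(gm: GenotypeMatrix, subset=None,
                         sites_per_tag: float | None = None) -> float:
    """Mean pairwise divergence over all unordered pairs (Nei-Li pi).

    By default pi is per assayed SNP site; pass ``sites_per_tag`` (e.g. the
    sequenced tag length) to rescale to a per-tag-base diversity.
    """
    if subset is not None:
        gm = gm.subset(sample_ids=list(subset))
    if gm.n_samples < 2:
        raise ValueError("nucleotide diversity needs at least 2 individuals")
    D = pairwise_divergence(gm).values
    iu = np.triu_indices(gm.n_samples, 1)
    pi = float(np.mean(D[iu]))
    if sites_per_tag:
        pi /= sites_per_tag
    return pi


def fst_from_diversity(pi_total: float, pi_within, sizes=None) -> float:
    """F_ST = (pi_T - pi_S) / pi_T, pi_S a size-weighted mean, clamped to [0,1]."""
    pi_within = np.asarray(pi_within, float)
    if sizes is None:
        sizes = np.ones_like(pi_within)
    sizes = np.asarray(sizes, float)
    if pi_total <= 0:
        warnings.warn("total diversity is zero; F_ST undefined", stacklevel=2)
        return np.nan
    pi_s = float(np.sum(sizes * pi_within) / np.sum(sizes))
    return float(np.clip((pi_total - pi_s) / pi_total, 0.0, 1.0))


@dataclass
class PopStructureResult:
    pi_total: float
    pi_within: dict           # cluster label -> pi
    cluster_sizes: dict
    clusters: pd.Series       # sample id -> cluster label
    fst: float


def population_structure(gm: GenotypeMatrix, clusters: pd.Series) -> PopStructureResult:
    """pi_T, per-cluster pi and F_ST for a given cluster assignment.

    Clusters of a single individual contribute no within-cluster pairs and
    are excluded from pi_S (with their size).
    """
    pi_total = nucleotide_diversity(gm)
    pi_within, sizes = {}, {}
    for label in pd.unique(clusters):
        members = list(clusters.index[clusters == label])
        if len(members) >= 2:
            pi_within[label] = nucleotide_diversity(gm, subset=members)
            sizes[label] = len(members)
    fst = fst_from_diversity(pi_total, list(pi_within.values()),
                             list(sizes.values()))
    return PopStructureResult(pi_total, pi_within, sizes, clusters, fst)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcate root).

    Ties in the Q-criterion break on the smallest (row, column) index pair;
    negative branch lengths are clamped to zero with the length transferred
    to the sister branch, preserving the pair's summed length.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")
    D = dm.values.copy()
    nodes = [TreeNode(name=str(s)) for s in dm.sample_ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties resolved by lexicographically smallest (i, j)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def _clamp_pair(li, lj):
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def cut_tree_clusters(tree: TreeNode, n_clusters: int = 4) -> pd.Series:
    """Cut an NJ tree into clusters at its longest internal branches.

    Removing the (n_clusters - 1) longest internal edges partitions the
    leaves into connected components, labeled C1..Cn by first leaf order.
    """
    edges = []  # (length, child) — edge between child and its parent

    def walk(node):
        for ch in node.children:
            if not ch.is_leaf():
                edges.append((ch.length, ch))
            walk(ch)

    walk(tree)
    edges.sort(key=lambda e: -e[0])
    cut = {id(ch) for _, ch in edges[:max(0, n_clusters - 1)]}

    assignments: dict[str, int] = {}

    def collect(node, comp):
        for ch in node.children:
            c = comp
            if id(ch) in cut:
                c = len(components)
                components.append(c)
            if ch.is_leaf():
                assignments[ch.name] = c
            else:
                collect(ch, c)

    components = [0]
    collect(tree, 0)
    relabel = {}
    labels = {}
    for leaf in tree.leaves():
        comp = assignments[leaf.name]
        if comp not in relabel:
            relabel[comp] = f"C{len(relabel) + 1}"
        labels[leaf.name] = relabel[comp]
    return pd.Series(labels, name="cluster")


# ---------------------------------------------------------------------------
# study-design helpers
# ---------------------------------------------------------------------------

def select_unrelated(pedigree: Pedigree, n: int = 50, generation: int = 1,
                     seed: int = 0) -> list:
    """Sample ids with at most one individual per full-sib family.

    Used to remove the sibling signal before building a population tree.
    """
    fams = pedigree.families(generation=generation)
    if len(fams) < n:
        raise ValueError(f"only {len(fams)} families in generation "
                         f"{generation}; cannot select {n} unrelated individuals")
    rng = np.random.default_rng(seed)
    keys = sorted(fams)
    chosen_fams = rng.choice(len(keys), size=n, replace=False)
    out = []
    for fi in sorted(chosen_fams):
        members = fams[keys[fi]]
        out.append(str(members[rng.integers(len(members))]))
    return out


WEIGHT_BINS = [30.0, 40.0, 50.0, 60.0, 70.0]
WEIGHT_LABELS = ["I", "II", "III", "IV", "V"]


def weight_categories(whole_weight) -> pd.Series:
    """Whole-weight classes I: [30,40) ... IV: [60,70), V: >=70 g.

    Left-closed bins, so a 40 g animal falls in II.  Weights below 30 g are
    labeled 'unbinned' rather than guessed into class I.
    """
    w = pd.Series(np.asarray(whole_weight, float))
    cats = pd.cut(w, bins=WEIGHT_BINS + [np.inf], right=False,
                  labels=WEIGHT_LABELS)
    out = cats.astype(object)
    out[w < WEIGHT_BINS[0]] = "unbinned"
    out[w.isna()] = np.nan
    return out
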