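"""Synthetic two-generation oyster breeding population with known truth.

The generator emulates the structure of a family-based shellfish breeding
program: a base of unrelated founders produces a first generation of
full-sib families (one sire x one dam each), and a second generation whose
parents are drawn from distinct first-generation families.  Genotypes are
produced by gene dropping (founders at Hardy-Weinberg equilibrium, Mendelian
transmission down the pedigree) and multi-trait phenotypes follow the
additive model

    y = mean + fixed effects + M alpha + e,

with marker effects drawn i.i.d. normal per trait, correlated across traits
through a genetic correlation matrix, and the genetic column rescaled so the
realized additive variance equals h2 * sigma_p^2 exactly.  True breeding
values are kept alongside the phenotypes so downstream estimators can be
checked against the truth.

Defaults mirror the target population: 57 first-generation families of 2-8
offspring, 33 second-generation families of 12-15 offspring (~650 phenotyped
animals), ~13,000 biallelic markers, per-trait heritabilities between 0.14
and 0.77, and a whole-weight/soft-tissue genetic correlation of 0.63.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .qc import GenotypeMatrix

_PED_STREAM, _GENO_STREAM, _PHENO_STREAM = 11, 13, 17


@dataclass
class TraitSpec:
    """One simulated trait: heritability, scale and fixed-effect profile.

    ``sigma_p`` is the phenotypic SD in trait units; fixed effects are
    expressed in trait units too.  ``age_slope`` holds one linear
    coefficient per generation (age nested within generation).
    """

    name: str
    h2_true: float
    sigma_p: float
    mean: float = 0.0
    gen2_effect: float = 0.0
    sex_effect: float = 0.0
    interaction_effect: float = 0.0
    age_slope: tuple = (0.0, 0.0)  # per generation (gen1, gen2)
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0 < self.h2_true < 1:
            raise ValueError(f"h2_true must be in (0,1), got {self.h2_true}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")


def default_traits() -> list[TraitSpec]:
    """The eleven harvest traits of the emulated program.

    Means/SDs are phenotypic summaries of the target population; missing
    rates reproduce per-trait sample sizes out of 647 animals; h2 values
    span the program's reported range (0.14-0.77).  Fixed effects default to
    moderate fractions of sigma_p.
    """
    rows = [
        # name, mean, sd, h2, n_observed (of 647)
        ("whole_weight", 51.07, 16.13, 0.45, 647),
        ("cup_ratio", 1.61, 0.33, 0.24, 361),
        ("fan_ratio", 2.93, 0.72, 0.33, 361),
        ("soft_tissue_weight", 9.55, 3.13, 0.43, 490),
        ("condition_index", 67.78, 21.65, 0.77, 284),
        ("shell_a", 2.35, 3.71, 0.14, 306),
        ("shell_b", 11.58, 4.25, 0.26, 306),
        ("shell_L", 23.63, 12.30, 0.34, 306),
        ("mantle_a", 4.40, 3.46, 0.54, 448),
        ("mantle_b", 10.11, 4.01, 0.49, 448),
        ("mantle_L", 24.21, 8.73, 0.34, 448),
    ]
    specs = []
    for name, mean, sd, h2, n in rows:
        specs.append(TraitSpec(
            name=name, h2_true=h2, sigma_p=sd, mean=mean,
            gen2_effect=0.3 * sd, sex_effect=0.1 * sd,
            interaction_effect=0.05 * sd,
            age_slope=(0.01 * sd, 0.015 * sd),
            missing_rate=round(1.0 - n / 647.0, 4),
        ))
    return specs


def default_genetic_correlations(traits: list[TraitSpec]) -> np.ndarray:
    """Genetic correlation matrix anchored on whole weight.

    Only the correlations of each trait with whole weight are specified by
    the emulated program; the matrix is completed with the single-factor
    structure R[i,j] = c_i * c_j (i, j != anchor), which is positive
    semi-definite by construction for any |c| <= 1.
    """
    anchor_rg = {
        "whole_weight": 1.0, "cup_ratio": 0.14, "fan_ratio": 0.08,
        "soft_tissue_weight": 0.63, "condition_index": 0.18,
        "shell_a": -0.13, "shell_b": -0.02, "shell_L": 0.34,
        "mantle_a": -0.13, "mantle_b": -0.14, "mantle_L": 0.14,
    }
    c = np.array([anchor_rg.get(t.name, 0.0) for t in traits])
    R = np.outer(c, c)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class SimulationConfig:
    families_gen1: int = 57
    offspring_gen1: tuple = (2, 8)
    families_gen2: int = 33
    offspring_gen2: tuple = (12, 15)
    n_markers: int = 13048
    founder_freq_law: tuple = ("uniform", 0.05, 0.5)
    traits: list = field(default_factory=default_traits)
    genetic_corr: np.ndarray | None = None   # default: single-factor anchor
    residual_corr: np.ndarray | None = None  # default: identity
    age_mean: float = 270.0   # days of grow-out to harvest
    age_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("families_gen1", "families_gen2", "n_markers"):
            if getattr(self, name) < 0 or (name != "families_gen2" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for rng_name in ("offspring_gen1", "offspring_gen2"):
            lo, hi = getattr(self, rng_name)
            if lo > hi or lo < 1:
                raise ValueError(f"empty offspring range {rng_name}={lo}-{hi}")
        if self.genetic_corr is None:
            self.genetic_corr = default_genetic_correlations(self.traits)
        if self.residual_corr is None:
            self.residual_corr = np.eye(len(self.traits))
        for label, R in (("genetic", self.genetic_corr), ("residual", self.residual_corr)):
            R = np.asarray(R, float)
            if R.shape != (len(self.traits),) * 2:
                raise ValueError(f"{label} correlation matrix shape {R.shape} "
                                 f"does not match {len(self.traits)} traits")
            _check_correlation(R, label)

    def founder_frequencies(self, rng: np.random.Generator) -> np.ndarray:
        law = self.founder_freq_law
        if isinstance(law, (tuple, list)) and law and law[0] == "uniform":
            p = rng.uniform(law[1], law[2], size=self.n_markers)
        elif isinstance(law, (tuple, list)) and law and law[0] == "fixed":
            p = np.full(self.n_markers, float(law[1]))
        else:
            p = np.asarray(law, float)
            if p.shape != (self.n_markers,):
                raise ValueError("founder frequency array length != n_markers")
        return p


def _check_correlation(R: np.ndarray, label: str) -> None:
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{label} correlation matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{label} correlation matrix diagonal is not 1")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ValueError(f"{label} correlation matrix is not positive "
                         f"semi-definite (eigenvalue {w.min():.3g})")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def make_pedigree(config: SimulationConfig) -> Pedigree:
    """Two-generation full-sib pedigree over fresh unrelated founders.

    Generation 1: one new sire x one new dam per family.  Generation 2:
    sire and dam sampled from generation-1 individuals of *different*
    families, each individual used as a parent at most once.
    """
    rng = np.random.default_rng([_PED_STREAM, config.seed])
    rows = []
    next_id = 1

    gen1_by_family: list[list[int]] = []
    for _ in range(config.families_gen1):
        sire, dam = next_id, next_id + 1
        next_id += 2
        rows.append((sire, 0, 0, 0))
        rows.append((dam, 0, 0, 0))
        lo, hi = config.offspring_gen1
        fam = []
        for _ in range(int(rng.integers(lo, hi + 1))):
            rows.append((next_id, sire, dam, 1))
            fam.append(next_id)
            next_id += 1
        gen1_by_family.append(fam)

    if config.families_gen2 > 0:
        if config.families_gen1 < 2:
            raise ValueError("impossible mating structure: need at least two "
                             "generation-1 families to mate generation 2")
        family_of = {i: f for f, fam in enumerate(gen1_by_family) for i in fam}
        pool = [i for fam in gen1_by_family for i in fam]
        for _ in range(config.families_gen2):
            if len(pool) < 2 or len({family_of[i] for i in pool}) < 2:
                raise ValueError("impossible mating structure: generation-1 "
                                 "parent pool exhausted")
            sire = int(pool[rng.integers(len(pool))])
            pool.remove(sire)
            candidates = [i for i in pool if family_of[i] != family_of[sire]]
            dam = int(candidates[rng.integers(len(candidates))])
            pool.remove(dam)
            lo, hi = config.offspring_gen2
            for _ in range(int(rng.integers(lo, hi + 1))):
                rows.append((next_id, sire, dam, 2))
                next_id += 1

    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Gene dropping: HWE founders, one allele from each parent per locus.

    Loci are unlinked (independent transmission).  Returns hard calls in
    {0, 1, 2} for every individual in the pedigree.
    """
    rng = np.random.default_rng([_GENO_STREAM, config.seed])
    p = config.founder_frequencies(rng)
    if np.any(p <= 0) or np.any(p >= 1):
        # monomorphic founders are allowed only via an explicit fixed law
        if not (isinstance(config.founder_freq_law, (tuple, list))
                and config.founder_freq_law[0] == "fixed"):
            raise ValueError("founder frequencies must lie in (0,1)")

    ped = pedigree.sorted()
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    m = config.n_markers
    calls = np.empty((len(ids), m), dtype=np.int8)

    for k, row in enumerate(ped.df.itertuples(index=False)):
        if row.sire == 0 and row.dam == 0:
            calls[k] = rng.binomial(2, p)
        elif row.sire == 0 or row.dam == 0:
            raise ValueError(f"id {row.id}: one known and one unknown parent "
                             "is not supported by gene dropping")
        else:
            gs = calls[pos[row.sire]]
            gd = calls[pos[row.dam]]
            calls[k] = ((rng.random(m) < gs / 2.0).astype(np.int8)
                        + (rng.random(m) < gd / 2.0).astype(np.int8))

    return GenotypeMatrix([str(i) for i in ids],
                          [f"snp{j + 1}" for j in range(m)],
                          calls.astype(float))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(gm: GenotypeMatrix, pedigree: Pedigree,
                        config: SimulationConfig) -> pd.DataFrame:
    """Multi-trait phenotypes for generation-1 and -2 individuals.

    Returns a table with sample_id, generation, sex, age, one column per
    trait (with per-trait missingness applied) and one ``tbv_<trait>``
    column holding the true breeding value of every animal.

    Marker effects are drawn i.i.d. normal and correlated across traits by
    the Cholesky factor of the genetic correlation matrix; each trait's
    effect scale is set so that, given the realized marker matrix, the
    expected sample variance of the genetic values equals h2 * sigma_p^2
    (the realized variance then fluctuates across replicates exactly as the
    additive model assumes).  Residuals are correlated by the residual
    correlation matrix at population scale (1 - h2) * sigma_p^2.
    """
    rng = np.random.default_rng([_PHENO_STREAM, config.seed])
    traits = config.traits
    T = len(traits)
    Rg = np.asarray(config.genetic_corr, float)
    Re = np.asarray(config.residual_corr, float)
    _check_correlation(Rg, "genetic")
    _check_correlation(Re, "residual")

    cohort = pedigree.df[pedigree.df.generation.isin([1, 2])]
    sample_ids = [str(i) for i in cohort["id"]]
    gm_cohort = gm.subset(sample_ids=sample_ids)
    n, m = gm_cohort.n_samples, gm_cohort.n_markers

    # centered marker matrix for the genetic values
    p_hat = np.nanmean(gm_cohort.calls, axis=0) / 2.0
    M = gm_cohort.calls - 2.0 * p_hat

    Lg = _psd_cholesky(Rg)
    alpha = rng.standard_normal((m, T)) @ Lg.T
    # sample variance of M alpha given M: E = sigma_alpha^2 tr(MM')/(n-1)
    # (columns of M are centered, so M alpha has exactly zero mean)
    tr_mm = float(np.sum(M * M))
    if tr_mm == 0:
        raise ValueError("degenerate genetic values (monomorphic markers?)")
    target_sd = np.array([np.sqrt(t.h2_true) * t.sigma_p for t in traits])
    g = (M @ alpha) * (target_sd * np.sqrt((n - 1) / tr_mm))

    Le = _psd_cholesky(Re)
    e = rng.standard_normal((n, T)) @ Le.T
    e *= np.array([np.sqrt(1.0 - t.h2_true) * t.sigma_p for t in traits])

    generation = cohort["generation"].to_numpy()
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    out = pd.DataFrame({"sample_id": sample_ids, "generation": generation,
                        "sex": sex, "age": age})
    is_g2 = (generation == 2).astype(float)
    is_m = (sex == "M").astype(float)
    for t_idx, t in enumerate(traits):
        slope = np.where(generation == 2, t.age_slope[1], t.age_slope[0])
        fixed = (t.mean + t.gen2_effect * is_g2 + t.sex_effect * is_m
                 + t.interaction_effect * is_g2 * is_m
                 + slope * (age - config.age_mean))
        y = fixed + g[:, t_idx] + e[:, t_idx]
        if t.missing_rate > 0:
            y = np.where(rng.random(n) < t.missing_rate, np.nan, y)
        out[t.name] = y
        out[f"tbv_{t.name}"] = g[:, t_idx]
    return out


def _psd_cholesky(R: np.ndarray) -> np.ndarray:
    """Cholesky-like factor that tolerates semi-definite correlation matrices."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass
class SimulatedDataset:
    """Bundle of one simulation draw: pedigree, cohort genotypes, phenotypes."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix  # generation-1 and -2 individuals only
    phenotypes: pd.DataFrame
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Run the three stages and restrict genotypes to the phenotyped cohort."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    ped = make_pedigree(config)
    gm_all = simulate_genotypes(ped, config)
    pheno = simulate_phenotypes(gm_all, ped, config)
    gm = gm_all.subset(sample_ids=list(pheno["sample_id"]))
    return SimulatedDataset(ped, gm, pheno, config)
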