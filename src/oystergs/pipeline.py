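"""End-to-end genomic-evaluation runs: simulate (or load) -> QC ->
relationship matrices -> REML -> cross-validation -> population structure.

A run writes five report files into its output directory:

* ``phenotype_summary.csv`` — n / mean / SD / min / max per trait
* ``heritability.csv``      — h2 (SE) per trait and genetic correlation
                              (SE) with the anchor trait
* ``cv_accuracy.csv``       — cross-validated R^2, GBLUP vs pedigree BLUP
* ``scatter_<trait>.csv``   — observed vs predicted pairs for plotting
* ``tree.nwk`` + ``popgen.json`` — NJ tree, clusters, pi and F_ST

plus ``manifest.json`` recording the config, seed and package version, and
``run.log`` with per-stage wall times.  Report numbers are rounded to two
decimals; full precision stays in the machine-readable CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinship import grm_gcta, grm_vanraden, nrm
from .pedigree import Pedigree
from .popgen import (cut_tree_clusters, neighbor_joining, pairwise_divergence,
                     population_structure, select_unrelated, weight_categories)
from .predict import cross_validate
from .qc import call_rate_filter, impute_mean, read_genotypes
from .reml import REMLOptions, genetic_correlation, heritability, \
    reml_bivariate, reml_univariate
from .simulate import SimulationConfig, simulate_dataset
from .traits import build_design

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    # either simulate ...
    simulation: SimulationConfig | None = None
    # ... or load from files
    genotypes: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    traits: list | None = None           # default: every simulated trait
    anchor_trait: str = "whole_weight"   # genetic correlations against this
    kinship_method: str = "vanraden"     # or "gcta"
    call_rate: float = 0.5
    cv_k: int = 5
    cv_replicates: int = 5
    scatter_trait: str | None = None     # default: anchor trait
    popgen_n_unrelated: int = 50
    popgen_generation: int = 1
    popgen_clusters: int = 4
    run_popgen: bool = True
    run_cv: bool = True
    run_bivariate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("offspring_gen1", "offspring_gen2"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def summarize_phenotypes(pt: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait n (non-missing), mean, sample SD, min and max."""
    if traits is None:
        skip = {"sample_id", "generation", "sex", "age"}
        traits = [c for c in pt.columns
                  if c not in skip and not str(c).startswith("tbv_")
                  and pd.api.types.is_numeric_dtype(pt[c])]
    if not traits:
        raise ValueError("no traits to summarize")
    rows = []
    for t in traits:
        v = pt[t].dropna()
        if len(v) == 0:
            rows.append((t, 0, np.nan, np.nan, np.nan, np.nan))
        else:
            rows.append((t, len(v), v.mean(), v.std(ddof=1), v.min(), v.max()))
    return pd.DataFrame(rows, columns=["trait", "n", "mean", "sd", "min", "max"])


class _Stage:
    """Context manager that logs wall time and names the failing stage."""

    def __init__(self, name, log_path):
        self.name = name
        self.log_path = log_path

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        with open(self.log_path, "a") as fh:
            status = "FAILED" if exc else "ok"
            fh.write(f"{self.name}\t{status}\t{dt:.2f}s\n")
        if exc:
            raise RuntimeError(
                f"pipeline stage {self.name!r} failed; completed stages are "
                f"checkpointed in {Path(self.log_path).parent}") from exc
        return False


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_path.write_text("")

    with _Stage("data", log_path):
        if cfg.simulation is not None or not (cfg.genotypes and cfg.phenotypes):
            sim_cfg = cfg.simulation or SimulationConfig()
            sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
            ds = simulate_dataset(sim_cfg)
            ped, gm_raw, pheno = ds.pedigree, ds.genotypes, ds.phenotypes
        else:
            gm_raw = read_genotypes(cfg.genotypes,
                                    "vcf" if str(cfg.genotypes).endswith(".vcf")
                                    else "csv_matrix")
            pheno = pd.read_csv(cfg.phenotypes)
            pheno["sample_id"] = pheno["sample_id"].astype(str)
            ped = Pedigree.read(cfg.pedigree) if cfg.pedigree else None
        trait_names = cfg.traits or [c for c in pheno.columns
                                     if c not in ("sample_id", "generation",
                                                  "sex", "age")
                                     and not str(c).startswith("tbv_")]

    with _Stage("qc", log_path):
        gm = call_rate_filter(gm_raw, cfg.call_rate)
        gm_imp = impute_mean(gm)

    with _Stage("summary", log_path):
        summary = summarize_phenotypes(pheno, trait_names)
        summary.to_csv(outdir / "phenotype_summary.csv", index=False,
                       float_format="%.2f")

    with _Stage("kinship", log_path):
        grm = grm_vanraden(gm_imp) if cfg.kinship_method == "vanraden" \
            else grm_gcta(gm_imp)
        A = nrm(ped) if ped is not None else None

    reml_opts = REMLOptions()
    with _Stage("reml", log_path):
        rows = []
        anchor = cfg.anchor_trait if cfg.anchor_trait in trait_names else trait_names[0]
        dm_anchor = build_design(pheno, anchor)
        for t in trait_names:
            dm = build_design(pheno, t)
            vc = reml_univariate(dm, grm, reml_opts)
            h2, h2_se = heritability(vc)
            rg = rg_se = np.nan
            if cfg.run_bivariate and t != anchor:
                vc2 = reml_bivariate(dm_anchor, dm, grm, reml_opts)
                rg, rg_se = genetic_correlation(vc2)
            rows.append((t, vc.kinship_kind, vc.sigma2_a[0], vc.sigma2_e[0],
                         h2, h2_se, rg, rg_se, vc.loglik, vc.n_iter,
                         vc.converged))
        h2_table = pd.DataFrame(rows, columns=[
            "trait", "kinship", "sigma2_a", "sigma2_e", "h2", "h2_se",
            f"rg_{anchor}", "rg_se", "loglik", "iterations", "converged"])
        h2_table.to_csv(outdir / "heritability_full.csv", index=False)
        h2_table.round(2).to_csv(outdir / "heritability.csv", index=False)

    if cfg.run_cv:
        with _Stage("cv", log_path):
            rows = []
            scatter_trait = cfg.scatter_trait or anchor
            for t in trait_names:
                dm = build_design(pheno, t)
                res_g = cross_validate(dm, grm, "gblup", cfg.cv_k,
                                       cfg.cv_replicates, cfg.seed, reml_opts)
                entry = {"trait": t, "gblup_r2": res_g.r2_mean,
                         "gblup_r": res_g.r_mean,
                         "gblup_r2_best_fold": res_g.r2_best_fold}
                if A is not None:
                    res_a = cross_validate(dm, A, "ablup", cfg.cv_k,
                                           cfg.cv_replicates, cfg.seed,
                                           reml_opts)
                    entry.update(ablup_r2=res_a.r2_mean, ablup_r=res_a.r_mean,
                                 ablup_r2_best_fold=res_a.r2_best_fold)
                rows.append(entry)
                if t == scatter_trait:
                    res_g.records.to_csv(outdir / f"scatter_{t}.csv",
                                         index=False)
            cv_table = pd.DataFrame(rows)
            cv_table.to_csv(outdir / "cv_accuracy_full.csv", index=False)
            cv_table.round(2).to_csv(outdir / "cv_accuracy.csv", index=False)

    if cfg.run_popgen and ped is not None:
        with _Stage("popgen", log_path):
            n_fam = len(ped.families(generation=cfg.popgen_generation))
            n_sel = min(cfg.popgen_n_unrelated, n_fam)
            ids = select_unrelated(ped, n=n_sel,
                                   generation=cfg.popgen_generation,
                                   seed=cfg.seed)
            gm_sel = gm.subset(sample_ids=ids)
            dmat = pairwise_divergence(gm_sel)
            tree = neighbor_joining(dmat)
            (outdir / "tree.nwk").write_text(tree.newick() + "\n")
            clusters = cut_tree_clusters(tree, cfg.popgen_clusters)
            res = population_structure(gm_sel, clusters)
            pheno_idx = pheno.set_index("sample_id")
            cats = {}
            if "whole_weight" in pheno.columns:
                ww = pheno_idx.reindex(ids)["whole_weight"]
                cats = {i: (None if pd.isna(c) else str(c))
                        for i, c in zip(ids, weight_categories(ww.to_numpy()))}
            payload = {
                "pi_total": res.pi_total,
                "pi_within": {str(k): v for k, v in res.pi_within.items()},
                "cluster_sizes": {str(k): v for k, v in res.cluster_sizes.items()},
                "fst": res.fst,
                "clusters": {str(k): str(v) for k, v in clusters.items()},
                "weight_categories": cats,
            }
            (outdir / "popgen.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n")

    with _Stage("manifest", log_path):
        manifest = {
            "package": "oystergs",
            "version": __version__,
            "seed": cfg.seed,
            "config": _jsonable(cfg),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
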