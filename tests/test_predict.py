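"""Mixed-model equations, ASE back-solving and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from oystergs.kinship import (RelationshipMatrix, centered_genotypes,
                              grm_vanraden, nrm)
from oystergs.predict import (_r2, backsolve_ase, cross_validate, make_folds,
                              predict_phenotypes, solve_mme)
from oystergs.qc import GenotypeMatrix
from oystergs.reml import VarianceComponents, reml_univariate
from oystergs.traits import DesignMatrix, build_design


def _vc(sa, se):
    return VarianceComponents(["t"], "A", np.array([sa]), np.array([se]))


def _dm(y, X=None, ids=None):
    y = np.asarray(y, float)
    X = np.ones((len(y), 1)) if X is None else np.asarray(X, float)
    ids = ids or [f"s{i}" for i in range(len(y))]
    return DesignMatrix(y, X, [f"c{j}" for j in range(X.shape[1])], ids, "t")


class TestSolveMME:
    def test_two_records_one_individual_closed_form(self):
        # both records on the same animal: the mean absorbs everything,
        # the MME reduce to lambda * g = 0
        K = RelationshipMatrix("A", np.eye(1), ["s0"])
        dm = _dm([4.0, 6.0], ids=["s0", "s0"])
        bvs = solve_mme(dm, K, _vc(1.0, 1.0))
        assert bvs.beta[0] == pytest.approx(5.0)
        assert bvs.g_hat["s0"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_gls_oracle_small_n(self, rng):
        """MME solutions equal direct V^-1 GLS on n <= 30."""
        n = 25
        L = rng.normal(size=(n, n)) / np.sqrt(n)
        K = L @ L.T + np.eye(n)
        ids = [f"s{i}" for i in range(n)]
        Krm = RelationshipMatrix("G_vanraden", K, ids)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        dm = DesignMatrix(y, X, ["int", "x"], ids, "t")
        sa, se = 2.0, 3.0
        bvs = solve_mme(dm, Krm, _vc(sa, se))
        V = sa * K + se * np.eye(n)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        g = sa * K @ Vinv @ (y - X @ beta)
        np.testing.assert_allclose(bvs.beta, beta, atol=1e-8)
        np.testing.assert_allclose(bvs.g_hat.to_numpy(), g, atol=1e-8)

    def test_complete_shrinkage_as_lambda_grows(self, small_ds):
        dm = build_design(small_ds.phenotypes, "t1")
        G = grm_vanraden(small_ds.genotypes)
        bvs = solve_mme(dm, G, _vc(1e-8, 1.0))
        assert np.max(np.abs(bvs.g_hat.to_numpy())) < 1e-4

    def test_unphenotyped_animals_receive_genetic_values(self, small_ds):
        dm = build_design(small_ds.phenotypes, "t1")
        sub = dm.subset(np.arange(dm.n - 10))
        G = grm_vanraden(small_ds.genotypes)
        vc = reml_univariate(sub, G)
        bvs = solve_mme(sub, G, vc)
        left_out = dm.sample_ids[-10:]
        assert np.all(np.isfinite(bvs.g_hat.loc[left_out]))

    def test_gblup_with_pedigree_matrix_equals_ablup(self, small_ds):
        dm = build_design(small_ds.phenotypes, "t1")
        A = nrm(small_ds.pedigree)
        vc = reml_univariate(dm, A)
        as_g = RelationshipMatrix("G_vanraden", A.values,
                                  list(A.sample_ids))
        b1 = solve_mme(dm, A, vc)
        b2 = solve_mme(dm, as_g, vc)
        np.testing.assert_allclose(b1.g_hat.to_numpy(),
                                   b2.g_hat.to_numpy(), atol=1e-8)


class TestASE:
    def test_reconstruction_identity(self, small_ds):
        from oystergs.qc import impute_mean
        gm = impute_mean(small_ds.genotypes)
        G = grm_vanraden(gm)
        dm = build_design(small_ds.phenotypes, "t1")
        vc = reml_univariate(dm, G)
        bvs = solve_mme(dm, G, vc)
        alpha = backsolve_ase(bvs, gm, G)
        M, _ = centered_genotypes(gm, G.freqs)
        ghat = bvs.g_hat.loc[list(G.sample_ids)].to_numpy()
        err = np.linalg.norm(M @ alpha + bvs.ase_offset - ghat) \
            / np.linalg.norm(ghat)
        assert err < 1e-6

    def test_zero_genetic_values_zero_effects(self, small_ds):
        from oystergs.qc import impute_mean
        gm = impute_mean(small_ds.genotypes)
        G = grm_vanraden(gm)
        bvs = solve_mme(build_design(small_ds.phenotypes, "t1"), G,
                        _vc(1.0, 1.0))
        bvs.g_hat[:] = 0.0
        alpha = backsolve_ase(bvs, gm, G)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)

    def test_single_marker_two_individuals_scalar_algebra(self):
        gm = GenotypeMatrix(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        G = grm_vanraden(gm)
        ghat = pd.Series([-1.5, 1.5], index=["a", "b"])
        bvs = type("B", (), {})()
        bvs.g_hat = ghat
        alpha = backsolve_ase(bvs, gm, G)
        # alpha = difference in g over difference in genotype
        assert alpha[0] == pytest.approx((1.5 - (-1.5)) / 2.0, rel=1e-3)

    def test_ase_route_equals_mme_route_for_validation(self, small_ds):
        """For animals in G with masked phenotypes, X beta + M alpha equals
        the MME genetic-value prediction."""
        from oystergs.qc import impute_mean
        gm = impute_mean(small_ds.genotypes)
        G = grm_vanraden(gm)
        dm = build_design(small_ds.phenotypes, "t1")
        train = np.arange(dm.n - 15)
        val = np.arange(dm.n - 15, dm.n)
        sub = dm.subset(train)
        vc = reml_univariate(sub, G)
        bvs = solve_mme(sub, G, vc)
        alpha = backsolve_ase(bvs, gm, G)
        val_ids = [dm.sample_ids[i] for i in val]
        M, _ = centered_genotypes(gm.subset(sample_ids=val_ids), G.freqs)
        y_ase = predict_phenotypes(dm.X[val], bvs.beta, M, alpha,
                                   bvs.ase_offset)
        y_mme = dm.X[val] @ bvs.beta + bvs.g_hat.loc[val_ids].to_numpy()
        np.testing.assert_allclose(y_ase, y_mme, rtol=1e-6, atol=1e-6)

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError, match="marker mismatch"):
            predict_phenotypes(np.ones((2, 1)), np.array([1.0]),
                               np.zeros((2, 3)), np.zeros(2))


class TestCrossValidation:
    def test_fold_sizes_647(self):
        folds = make_folds(647, 5, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [129, 129, 129, 130, 130]
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(647))

    def test_perfect_predictions_give_unit_r2(self, rng):
        y = rng.normal(size=50)
        r2, r = _r2(y, y.copy())
        assert r2 == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_too_small_folds_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(10, 5, np.random.default_rng(0))

    def test_fold_reproducibility_and_replicate_variation(self):
        rng1 = np.random.default_rng([7, 0])
        rng2 = np.random.default_rng([7, 0])
        rng3 = np.random.default_rng([7, 1])
        f1 = make_folds(100, 5, rng1)
        f2 = make_folds(100, 5, rng2)
        f3 = make_folds(100, 5, rng3)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        assert any(not np.array_equal(a, b) for a, b in zip(f1, f3))

    def test_gblup_cv_runs_and_is_reproducible(self, small_ds):
        dm = build_design(small_ds.phenotypes, "t1")
        G = grm_vanraden(small_ds.genotypes)
        res1 = cross_validate(dm, G, "gblup", k=4, replicates=2, seed=3)
        res2 = cross_validate(dm, G, "gblup", k=4, replicates=2, seed=3)
        assert res1.r2_mean == pytest.approx(res2.r2_mean)
        assert 0.0 <= res1.r2_mean <= 1.0
        assert len(res1.records) == 2 * dm.n
        # folds partition the samples within each replicate
        counts = res1.records.groupby("replicate")["sample_id"].nunique()
        assert (counts == dm.n).all()

    def test_strict_exclusion_mode(self, small_ds):
        dm = build_design(small_ds.phenotypes, "t1")
        G = grm_vanraden(small_ds.genotypes)
        res = cross_validate(dm, G, "gblup", k=4, replicates=1, seed=3,
                             strict_exclusion=True)
        assert np.isfinite(res.r2_mean)
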