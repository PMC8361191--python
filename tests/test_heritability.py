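import numpy as np
import pandas as pd
import pytest

from oracles import dense_reml_oracle, dense_restricted_loglik

from scfc.datatypes import PhenotypeTable
from scfc.heritability import (
    ACEModel,
    VarianceComponents,
    expansion_matrix,
    heritability,
    kinship_matrix,
    regional_heritability,
    reml_fit,
    shared_env_matrix,
)
from scfc.simulate import (
    FamilyComposition,
    TrueVariances,
    generate_covariates,
    generate_pedigree,
    simulate_ace_phenotypes,
    simulate_regional_traits,
)


def _stack(pedigree, phen, column="trait", standardize=True):
    K = kinship_matrix(pedigree)
    L = shared_env_matrix(pedigree)
    T = expansion_matrix(phen, subject_order=pedigree.subject_ids)
    y = phen.table[column].to_numpy(dtype=float)
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
    X = np.ones((y.size, 1))
    return y, X, K, L, T


class TestPedigreeMatrices:
    def test_mz_pair_entry_one(self):
        ped = generate_pedigree(FamilyComposition(1, 0, 0, 0), seed=0)
        K = kinship_matrix(ped)
        assert K[0, 1] == 1.0 and K[0, 0] == 1.0

    def test_dz_pair_entry_half(self):
        ped = generate_pedigree(FamilyComposition(0, 1, 0, 0), seed=0)
        assert kinship_matrix(ped)[0, 1] == 0.5

    def test_siblings_entry_half_and_shared_env(self, tiny_pedigree):
        K = kinship_matrix(tiny_pedigree)
        L = shared_env_matrix(tiny_pedigree)
        idx = {s: i for i, s in enumerate(tiny_pedigree.subject_ids)}
        assert K[idx["s1"], idx["s2"]] == 0.5
        assert L[idx["s1"], idx["s3"]] == 1.0
        assert K[idx["s1"], idx["u1"]] == 0.0
        assert L[idx["m1a"], idx["u2"]] == 0.0

    def test_singletons_give_identity(self):
        ped = generate_pedigree(FamilyComposition(0, 0, 0, 2), seed=0)
        assert np.array_equal(kinship_matrix(ped), np.eye(2))
        assert np.array_equal(shared_env_matrix(ped), np.eye(2))

    def test_expansion_matrix_column_sums(self):
        rows = []
        for sid, m in (("a", 2), ("b", 1), ("c", 4)):
            for j in range(m):
                rows.append({"subject_id": sid, "measurement_index": j + 1,
                             "trait": 0.0})
        phen = PhenotypeTable(pd.DataFrame(rows))
        T = expansion_matrix(phen)
        assert T.shape == (7, 3)
        assert T.sum(axis=0).tolist() == [2, 1, 4]
        assert (T.sum(axis=1) == 1).all()


class TestAssembledCovariance:
    def test_matches_component_sum_entrywise(self, tiny_pedigree):
        phen = simulate_ace_phenotypes(
            tiny_pedigree, TrueVariances(), n_measurements=3, seed=0
        )
        y, X, K, L, T = _stack(tiny_pedigree, phen)
        sig = np.array([0.37, 0.11, 0.29, 0.23])
        explicit = (
            sig[0] * T @ K @ T.T
            + sig[1] * T @ L @ T.T
            + sig[2] * T @ T.T
            + sig[3] * np.eye(y.size)
        )
        model = ACEModel(kinship=K, shared_env=L, expansion=T)
        blocks, *_ = model._structure()
        assembled = np.zeros_like(explicit)
        for b in blocks:
            V = sum(s * c for s, c in zip(sig, b.comps))
            for rows in b.row_idx:
                assembled[np.ix_(rows, rows)] = V
        assert np.array_equal(assembled, explicit)


class TestRemlFit:
    def test_matches_dense_oracle_on_tiny_pedigree(self):
        ped = generate_pedigree(FamilyComposition(2, 1, 0, 2), seed=1)
        phen = simulate_ace_phenotypes(
            ped, TrueVariances(0.5, 0.2, 0.3, 0.2), n_measurements=2, seed=2
        )
        y, X, K, L, T = _stack(ped, phen)
        vc = reml_fit(y, X, K, L, T)
        sig_oracle, ll_oracle = dense_reml_oracle(y, X, K, L, T)
        ours = np.array([vc.sigma2_A, vc.sigma2_C, vc.sigma2_E, vc.sigma2_M])
        assert np.allclose(ours, sig_oracle, atol=1e-4)
        assert vc.reml_loglik >= ll_oracle - 1e-6

    def test_loglik_at_estimate_beats_truth(self, tiny_pedigree):
        truth = TrueVariances(0.4, 0.2, 0.4, 0.25)
        phen = simulate_ace_phenotypes(
            tiny_pedigree, truth, n_measurements=4, seed=5
        )
        y, X, K, L, T = _stack(tiny_pedigree, phen, standardize=False)
        vc = reml_fit(y, X, K, L, T)
        ll_truth = dense_restricted_loglik(
            np.array([0.4, 0.2, 0.4, 0.25]), y, X, K, L, T
        )
        assert vc.reml_loglik >= ll_truth - 1e-6

    def test_constant_phenotype_flagged_degenerate(self, tiny_pedigree):
        phen = simulate_ace_phenotypes(
            tiny_pedigree, TrueVariances(0, 0, 0, 0), n_measurements=2, seed=0
        )
        y, X, K, L, T = _stack(tiny_pedigree, phen, standardize=False)
        vc = reml_fit(y, X, K, L, T)
        assert "degenerate_constant_phenotype" in vc.boundary_flags
        assert vc.sigma2_A == vc.sigma2_M == 0.0
        assert np.isnan(vc.h2)

    def test_subject_permutation_invariance(self):
        ped = generate_pedigree(FamilyComposition(2, 1, 5, 2), seed=3)
        phen = simulate_ace_phenotypes(
            ped, TrueVariances(0.5, 0.1, 0.3, 0.2), n_measurements=2, seed=4
        )
        y, X, K, L, T = _stack(ped, phen)
        vc = reml_fit(y, X, K, L, T)
        n = len(y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        subj_perm = rng.permutation(K.shape[0])
        vc2 = reml_fit(
            y[perm],
            X[perm],
            K[np.ix_(subj_perm, subj_perm)],
            L[np.ix_(subj_perm, subj_perm)],
            T[np.ix_(perm, subj_perm)],
        )
        for a, b in zip(
            (vc.sigma2_A, vc.sigma2_C, vc.sigma2_E, vc.sigma2_M),
            (vc2.sigma2_A, vc2.sigma2_C, vc2.sigma2_E, vc2.sigma2_M),
        ):
            assert a == pytest.approx(b, abs=2e-5)

    def test_all_singletons_flags_ace_inseparable(self):
        ped = generate_pedigree(FamilyComposition(0, 0, 0, 30), seed=0)
        truth = TrueVariances(0.0, 0.0, 0.7, 0.3)
        phen = simulate_ace_phenotypes(ped, truth, n_measurements=3, seed=1)
        y, X, K, L, T = _stack(ped, phen, standardize=False)
        vc = reml_fit(y, X, K, L, T)
        assert "ace_inseparable" in vc.identifiability_flags
        # the inter-subject total and the measurement error remain estimable
        total = vc.sigma2_A + vc.sigma2_C + vc.sigma2_E
        assert total == pytest.approx(0.7, abs=0.35)
        assert vc.sigma2_M == pytest.approx(0.3, abs=0.15)

    def test_only_mz_pairs_flags_a_c_inseparable(self):
        ped = generate_pedigree(FamilyComposition(10, 0, 0, 5), seed=0)
        phen = simulate_ace_phenotypes(
            ped, TrueVariances(0.4, 0.2, 0.3, 0.2), n_measurements=2, seed=2
        )
        y, X, K, L, T = _stack(ped, phen)
        vc = reml_fit(y, X, K, L, T)
        assert "a_c_inseparable" in vc.identifiability_flags

    def test_single_measurement_drops_m_with_warning(self, tiny_pedigree):
        phen = simulate_ace_phenotypes(
            tiny_pedigree, TrueVariances(), n_measurements=1, seed=0
        )
        y, X, K, L, T = _stack(tiny_pedigree, phen)
        with pytest.warns(UserWarning, match="single measurement"):
            vc = reml_fit(y, X, K, L, T)
        assert vc.sigma2_M == 0.0
        assert "measurement_error_dropped" in vc.identifiability_flags

    def test_h2_always_in_unit_interval(self):
        ped = generate_pedigree(FamilyComposition(3, 2, 6, 3), seed=7)
        for seed in range(4):
            phen = simulate_ace_phenotypes(
                ped, TrueVariances(0.1, 0.0, 0.8, 0.4), n_measurements=2,
                seed=seed,
            )
            y, X, K, L, T = _stack(ped, phen)
            vc = reml_fit(y, X, K, L, T)
            assert np.isnan(vc.h2) or 0.0 <= vc.h2 <= 1.0
            assert min(vc.sigma2_A, vc.sigma2_C, vc.sigma2_E, vc.sigma2_M) >= 0


class TestHeritabilityRatio:
    @pytest.mark.parametrize(
        "a, c, e, expected",
        [(0.0, 0.3, 0.7, 0.0), (0.5, 0.0, 0.0, 1.0), (0.4, 0.2, 0.4, 0.4)],
    )
    def test_ratio(self, a, c, e, expected):
        vc = VarianceComponents(a, c, e, 0.1, np.zeros(1), np.nan, 0.0, True)
        assert heritability(vc) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        vc = VarianceComponents(0, 0, 0, 0.1, np.zeros(1), np.nan, 0.0, True)
        assert np.isnan(heritability(vc))


class TestRegionalHeritability:
    def test_table_structure_and_skipping(self):
        ped = generate_pedigree(FamilyComposition(4, 2, 8, 4), seed=0)
        cov = generate_covariates(ped, seed=1)
        phen = simulate_regional_traits(
            ped, [TrueVariances(), TrueVariances(0.1, 0.1, 0.8, 0.3)],
            covariates=cov, n_measurements=2, seed=2,
        )
        t = phen.table.copy()
        t.loc[0, "region_000"] = np.nan  # this region must be skipped
        with pytest.warns(UserWarning, match="skipped"):
            res = regional_heritability(PhenotypeTable(t), cov, ped)
        assert res["region"].tolist() == ["region_001"]
        assert {"sigma2_A", "h2", "frac_M", "flags"} <= set(res.columns)

    def test_missing_covariate_named(self):
        ped = generate_pedigree(FamilyComposition(2, 1, 4, 2), seed=0)
        cov = generate_covariates(ped, seed=1)
        phen = simulate_regional_traits(
            ped, [TrueVariances()], covariates=cov, n_measurements=2, seed=2
        )
        with pytest.raises(ValueError, match="nonexistent"):
            regional_heritability(
                phen, cov, ped, covariates=("age", "nonexistent")
            )

    def test_extra_covariates_broadcast_and_used(self):
        ped = generate_pedigree(FamilyComposition(3, 2, 6, 3), seed=0)
        cov = generate_covariates(ped, seed=1)
        phen = simulate_regional_traits(
            ped, [TrueVariances()], covariates=cov, n_measurements=4, seed=2
        )
        strength = PhenotypeTable(
            pd.DataFrame(
                {
                    "subject_id": ped.subject_ids,
                    "measurement_index": 1,
                    "region_000": np.random.default_rng(3).normal(
                        size=ped.n_subjects
                    ),
                }
            )
        )
        res = regional_heritability(
            phen, cov, ped, extra_covariates={"sc_strength": strength}
        )
        assert len(res) == 1
        assert res["converged"].all()
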