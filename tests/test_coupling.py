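import numpy as np
import pytest

from oracles import coupling_oracle

from scfc.coupling import (
    average_fc,
    fisher_z,
    functional_connectivity,
    intra_hemisphere_coupling,
    network_restricted_coupling,
    node_strength,
    partial_coupling_distance,
    regional_coupling,
)
from scfc.datatypes import Connectome

from conftest import random_connectome_pair


def _sym(off_rows):
    """Build a symmetric matrix from a full square array by averaging."""
    m = np.asarray(off_rows, dtype=float)
    return (m + m.T) / 2


class TestFunctionalConnectivity:
    def test_identical_columns_correlate_to_one(self, rng):
        base = rng.normal(size=10)
        ts = np.column_stack([base, base, rng.normal(size=10)])
        fc = functional_connectivity(ts)
        assert fc.matrix[0, 1] == pytest.approx(1.0)

    def test_negated_column_correlates_to_minus_one(self, rng):
        base = rng.normal(size=10)
        ts = np.column_stack([base, -base, rng.normal(size=10)])
        fc = functional_connectivity(ts)
        assert fc.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_normalization(self, rng):
        ts = rng.normal(size=(5, 3))
        fc = functional_connectivity(ts).matrix
        c = ts - ts.mean(axis=0)
        cov = c.T @ c
        expected = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.allclose(fc, expected, atol=1e-12)

    def test_constant_column_names_region(self, rng):
        ts = rng.normal(size=(6, 3))
        ts[:, 1] = 2.0
        with pytest.raises(ValueError, match="1"):
            functional_connectivity(ts)


class TestRegionalCoupling:
    def test_monotone_transform_gives_one(self, rng):
        sc_vals = rng.lognormal(size=(6, 6))
        sc = Connectome(_sym(sc_vals), "SC")
        fc = Connectome(np.tanh(sc.matrix) * 0.99 + np.eye(6) * 0.01, "FC")
        cv = regional_coupling(sc, fc)
        assert np.allclose(cv.values, 1.0)

    def test_rank_example(self):
        # region 0's SC partners rank (3,1,4,2); FC values rank (2,1,4,3)
        # sum of squared rank differences = 2 -> rho = 1 - 12/60 = 0.8
        sc = np.zeros((5, 5))
        sc[0, 1:] = [0.3, 0.1, 0.4, 0.2]
        fc = np.zeros((5, 5))
        fc[0, 1:] = [0.2, 0.1, 0.4, 0.3]
        sc, fc = _sym(sc) * 2, _sym(fc) * 2
        np.fill_diagonal(fc, 1.0)
        cv = regional_coupling(Connectome(sc, "SC"), Connectome(fc, "FC"))
        assert cv.values[0] == pytest.approx(0.8, abs=1e-12)

    def test_rank_reversal_gives_minus_one(self, rng):
        sc_vals = _sym(rng.lognormal(size=(6, 6)))
        fc_vals = np.tanh(-sc_vals)
        np.fill_diagonal(fc_vals, 1.0)
        cv = regional_coupling(Connectome(sc_vals, "SC"), Connectome(fc_vals, "FC"))
        assert np.allclose(cv.values, -1.0)

    def test_all_zero_sc_row_flagged_undefined(self, rng):
        sc = _sym(rng.lognormal(size=(6, 6)))
        sc[0, :] = 0.0
        sc[:, 0] = 0.0
        fc = np.tanh(_sym(rng.normal(size=(6, 6))))
        np.fill_diagonal(fc, 1.0)
        cv = regional_coupling(Connectome(sc, "SC"), Connectome(fc, "FC"))
        assert np.isnan(cv.values[0])
        assert cv.defined[1:].all()

    def test_monotone_invariance_of_sc_row(self, rng):
        sc, fc = random_connectome_pair(10, rng)
        base = regional_coupling(sc, fc).values
        transformed = Connectome(np.exp(sc.matrix) - 1.0, "SC")
        assert np.allclose(
            regional_coupling(transformed, fc).values, base, atol=1e-12
        )


class TestVariants:
    def test_single_network_within_equals_whole_brain(self, rng, parc12):
        t = parc12.table.copy()
        t["network"] = "VIS"
        from scfc.datatypes import Parcellation

        parc_one = Parcellation(t)
        sc, fc = random_connectome_pair(12, rng)
        whole = regional_coupling(sc, fc).values
        within = network_restricted_coupling(sc, fc, parc_one, "within").values
        assert np.array_equal(within, whole)

    def test_region_alone_in_network_undefined(self, rng, parc12):
        t = parc12.table.copy()
        t.loc[0, "network"] = "LIM"  # region 0 becomes sole LIM member
        from scfc.datatypes import Parcellation

        parc = Parcellation(t)
        sc, fc = random_connectome_pair(12, rng)
        within = network_restricted_coupling(sc, fc, parc, "within")
        assert np.isnan(within.values[0])

    @pytest.mark.parametrize("mode", ["within", "between"])
    def test_network_restricted_matches_masked_oracle(self, rng, parc12, mode):
        sc, fc = random_connectome_pair(12, rng)
        nets = parc12.networks
        same = nets[:, None] == nets[None, :]
        masks = list(same if mode == "within" else ~same)
        expected = coupling_oracle(sc.matrix, fc.matrix, masks)
        got = network_restricted_coupling(sc, fc, parc12, mode).values
        assert np.allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_single_hemisphere_matches_masked_oracle(self, rng, parc12):
        sc, fc = random_connectome_pair(12, rng)
        hemi = parc12.hemispheres
        masks = list(hemi[:, None] == hemi[None, :])
        expected = coupling_oracle(sc.matrix, fc.matrix, masks)
        got = intra_hemisphere_coupling(sc, fc, parc12).values
        assert np.allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_all_one_hemisphere_equals_whole_brain(self, rng, parc12):
        t = parc12.table.copy()
        t["hemisphere"] = "left"
        from scfc.datatypes import Parcellation

        sc, fc = random_connectome_pair(12, rng)
        whole = regional_coupling(sc, fc).values
        got = intra_hemisphere_coupling(sc, fc, Parcellation(t)).values
        assert np.array_equal(got, whole)


class TestPartialDistance:
    def test_constant_distance_equals_plain_coupling(self, rng, parc12):
        t = parc12.table.copy()
        t[["x", "y", "z"]] = 0.0
        from scfc.datatypes import Parcellation

        parc = Parcellation(t)
        sc, fc = random_connectome_pair(12, rng)
        plain = regional_coupling(sc, fc).values
        with pytest.warns(UserWarning, match="constant"):
            partial = partial_coupling_distance(sc, fc, parc).values
        assert np.allclose(partial, plain, atol=0)

    def test_matches_partial_correlation_of_ranks_oracle(self, rng, parc12):
        import pandas as pd
        import pingouin as pg
        from scipy.stats import rankdata

        # make SC/FC distance-confounded so the adjustment matters
        d = np.sqrt(
            ((parc12.centroids[:, None] - parc12.centroids[None]) ** 2).sum(-1)
        )
        noise = _sym(rng.normal(size=(12, 12)))
        sc = np.exp(-d / 50 + 0.5 * noise)
        np.fill_diagonal(sc, 0.0)
        fc = np.tanh(np.exp(-d / 60) + 0.4 * _sym(rng.normal(size=(12, 12))))
        np.fill_diagonal(fc, 1.0)
        scc, fcc = Connectome(_sym(sc), "SC"), Connectome(_sym(fc), "FC")
        got = partial_coupling_distance(scc, fcc, parc12).values
        mask = ~np.eye(12, dtype=bool)
        for i in [0, 5, 11]:
            df = pd.DataFrame(
                {
                    "sc": scc.matrix[i, mask[i]],
                    "fc": fcc.matrix[i, mask[i]],
                    "d": d[i, mask[i]],
                }
            )
            expected = pg.partial_corr(
                df, x="sc", y="fc", covar="d", method="spearman"
            )["r"].iloc[0]
            assert got[i] == pytest.approx(expected, abs=1e-10)

    def test_orthogonal_residuals_give_zero(self):
        # SC ranks equal distance ranks -> residualizing SC on distance
        # leaves nothing; correlation with any FC residual is 0
        n = 8
        vals = np.arange(1.0, n)
        sc = np.zeros((n, n))
        sc[0, 1:] = vals
        sc = _sym(sc) * 2
        fc = np.zeros((n, n))
        fc[0, 1:] = np.array([0.1, -0.2, 0.3, -0.1, 0.2, 0.05, -0.3])
        fc = _sym(fc) * 2
        np.fill_diagonal(fc, 1.0)
        from scfc.datatypes import Parcellation
        import pandas as pd

        rows = [
            {
                "region_id": i,
                "label": f"r{i}",
                "hemisphere": "left",
                "network": "VIS",
                "x": float(i * 10.0),
                "y": 0.0,
                "z": 0.0,
            }
            for i in range(n)
        ]
        parc = Parcellation(pd.DataFrame(rows))
        got = partial_coupling_distance(
            Connectome(sc, "SC"), Connectome(fc, "FC"), parc
        )
        assert np.isnan(got.values[0]) or abs(got.values[0]) < 1e-10


class TestNodeStrength:
    def test_sc_row_sum_excludes_diagonal(self):
        m = _sym(np.array([[9, 0, 1], [0, 9, 2], [1, 2, 9]], float))
        assert node_strength(Connectome(m, "SC")).values[2] == pytest.approx(3.0)

    def test_fc_absolute_sum(self):
        m = np.array([[1.0, -0.5, 0.5], [-0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        ns = node_strength(Connectome(m, "FC"))
        assert ns.values[0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        sc, fc = random_connectome_pair(10, rng)
        for conn in (sc, fc):
            got = node_strength(conn).values
            expected = np.zeros(10)
            for i in range(10):
                for j in range(10):
                    if i != j:
                        expected[i] += (
                            abs(conn.matrix[i, j])
                            if conn.modality == "FC"
                            else conn.matrix[i, j]
                        )
            assert np.allclose(got, expected, rtol=1e-13, atol=1e-13)


class TestFisherZ:
    def test_values_and_symmetry(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(-0.5) == -fisher_z(0.5)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


def test_average_fc_is_entrywise_mean(rng):
    mats = [np.tanh(_sym(rng.normal(size=(5, 5)))) for _ in range(4)]
    for m in mats:
        np.fill_diagonal(m, 1.0)
    fcs = [Connectome(m, "FC") for m in mats]
    avg = average_fc(fcs)
    assert np.allclose(avg.matrix, np.mean(mats, axis=0), atol=1e-15)
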