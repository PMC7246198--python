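import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import phytoland as pl
from phytoland.network import (
    NetworkParams,
    detect_modules,
    export_network,
    find_modules,
    merge_modules,
    module_eigenvector,
    scale_free_fit,
    scale_free_r2,
    second_round,
    signed_adjacency,
    tom_dissimilarity,
)
from conftest import make_null_compound_matrix


def _factor_matrix(rng, n, blocks, rho):
    """Columns grouped in blocks sharing a latent factor (correlation rho)."""
    cols = []
    for size in blocks:
        z = rng.standard_normal(n)
        for _ in range(size):
            cols.append(np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n))
    return np.column_stack(cols)


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.03125)]
    )
    def test_closed_form_values(self, r, expected):
        cor = np.array([[1.0, r], [r, 1.0]])
        adj = signed_adjacency(cor, 5.0)
        assert adj[0, 1] == pytest.approx(expected)
        assert adj[0, 0] == 1.0

    def test_monotone_increasing_in_r(self):
        rs = np.linspace(-1, 1, 21)
        vals = [signed_adjacency(np.array([[1, r], [r, 1]]), 5.0)[0, 1] for r in rs]
        assert np.all(np.diff(vals) >= 0)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            signed_adjacency(np.array([[1.0, 0.5], [0.2, 1.0]]), 5.0)


class TestScaleFreeFit:
    def test_power_law_connectivity_fits_well(self):
        # construct a connectivity sequence straight from a power law
        rng = np.random.default_rng(0)
        k = (rng.pareto(2.0, size=2000) + 1.0) * 3.0
        assert scale_free_r2(k) >= 0.9

    def test_two_node_network_is_degenerate(self):
        cor = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = scale_free_fit(cor, [1, 2, 3])
        assert out["r_squared"].isna().all()

    def test_mean_connectivity_non_increasing_in_power(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 40))
        cor = np.corrcoef(x, rowvar=False)
        out = scale_free_fit(cor, [1, 2, 4, 6, 8])
        assert np.all(np.diff(out["mean_connectivity"]) <= 1e-12)


class TestTomDissimilarity:
    def test_three_node_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        d = tom_dissimilarity(a)
        # l = 0.25, k = 1: TOM = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert d[0, 1] == pytest.approx(0.5)
        assert np.all(np.diag(d) == 0)

    def test_exclusive_pair_has_perfect_overlap(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        d = tom_dissimilarity(a)
        assert d[0, 1] == pytest.approx(0.0)

    def test_edgeless_network_is_maximally_dissimilar(self):
        d = tom_dissimilarity(np.eye(4))
        off = d[~np.eye(4, dtype=bool)]
        assert np.all(off == 1.0)


class TestDetectModules:
    def test_two_separated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x = _factor_matrix(rng, 100, [10, 8], rho=0.95)
        cor = np.corrcoef(x, rowvar=False)
        d = tom_dissimilarity(signed_adjacency(cor, 5))
        labels = detect_modules(d, NetworkParams())
        truth = np.r_[np.zeros(10), np.ones(8)]
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(set(labels)) == 2 and 0 not in set(labels)

    def test_identical_compounds_form_one_module(self):
        n = 8
        d = np.zeros((n, n))
        labels = detect_modules(d, NetworkParams())
        assert set(labels) == {1}

    def test_independent_compounds_stay_unassigned(self):
        hits = 0
        for s in range(10):
            cm = make_null_compound_matrix(300 + s)
            cor = np.corrcoef(cm.zscores().to_numpy(), rowvar=False)
            d = tom_dissimilarity(signed_adjacency(cor, 5))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = detect_modules(d, NetworkParams())
            hits += int(np.all(labels == 0))
        assert hits >= 9

    def test_too_few_compounds_warns_and_unassigns(self):
        with pytest.warns(UserWarning, match="unassigned"):
            labels = detect_modules(np.zeros((3, 3)), NetworkParams(min_module_size=5))
        assert np.all(labels == 0)


class TestModuleEigenvector:
    def test_single_compound_module_is_its_zscore(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        e = module_eigenvector(x[:, None])
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(e, z, atol=1e-10)

    def test_identical_columns_give_shared_zscore_positive(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        e = module_eigenvector(np.column_stack([x, x, x]))
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(e, z, atol=1e-10)

    def test_two_compound_module_correlation_matches_pca_closed_form(self):
        # loading correlation for a 2x2 correlation matrix is sqrt((1+r)/2)
        rng = np.random.default_rng(6)
        n = 5000
        z = rng.standard_normal(n)
        r = 0.8
        x1 = np.sqrt(r) * z + np.sqrt(1 - r) * rng.standard_normal(n)
        x2 = np.sqrt(r) * z + np.sqrt(1 - r) * rng.standard_normal(n)
        e = module_eigenvector(np.column_stack([x1, x2]))
        for x in (x1, x2):
            assert np.corrcoef(e, x)[0, 1] >= 0.94

    def test_eigenvector_beats_any_member_as_summary(self):
        rng = np.random.default_rng(7)
        x = _factor_matrix(rng, 60, [6], rho=0.6)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        e = module_eigenvector(x)
        mean_cor_e = np.mean([abs(np.corrcoef(e, z[:, j])[0, 1]) for j in range(6)])
        for k in range(6):
            mean_cor_k = np.mean(
                [abs(np.corrcoef(z[:, k], z[:, j])[0, 1]) for j in range(6)]
            )
            assert mean_cor_e >= mean_cor_k - 1e-10


class TestMergeModules:
    def _assignment(self, ids_a, ids_b):
        return pd.Series(
            [1] * len(ids_a) + [2] * len(ids_b), index=ids_a + ids_b
        )

    def _correlated_blocks(self, cross):
        rng = np.random.default_rng(8)
        n = 2000
        shared = rng.standard_normal(n)
        blocks = []
        for _ in range(2):
            z = np.sqrt(cross) * shared + np.sqrt(1 - cross) * rng.standard_normal(n)
            blocks.append(
                np.column_stack(
                    [0.95 * z + 0.1 * rng.standard_normal(n) for _ in range(4)]
                )
            )
        cols = {f"a{j}": blocks[0][:, j] for j in range(4)}
        cols.update({f"b{j}": blocks[1][:, j] for j in range(4)})
        return pd.DataFrame(cols)

    def test_highly_correlated_modules_merge(self):
        z = self._correlated_blocks(cross=0.9)  # eigenvector cor ~0.9 > 0.75
        assign = self._assignment([f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)])
        merged = merge_modules(z, assign, merge_cut_height=0.25)
        assert merged.nunique() == 1

    def test_moderately_correlated_modules_stay_separate(self):
        z = self._correlated_blocks(cross=0.5)
        assign = self._assignment([f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)])
        merged = merge_modules(z, assign, merge_cut_height=0.25)
        assert merged.nunique() == 2

    def test_fixed_point_has_no_mergeable_pair(self, block_config):
        cm, _, _, _ = pl.generate(block_config, seed=0)
        sol = find_modules(cm)
        eig = sol.eigenvectors.to_numpy()
        if eig.shape[1] > 1:
            cor = np.corrcoef(eig, rowvar=False)
            np.fill_diagonal(cor, 0.0)
            assert cor.max() < 0.75


class TestSecondRound:
    def _hidden_block_matrix(self, seed=1, rho_hidden=0.45, n_noise=25, n_plants=45):
        rng = np.random.default_rng(seed)
        cols = {}
        zA = rng.standard_normal(n_plants)
        for j in range(12):
            cols[f"A{j}"] = np.sqrt(0.9) * zA + np.sqrt(0.1) * rng.standard_normal(n_plants)
        zB = rng.standard_normal(n_plants)
        for j in range(6):
            cols[f"B{j}"] = np.sqrt(rho_hidden) * zB + np.sqrt(1 - rho_hidden) * rng.standard_normal(n_plants)
        for j in range(n_noise):
            cols[f"N{j}"] = rng.standard_normal(n_plants)
        ab = np.exp(0.3 * pd.DataFrame(cols))
        ab.index = [f"P{i}" for i in range(n_plants)]
        return pl.CompoundMatrix(ab, pd.Series("OT", index=ab.columns))

    def test_orphaned_tight_block_recovered_in_round_two(self):
        cm = self._hidden_block_matrix()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = find_modules(cm)
        b_rounds = sol.round_of_assignment[[f"B{j}" for j in range(6)]]
        b_mods = sol.assignment[[f"B{j}" for j in range(6)]]
        assert (b_rounds == 2).sum() >= 5
        recovered = b_mods[b_rounds == 2]
        assert recovered.nunique() == 1  # one coherent new module

    def test_no_leftovers_is_a_noop(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame(
            (lambda x: (x - x.mean(0)) / x.std(0, ddof=1))(
                _factor_matrix(rng, 50, [6], rho=0.9)
            ),
            columns=[f"c{j}" for j in range(6)],
        )
        assign = pd.Series(1, index=z.columns)
        out, rounds = second_round(z, assign, NetworkParams())
        pd.testing.assert_series_equal(out, assign)
        assert (rounds == 1).all()


class TestModuleRecovery:
    def test_ari_above_090_with_strong_blocks(self, block_config):
        aris = []
        for s in range(5):
            cm, _, _, truth = pl.generate(block_config, seed=s)
            sol = find_modules(cm)
            aris.append(adjusted_rand_score(truth.membership, sol.assignment))
        assert np.mean(aris) >= 0.9


class TestExportNetwork:
    @pytest.fixture()
    def tiny_solution(self):
        ids = ["x", "y", "z"]
        assign = pd.Series([1, 1, 2], index=ids)
        eig = pd.DataFrame(np.zeros((4, 2)), columns=["m1", "m2"])
        sol = pl.ModuleSolution(
            assignment=assign,
            eigenvectors=eig,
            round_of_assignment=pd.Series([1, 1, 1], index=ids),
        )
        return sol

    def test_threshold_rules(self, tiny_solution):
        cor = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.1], [0.3, 0.1, 1.0]])
        classes = pd.Series(["SA", "AL", "PG"], index=["x", "y", "z"])
        edges, G = export_network(cor, tiny_solution, classes)
        pairs = set(map(tuple, edges[["source", "target"]].to_numpy()))
        assert ("x", "y") in pairs  # r = 0.6 >= 0.5
        assert ("x", "z") not in pairs  # r = 0.3, not in weak set
        assert G.nodes["x"]["module"] == 1 and G.nodes["x"]["compound_class"] == "SA"

    def test_weak_module_pairs_kept_at_lower_threshold(self, tiny_solution):
        cor = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.0], [0.0, 0.0, 1.0]])
        edges, _ = export_network(
            cor, tiny_solution, None, weak_modules={1}
        )
        pairs = set(map(tuple, edges[["source", "target"]].to_numpy()))
        assert ("x", "y") in pairs  # both in weak module 1, r = 0.3 > 0.1


@given(st.floats(min_value=-1.0, max_value=1.0), st.floats(min_value=1.0, max_value=12.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_signed_adjacency_bounds(r, beta):
    adj = signed_adjacency(np.array([[1.0, r], [r, 1.0]]), beta)
    assert 0.0 <= adj[0, 1] <= 1.0
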