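"""Coexpression networks: filtering, bicor, adjacency, modules, preservation."""

import numpy as np
import pandas as pd
import pytest

from polyshock import de, networks


def _latent_blocks(n_blocks=2, block_size=50, n_samples=30, noise_sd=0.1, seed=0):
    """Expression matrix with blocks driven by independent latent factors."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_blocks):
        f = rng.normal(0, 1, n_samples)
        rows.append(f + rng.normal(0, noise_sd, (block_size, n_samples)))
    x = np.vstack(rows)
    idx = [f"g{i:04d}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=idx, columns=[f"s{j}" for j in range(n_samples)])


class TestFilter:
    def test_gene_zero_in_exactly_half_removed(self):
        counts = pd.DataFrame([[0, 0, 5, 5]], index=["g1"])
        assert len(networks.filter_low_counts(counts)) == 0

    def test_gene_positive_everywhere_kept(self):
        counts = pd.DataFrame([[1, 2, 3, 4]], index=["g1"])
        assert len(networks.filter_low_counts(counts)) == 1

    def test_ten_samples_four_zeros_kept(self):
        counts = pd.DataFrame([[0, 0, 0, 0, 1, 1, 1, 1, 1, 1]], index=["g1"])
        assert len(networks.filter_low_counts(counts)) == 1


class TestVst:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"a": [0, 7], "b": [0, 7]})
        out = networks.vst(counts, factors=pd.Series(1.0, index=["a", "b"]))
        assert out.iloc[0, 0] == 0.0

    def test_count_seven_maps_to_three(self):
        counts = pd.DataFrame({"a": [7], "b": [7]})
        out = networks.vst(counts, factors=pd.Series(1.0, index=["a", "b"]))
        assert out.iloc[0, 0] == pytest.approx(3.0)

    def test_doubled_library_is_rescaled(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        out = networks.vst(counts)
        # a library sequenced twice as deep is identical after the transform
        np.testing.assert_allclose(out["a"], out["b"], atol=1e-12)


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        assert networks.bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_negated_vector_gives_minus_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        assert networks.bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_independent_scalar_implementation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)

        def weights(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            u = (v - med) / (9 * mad)
            w = (1 - u**2) ** 2 * (np.abs(u) < 1)
            return (v - med) * w

        xw, yw = weights(x), weights(y)
        ref = np.sum(xw * yw) / np.sqrt(np.sum(xw**2) * np.sum(yw**2))
        assert networks.bicor(x, y) == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=25), rng.normal(size=25)
        a = networks.bicor(x, y)
        b = networks.bicor(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert b == pytest.approx(a, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            networks.bicor(np.ones(10), np.arange(10.0))


class TestAdjacency:
    def test_perfect_correlation_gives_unit_weight(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        adj = networks.adjacency_signed_hybrid(cor, beta=6)
        assert adj[0, 1] == 1.0
        assert adj[0, 0] == 0.0  # diagonal excluded

    def test_negative_correlation_zeroed(self):
        cor = np.array([[1.0, -0.9], [-0.9, 1.0]])
        adj = networks.adjacency_signed_hybrid(cor, beta=6)
        assert adj[0, 1] == 0.0

    def test_soft_power_closed_form(self):
        cor = np.array([[1.0, 0.5], [0.5, 1.0]])
        adj = networks.adjacency_signed_hybrid(cor, beta=6)
        assert adj[0, 1] == pytest.approx(0.015625, abs=1e-15)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            networks.adjacency_signed_hybrid(np.eye(2), beta=0.5)


class TestDegree:
    def test_zero_adjacency(self):
        assert (networks.degree(np.zeros((4, 4))) == 0).all()

    def test_complete_graph(self):
        adj = np.ones((5, 5))
        np.fill_diagonal(adj, 0.0)
        np.testing.assert_allclose(networks.degree(adj), 4.0)

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(5)
        adj = rng.uniform(size=(10, 10))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        ref = [sum(adj[i, j] for j in range(10) if j != i) for i in range(10)]
        np.testing.assert_allclose(networks.degree(adj), ref, rtol=1e-12)


class TestModules:
    def test_two_planted_blocks_recovered(self):
        expr = _latent_blocks(n_blocks=2, block_size=50, seed=6)
        mods = networks.detect_modules(expr, min_size=30)
        found = [m for m in mods.unique() if m != networks.UNASSIGNED]
        assert len(found) == 2
        # label agreement up to renaming
        truth = np.repeat([0, 1], 50)
        agreement = max(
            (mods.to_numpy() == np.where(truth == k, "M1", "M2")).mean()
            for k in (0, 1)
        )
        assert agreement >= 0.95

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.normal(size=(200, 30)),
            index=[f"g{i}" for i in range(200)],
        )
        mods = networks.detect_modules(expr, min_size=30)
        assert (mods == networks.UNASSIGNED).mean() >= 0.9

    def test_duplicated_block_is_merged(self):
        expr = _latent_blocks(n_blocks=2, block_size=50, seed=8)
        dup = expr.iloc[:50].copy()
        dup.index = [f"d{i:04d}" for i in range(50)]
        both = pd.concat([expr, dup])
        mods = networks.detect_modules(both, min_size=30)
        # the duplicate shares its eigengene with block 1 -> single module
        assert mods.loc[both.index[0]] == mods.loc["d0000"]

    def test_label_permutation_equivariance(self):
        expr = _latent_blocks(n_blocks=2, block_size=40, seed=9)
        mods = networks.detect_modules(expr, min_size=25)
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(expr))
        mods_p = networks.detect_modules(expr.iloc[perm], min_size=25)
        same = (
            (mods.iloc[perm].to_numpy() == mods.to_numpy()[perm])
        )
        assert same.all()
        # and module contents agree up to renaming
        a = pd.Series(mods.to_numpy()[perm], index=expr.index[perm])
        pairs = set(zip(a.to_numpy(), mods_p.to_numpy()))
        assert len(pairs) == len({x for x, _ in pairs})


@pytest.fixture(scope="module")
def planted():
    expr = _latent_blocks(n_blocks=2, block_size=40, noise_sd=0.3, seed=11)
    rng = np.random.default_rng(12)
    noise = pd.DataFrame(
        rng.normal(size=(120, expr.shape[1])),
        index=[f"n{i:04d}" for i in range(120)],
        columns=expr.columns,
    )
    full = pd.concat([expr, noise])
    modules = pd.Series(networks.UNASSIGNED, index=full.index, dtype=object)
    modules.iloc[:40] = "M1"
    modules.iloc[40:80] = "M2"
    return full, modules


class TestPreservation:
    def test_self_preservation(self, planted):
        full, modules = planted
        rep = networks.preservation(full, full, modules, n_perm=100, seed=0)
        assert rep["preserved"].all()
        assert (rep["n_significant"] == 7).all()
        # minimum attainable permutation p
        pcols = [c for c in rep.columns if c.startswith("p.")]
        assert rep[pcols].min().min() == pytest.approx(1 / 101)

    def test_shuffled_labels_destroy_preservation(self, planted):
        full, modules = planted
        rng = np.random.default_rng(13)
        shuffled = full.copy()
        shuffled[:] = full.to_numpy()[rng.permutation(len(full))]
        rep = networks.preservation(full, shuffled, modules, n_perm=100, seed=0)
        assert not rep["preserved"].any()

    def test_module_exceeding_null_pool_rejected(self, planted):
        full, modules = planted
        big = modules.copy()
        big[big == networks.UNASSIGNED] = "M1"  # no background genes left
        with pytest.raises(ValueError, match="null pool"):
            networks.preservation(full, full, big, n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self, planted):
        full, modules = planted
        with pytest.raises(ValueError):
            networks.preservation(full, full, modules, n_perm=10, seed=0)
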