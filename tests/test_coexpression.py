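"""Network construction, TOM, clustering and eigengenes vs naive oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from resistnet.coexpression import (
    NetworkConfig,
    adjacency,
    adjacency_from_correlation,
    cluster_modules,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    topological_overlap,
)
from resistnet.synthetic_data import SimulationConfig, generate_cohort


def _block_cohort(n_blocks=3, block=8, n_samples=40, loading=1.0, noise=0.0, seed=0):
    """Planted-block expression frame: each block follows one latent factor."""
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_blocks, n_samples))
    rows, labels = [], []
    for b in range(n_blocks):
        for _ in range(block):
            rows.append(loading * factors[b] + noise * rng.standard_normal(n_samples))
            labels.append(b + 1)
    genes = [f"G{i:03d}" for i in range(len(rows))]
    return (
        pd.DataFrame(rows, index=genes, columns=[f"S{j}" for j in range(n_samples)]),
        np.array(labels),
        factors,
    )


class TestAdjacency:
    def test_unsigned_powers_of_correlation(self):
        cor = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = adjacency_from_correlation(cor, power=2, signed=False)
        assert adj[0, 1] == pytest.approx(0.25)
        assert adj[0, 0] == 1.0

    def test_signed_transform(self):
        cor = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = adjacency_from_correlation(cor, power=2, signed=True)
        assert adj[0, 1] == pytest.approx(0.0625)  # ((1-0.5)/2)^2

    def test_perfect_and_zero_correlation(self):
        cor = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        adj = adjacency_from_correlation(cor, power=7)
        assert adj[0, 1] == 1.0
        assert adj[0, 2] == 0.0

    def test_range_and_symmetry_on_data(self):
        expr, _, _ = _block_cohort(noise=0.5, loading=0.7)
        adj = adjacency(expr, power=6)
        assert np.allclose(adj, adj.T)
        assert adj.min() >= 0.0 and adj.max() <= 1.0

    def test_too_few_samples(self):
        expr = pd.DataFrame(np.ones((4, 2)))
        with pytest.raises(ValueError):
            adjacency(expr, power=2)


def _tom_naive(adj: np.ndarray) -> np.ndarray:
    """Literal triple-loop topological overlap (oracle)."""
    n = adj.shape[0]
    out = np.eye(n)
    k = [sum(adj[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return out


class TestTopologicalOverlap:
    def test_matches_naive_oracle(self, rng):
        raw = rng.uniform(0, 1, size=(9, 9))
        adj = (raw + raw.T) / 2
        np.fill_diagonal(adj, 1.0)
        np.testing.assert_allclose(topological_overlap(adj), _tom_naive(adj), atol=1e-12)

    def test_three_node_hand_value(self):
        adj = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.2], [0.4, 0.2, 1.0]])
        tom = topological_overlap(adj)
        # l_12 = a13*a23 = 0.08; k = (0.9, 0.7, 0.6); denom = 0.7 + 1 - 0.5
        assert tom[0, 1] == pytest.approx((0.08 + 0.5) / 1.2, abs=1e-12)
        np.testing.assert_allclose(tom, _tom_naive(adj), atol=1e-12)

    def test_clique_is_all_ones(self):
        adj = np.ones((6, 6))
        np.testing.assert_allclose(topological_overlap(adj), 1.0)

    def test_isolated_pair_is_zero(self):
        adj = np.eye(4)
        tom = topological_overlap(adj)
        assert tom[0, 1] == 0.0

    def test_bounds_and_diagonal(self, rng):
        raw = rng.uniform(0, 1, size=(20, 20))
        adj = (raw + raw.T) / 2
        np.fill_diagonal(adj, 1.0)
        tom = topological_overlap(adj)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)

    def test_rejects_asymmetric(self):
        adj = np.eye(3)
        adj[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(adj)


class TestClusterModules:
    def test_perfect_blocks_recovered_exactly(self):
        expr, labels, _ = _block_cohort()
        adj = adjacency(expr, power=6)
        part = cluster_modules(
            1 - topological_overlap(adj), expr.index, NetworkConfig(min_module_size=5)
        )
        assert part.n_modules == 3
        assert adjusted_rand_score(labels, part.labels.to_numpy()) == 1.0

    def test_noise_goes_to_module_zero(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.standard_normal((30, 25)))
        adj = adjacency(expr, power=6)
        part = cluster_modules(
            1 - topological_overlap(adj), expr.index, NetworkConfig(min_module_size=16)
        )
        assert (part.labels == 0).all()
        assert part.n_modules == 0

    def test_renumbered_by_decreasing_size(self):
        expr, _, _ = _block_cohort(n_blocks=2, block=6)
        extra, _, _ = _block_cohort(n_blocks=1, block=10, seed=9)
        extra.index = [f"H{i}" for i in range(len(extra))]
        both = pd.concat([expr, extra])
        adj = adjacency(both, power=6)
        part = cluster_modules(
            1 - topological_overlap(adj), both.index, NetworkConfig(min_module_size=5)
        )
        sizes = part.labels.value_counts()
        assert sizes[1] >= sizes[2] >= sizes[3]

    def test_deterministic(self):
        expr, _, _ = _block_cohort(noise=0.4, loading=0.8)
        diss = 1 - topological_overlap(adjacency(expr, power=6))
        a = cluster_modules(diss, expr.index, NetworkConfig(min_module_size=5))
        b = cluster_modules(diss, expr.index, NetworkConfig(min_module_size=5))
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_rejects_bad_dissimilarity(self):
        with pytest.raises(ValueError):
            cluster_modules(np.ones((3, 3)), ["a", "b", "c"])


class TestEigengene:
    def test_identical_genes_fully_explained(self):
        profile = np.sin(np.arange(20))
        expr = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        part = cluster_modules(
            np.zeros((5, 5)), expr.index, NetworkConfig(min_module_size=2, cut_height=0.5)
        )
        eig = module_eigengene(expr, part)
        assert eig.var_explained["ME1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        c = np.corrcoef(eig.values.loc["ME1"], z)[0, 1]
        assert c == pytest.approx(1.0, abs=1e-10)  # sign convention: positive

    def test_sign_flip_symmetry(self):
        expr, labels, _ = _block_cohort(n_blocks=1, block=6, noise=0.2)
        part = cluster_modules(
            1 - topological_overlap(adjacency(expr, power=6)),
            expr.index,
            NetworkConfig(min_module_size=3),
        )
        eig = module_eigengene(expr, part)
        flipped = module_eigengene(-expr, part)
        np.testing.assert_allclose(
            eig.values.loc["ME1"], -flipped.values.loc["ME1"], atol=1e-10
        )
        assert eig.var_explained["ME1"] == pytest.approx(flipped.var_explained["ME1"])

    def test_duplicating_members_preserves_eigengene(self):
        expr, _, _ = _block_cohort(n_blocks=1, block=6, noise=0.2)
        doubled = pd.concat([expr, expr.set_index(expr.index + "_copy")])
        part1 = cluster_modules(np.zeros((6, 6)), expr.index, NetworkConfig(min_module_size=2))
        part2 = cluster_modules(np.zeros((12, 12)), doubled.index, NetworkConfig(min_module_size=2))
        e1 = module_eigengene(expr, part1).values.loc["ME1"]
        e2 = module_eigengene(doubled, part2).values.loc["ME1"]
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-10)

    def test_sample_permutation_equivariance(self, rng):
        expr, _, _ = _block_cohort(n_blocks=1, block=6, noise=0.2)
        part = cluster_modules(np.zeros((6, 6)), expr.index, NetworkConfig(min_module_size=2))
        perm = rng.permutation(expr.columns)
        e1 = module_eigengene(expr, part).values.loc["ME1"]
        e2 = module_eigengene(expr[perm], part).values.loc["ME1"]
        np.testing.assert_allclose(e1[perm].to_numpy(), e2.to_numpy(), atol=1e-10)

    def test_recovers_planted_factor(self):
        expr, _, factors = _block_cohort(n_blocks=2, block=15, loading=0.9, noise=0.3, seed=5)
        part = cluster_modules(
            1 - topological_overlap(adjacency(expr, power=6)),
            expr.index,
            NetworkConfig(min_module_size=5),
        )
        eig = module_eigengene(expr, part)
        best = max(
            abs(np.corrcoef(eig.values.loc["ME1"], factors[b])[0, 1]) for b in range(2)
        )
        assert best >= 0.95


class TestModuleTraitCorrelation:
    @staticmethod
    def _me(values: np.ndarray, samples) -> "module_eigengene":
        from resistnet.coexpression import EigengeneMatrix

        return EigengeneMatrix(
            values=pd.DataFrame([values], index=["ME1"], columns=samples),
            var_explained=pd.Series({"ME1": 1.0}),
        )

    def test_perfect_correlation(self):
        samples = [f"S{i}" for i in range(8)]
        trait = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        me = self._me((trait - trait.mean()) / trait.std(), samples)
        out = module_trait_correlation(me, pd.DataFrame({"tumor": trait}, index=samples))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_gives_p_one(self):
        samples = [f"S{i}" for i in range(8)]
        trait = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        eig = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        out = module_trait_correlation(
            self._me(eig, samples), pd.DataFrame({"tumor": trait}, index=samples)
        )
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self, rng):
        samples = [f"S{i}" for i in range(10)]
        eig = rng.standard_normal(10)
        trait = rng.binomial(1, 0.5, 10).astype(float)
        out = module_trait_correlation(
            self._me(eig, samples), pd.DataFrame({"ER": trait}, index=samples)
        )
        # independent direct evaluation of r and the t-tail
        xm, ym = eig - eig.mean(), trait - trait.mean()
        r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
        t = r * np.sqrt(8 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df=8)
        assert out["r"].iloc[0] == pytest.approx(r, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_pairwise_complete_over_missing(self, rng):
        samples = [f"S{i}" for i in range(12)]
        eig = rng.standard_normal(12)
        trait = rng.binomial(1, 0.5, 12).astype(float)
        trait[[2, 7]] = np.nan
        out = module_trait_correlation(
            self._me(eig, samples), pd.DataFrame({"HER2": trait}, index=samples)
        )
        mask = ~np.isnan(trait)
        expected = np.corrcoef(eig[mask], trait[mask])[0, 1]
        assert out["n"].iloc[0] == 10
        assert out["r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_trait_reported_missing(self):
        samples = [f"S{i}" for i in range(6)]
        out = module_trait_correlation(
            self._me(np.arange(6, dtype=float), samples),
            pd.DataFrame({"PR": np.ones(6)}, index=samples),
        )
        assert np.isnan(out["r"].iloc[0])
        assert not out["significant"].iloc[0]


def _fit_index_oracle(k: np.ndarray, n_bins: int = 10) -> float:
    """Independent reimplementation of the binned scale-free fit index."""
    k = k[k > 0]
    if len(k) < 3 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    xs, ys = [], []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        sel = (k >= lo) & (k < hi) if b < n_bins - 1 else (k >= lo) & (k <= hi)
        if sel.any():
            xs.append(np.log10(np.mean(k[sel])))
            ys.append(np.log10(sel.sum()))
    if len(xs) < 3:
        return 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2) if slope < 0 else -float(r**2)


class TestPickSoftThreshold:
    def test_single_candidate_returned(self):
        expr, _, _ = _block_cohort(noise=0.3, loading=0.8)
        power, _ = pick_soft_threshold(expr, NetworkConfig(candidate_powers=(6,)))
        assert power == 6

    def test_matches_brute_force_oracle(self):
        expr, _, _ = _block_cohort(n_blocks=4, block=10, loading=0.9, noise=0.3, seed=8)
        config = NetworkConfig(candidate_powers=tuple(range(1, 13)))
        power, diag = pick_soft_threshold(expr, config)
        cor = np.corrcoef(expr.to_numpy())
        fits = {}
        for p in config.candidate_powers:
            adj = np.abs(cor) ** p
            np.fill_diagonal(adj, 1.0)
            fits[p] = _fit_index_oracle(adj.sum(axis=0) - 1.0)
        reaching = [p for p in config.candidate_powers if fits[p] >= 0.8]
        expected = reaching[0] if reaching else max(fits, key=lambda p: fits[p])
        assert power == expected
        np.testing.assert_allclose(diag["fit_r2"], [fits[p] for p in config.candidate_powers],
                                   atol=1e-10)

    def test_pure_noise_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(rng.standard_normal((60, 30)))
        config = NetworkConfig(candidate_powers=(1, 2), scale_free_r2_target=0.999)
        with caplog.at_level("WARNING"):
            power, diag = pick_soft_threshold(expr, config)
        assert "no candidate power reached" in caplog.text
        assert power == int(diag.loc[diag["fit_r2"].idxmax(), "power"])

    def test_scale_free_fit_degenerate(self):
        assert scale_free_fit(np.ones(50))[0] == 0.0


def test_detect_modules_recovers_demo_partition(demo_data):
    """End-to-end network stage recovers the planted demo modules."""
    cohort, _, truth = demo_data
    result = detect_modules(cohort.expression, cohort.traits)
    ari = adjusted_rand_score(
        truth.module_labels.to_numpy(), result.partition.labels.to_numpy()
    )
    assert ari >= 0.9
    # tumor-shifted module correlates with the tumor trait
    tc = result.trait_correlation
    sig = tc[(tc["trait"] == "tumor") & tc["significant"]]
    assert len(sig) >= 1


def test_constant_genes_dropped_with_warning(caplog):
    expr, _, _ = _block_cohort(noise=0.3, loading=0.8)
    expr.iloc[0] = 1.0  # constant row
    with caplog.at_level("WARNING"):
        result = detect_modules(expr, config=NetworkConfig(min_module_size=5))
    assert "constant" in caplog.text
    assert expr.index[0] not in result.partition.labels.index
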