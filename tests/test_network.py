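"""Network construction, module detection and hub ranking against oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stemnet.data import ExpressionMatrix
from stemnet.network import (
    MODULE_PALETTE,
    UNASSIGNED,
    ModuleSet,
    NetworkModel,
    adjacency,
    apply_strong_correlation_filter,
    cluster_module_profiles,
    detect_modules,
    hub_variant_overlap,
    intramodular_connectivity,
    module_eigengenes,
    pearson_correlation,
    rank_hub_genes,
    soft_threshold_scan,
    topological_overlap,
)

from conftest import make_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference for the topological overlap formula."""
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            ki = sum(a[i, u] for u in range(n))
            kj = sum(a[j, u] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return tom


def brute_force_connectivity(a: np.ndarray, labels: list[str]):
    """Double-loop reference for intramodular connectivity."""
    n = a.shape[0]
    rows = []
    for i in range(n):
        k_total = sum(a[i, j] for j in range(n) if j != i)
        k_within = sum(
            a[i, j] for j in range(n)
            if j != i and labels[j] == labels[i] and labels[i] != UNASSIGNED
        )
        rows.append((k_total, k_within))
    return rows


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestCorrelation:
    def test_duplicate_gene_is_perfectly_correlated(self):
        x = np.vstack([[1, 2, 3, 4.0], [1, 2, 3, 4.0], [4, 3, 2, 1.0]])
        corr, _ = pearson_correlation(make_expression(x))
        assert np.isclose(corr[0, 1], 1.0)
        assert np.isclose(corr[0, 2], -1.0)

    def test_hand_computed_value(self):
        x = np.vstack([[1, 2, 3, 4.0], [1, 2, 3, 5.0]])
        corr, _ = pearson_correlation(make_expression(x))
        assert np.isclose(corr[0, 1], 0.9827, atol=5e-5)

    def test_zero_variance_genes_dropped_with_warning(self):
        x = np.vstack([[1, 2, 3, 4.0], [5, 5, 5, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, used = pearson_correlation(make_expression(x))
        assert used == ["g000"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_correlation(make_expression(np.ones((3, 2))))


class TestAdjacency:
    def test_threshold_mapping_at_published_power(self):
        # r = 0.82 at beta = 12 gives adjacency ~0.1 (one decimal)
        a = adjacency(np.array(0.82), beta=12, variant="signed_hybrid")
        assert round(float(a), 1) == 0.1

    @pytest.mark.parametrize("variant", ["unsigned", "signed", "signed_hybrid"])
    def test_perfect_correlation_maps_to_one(self, variant):
        assert adjacency(np.array(1.0), beta=7, variant=variant) == 1.0

    def test_negative_correlations_zeroed_in_hybrid(self):
        assert adjacency(np.array(-0.5), beta=12, variant="signed_hybrid") == 0.0

    def test_signed_variant_keeps_negative_information(self):
        a = adjacency(np.array(-0.5), beta=2, variant="signed")
        assert np.isclose(a, 0.0625)

    def test_monotone_in_r_and_bounded(self):
        r = np.linspace(0, 1, 50)
        for variant in ("unsigned", "signed", "signed_hybrid"):
            a = adjacency(r, beta=12, variant=variant, zero_diagonal=False)
            assert (np.diff(a) >= -1e-12).all()
            assert a.min() >= 0 and a.max() <= 1

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            adjacency(np.eye(2), variant="nope")


class TestSoftThresholdScan:
    def test_identity_correlation_has_zero_connectivity(self):
        scan = soft_threshold_scan(np.eye(60), powers=(2, 6, 12))
        assert (scan["mean_connectivity"] == 0).all()

    def test_mean_connectivity_decreases_with_power(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 30))
        corr = np.corrcoef(x)
        scan = soft_threshold_scan(corr, powers=(6, 12))
        assert scan.loc[12, "mean_connectivity"] < scan.loc[6, "mean_connectivity"]

    def test_decaying_degree_distribution_scores_high(self):
        # modular correlation structure yields a heavy-tailed connectivity
        rng = np.random.default_rng(5)
        latent = rng.normal(size=100)
        loadings = rng.uniform(0.2, 1.0, size=200)
        x = loadings[:, None] * latent[None, :] + rng.normal(
            0, 0.7, size=(200, 100)
        )
        corr = np.corrcoef(x)
        scan = soft_threshold_scan(corr, powers=(12,))
        assert scan.loc[12, "fit_r2"] >= 0.8


class TestTopologicalOverlap:
    def test_complete_unit_graph_is_all_one(self):
        a = np.ones((5, 5)) - np.eye(5)
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.9
        a[2, 3] = a[3, 2] = 0.9
        tom = topological_overlap(a)
        assert tom[0, 2] == 0.0

    def test_three_node_path_hand_value(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        tom = topological_overlap(a)
        assert np.isclose(tom[0, 2], (0.25 + 0.0) / (0.5 + 1.0 - 0.0))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 11))
            a = random_adjacency(rng, n)
            np.testing.assert_allclose(
                topological_overlap(a), brute_force_tom(a), atol=1e-12
            )

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


def _block_expression(rng, blocks, n_samples=60, within_sd=0.2):
    """Expression with planted correlated blocks plus noise genes."""
    rows, labels = [], []
    for b, size in enumerate(blocks):
        latent = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(latent + rng.normal(0, within_sd, n_samples))
            labels.append(f"block{b}")
    return make_expression(np.array(rows)), labels


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        expr, truth = _block_expression(rng, [50, 50])
        corr, used = pearson_correlation(expr)
        tom = topological_overlap(adjacency(corr))
        ms = detect_modules(tom, expr, used, min_module_size=30)
        assert len(ms.modules) == 2
        assert adjusted_rand_score(truth, ms.labels.to_numpy()) == 1.0
        # deterministic color naming from the fixed palette
        assert set(ms.modules) <= set(MODULE_PALETTE)

    def test_pure_noise_is_mostly_unassigned(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 60))
        expr = make_expression(x)
        corr, used = pearson_correlation(expr)
        tom = topological_overlap(adjacency(corr))
        ms = detect_modules(tom, expr, used, min_module_size=30)
        assert (ms.labels == UNASSIGNED).mean() >= 0.9

    def test_identical_blocks_are_merged(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=60)
        rows = [latent + rng.normal(0, 0.1, 60) for _ in range(80)]
        expr = make_expression(np.array(rows))
        corr, used = pearson_correlation(expr)
        tom = topological_overlap(adjacency(corr))
        ms = detect_modules(tom, expr, used, min_module_size=30,
                            merge_correlation=0.75)
        assert len(ms.modules) == 1

    def test_single_gene_rejected(self):
        expr = make_expression(np.ones((1, 5)))
        with pytest.raises(ValueError, match="2 genes"):
            detect_modules(np.ones((1, 1)), expr, ["g000"])


class TestEigengenes:
    def test_identical_genes_give_their_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = make_expression(np.tile(profile, (4, 1)))
        labels = pd.Series(["m"] * 4, index=expr.gene_ids)
        eig = module_eigengenes(expr, labels)["m"].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, z / np.linalg.norm(z), atol=1e-10)

    def test_orientation_invariant_to_global_sign_flip(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 20))
        expr = make_expression(x)
        labels = pd.Series(["m"] * 6, index=expr.gene_ids)
        e1 = module_eigengenes(expr, labels)["m"]
        # flipping all genes flips the mean profile and the PC together
        e2 = module_eigengenes(make_expression(-x), labels)["m"]
        assert abs(np.corrcoef(e1, e2)[0, 1]) > 0.999

    def test_eigengene_explains_most_variance_two_genes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 30))
        expr = make_expression(x)
        labels = pd.Series(["m"] * 2, index=expr.gene_ids)
        eig = module_eigengenes(expr, labels)["m"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        var_eig = ((z @ eig) ** 2).sum()
        for gene in z:
            g = gene / np.linalg.norm(gene)
            assert var_eig >= ((z @ g) ** 2).sum() - 1e-9

    def test_constant_module_rejected(self):
        expr = make_expression(np.ones((3, 5)))
        labels = pd.Series(["m"] * 3, index=expr.gene_ids)
        with pytest.raises(ValueError, match="constant"):
            module_eigengenes(expr, labels)


class TestStrongCorrelationFilter:
    def _model_and_modules(self, r):
        corr = np.array([[1.0, r], [r, 1.0]])
        model = NetworkModel(["a", "b"], corr)
        labels = pd.Series(["turquoise", "turquoise"], index=["a", "b"])
        return model, ModuleSet(labels=labels)

    def test_pair_above_threshold_retained(self):
        model, ms = self._model_and_modules(0.83)  # 0.83^12 ~ 0.106 >= 0.1
        ms = apply_strong_correlation_filter(model, ms, min_retained=2)
        assert ms.retained["turquoise"] == ["a", "b"]

    def test_pair_below_threshold_dropped(self):
        model, ms = self._model_and_modules(0.80)  # 0.80^12 ~ 0.069 < 0.1
        ms = apply_strong_correlation_filter(model, ms, min_retained=2)
        assert "turquoise" not in ms.retained

    def test_raising_threshold_never_adds_genes(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 40))
        expr = make_expression(0.5 * x + 0.5 * rng.normal(size=(30, 40)))
        corr, used = pearson_correlation(expr)
        labels = pd.Series(["m"] * 30, index=used)
        previous = None
        for threshold in (0.01, 0.05, 0.1, 0.3):
            model = NetworkModel(used, corr, adjacency_threshold=threshold)
            ms = apply_strong_correlation_filter(
                model, ModuleSet(labels=labels.copy()), min_retained=1
            )
            current = set(ms.retained.get("m", []))
            if previous is not None:
                assert current <= previous
            previous = current


class TestProfileClusters:
    def test_identical_profiles_cluster_together(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=20)
        profiles = pd.DataFrame(
            {
                "m1": base,
                "m2": base + rng.normal(0, 0.01, 20),
                "m3": rng.normal(size=20),
            }
        )
        assignment, corr = cluster_module_profiles(profiles, n_clusters=2)
        assert assignment["m1"] == assignment["m2"] != assignment["m3"]
        assert np.isclose(corr.loc["m1", "m1"], 1.0)

    def test_planted_archetypes_grouped(self):
        rng = np.random.default_rng(7)
        archetypes = [rng.normal(size=30) for _ in range(3)]
        data = {}
        for m in range(9):
            data[f"mod{m}"] = archetypes[m % 3] + rng.normal(0, 0.05, 30)
        assignment, _ = cluster_module_profiles(pd.DataFrame(data), n_clusters=3)
        for m in range(9):
            assert assignment[f"mod{m}"] == assignment[f"mod{m % 3}"]

    def test_too_many_clusters_rejected(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="clusters"):
            cluster_module_profiles(profiles, n_clusters=5)


class TestConnectivity:
    def test_complete_module_closed_form(self):
        m, c = 6, 0.4
        a = np.full((m, m), c)
        np.fill_diagonal(a, 0.0)
        genes = [f"g{i}" for i in range(m)]
        ms = ModuleSet(labels=pd.Series(["mod"] * m, index=genes))
        conn = intramodular_connectivity(a, ms, genes)
        np.testing.assert_allclose(conn["kWithin"], (m - 1) * c)
        np.testing.assert_allclose(conn["kOut"], 0.0)

    def test_isolated_gene_is_all_zero(self):
        a = np.zeros((3, 3))
        genes = ["g0", "g1", "g2"]
        ms = ModuleSet(labels=pd.Series(["m", "m", UNASSIGNED], index=genes))
        conn = intramodular_connectivity(a, ms, genes)
        assert (conn[["kTotal", "kWithin", "kOut", "kDiff"]].to_numpy() == 0).all()

    def test_matches_brute_force_and_conserves_totals(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            a = random_adjacency(rng, n)
            genes = [f"g{i}" for i in range(n)]
            labels = [
                rng.choice(["x", "y", UNASSIGNED]) for _ in range(n)
            ]
            ms = ModuleSet(labels=pd.Series(labels, index=genes))
            conn = intramodular_connectivity(a, ms, genes)
            oracle = brute_force_connectivity(a, labels)
            for i, (kt, kw) in enumerate(oracle):
                assert np.isclose(conn["kTotal"].iloc[i], kt)
                assert np.isclose(conn["kWithin"].iloc[i], kw)
            assert np.isclose(
                conn["kWithin"].sum() + conn["kOut"].sum(), conn["kTotal"].sum()
            )


class TestHubRanking:
    def _make(self, kwithin: dict[str, float], module="m"):
        genes = list(kwithin)
        conn = pd.DataFrame(
            {"kWithin": list(kwithin.values())},
            index=pd.Index(genes, name="gene_id"),
        )
        ms = ModuleSet(labels=pd.Series([module] * len(genes), index=genes))
        return conn, ms

    def test_top_fraction_size_uses_ceiling(self):
        conn, ms = self._make({f"g{i:02d}": float(i) for i in range(29)})
        hubs = rank_hub_genes(conn, ms, top_fraction=0.10)
        assert len(hubs["m"]["top_fraction"]) == 3  # ceil(2.9)

    def test_ties_break_by_gene_id(self):
        conn, ms = self._make({"gB": 1.0, "gA": 1.0, "gC": 1.0})
        hubs = rank_hub_genes(conn, ms, top_n=2)
        assert hubs["m"]["top_n"] == ["gA", "gB"]

    def test_retained_variant_and_overlap(self):
        conn, ms = self._make({f"g{i:02d}": float(30 - i) for i in range(20)})
        ms.retained = {"m": [f"g{i:02d}" for i in range(5, 20)]}
        full = rank_hub_genes(conn, ms, top_n=3, use_retained=False)
        filt = rank_hub_genes(conn, ms, top_n=3, use_retained=True)
        assert full["m"]["top_n"] == ["g00", "g01", "g02"]
        assert filt["m"]["top_n"] == ["g05", "g06", "g07"]
        overlap = hub_variant_overlap(conn, ms, top_n=3)
        assert overlap.loc["m", "top_n_overlap"] == 0
        assert not overlap.loc["m", "top_n_identical"]
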