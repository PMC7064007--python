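"""Two-layer bait subnetwork extraction and enrichment classification."""

import numpy as np
import pandas as pd
import pytest

from stemnet.subnetworks import (
    classify_cw_enrichment,
    screen_baits,
    top_neighbors,
    two_layer_subnetwork,
)


def symmetric(rng, n):
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return c


def disjoint_tree_correlation(k: int = 15):
    """Bait -> k children -> k*k grandchildren, all neighbor sets disjoint.

    The bait correlates 0.9 with its k layer-1 genes; each layer-1 gene
    correlates 0.95 with its own k layer-2 genes (so its top-k list holds
    exactly those, the bait ranking k+1-th); everything else ~0.
    """
    n = 1 + k + k * k
    genes = [f"g{i:03d}" for i in range(n)]
    corr = np.zeros((n, n))
    np.fill_diagonal(corr, 1.0)
    for i in range(1, k + 1):
        corr[0, i] = corr[i, 0] = 0.9
        for j in range(k):
            child = 1 + k + (i - 1) * k + j
            corr[i, child] = corr[child, i] = 0.95
    return corr, genes


class TestTopNeighbors:
    def test_perfect_duplicate_ranks_first(self):
        corr = np.array([[1, 1.0, 0.2], [1.0, 1, 0.2], [0.2, 0.2, 1]])
        assert top_neighbors("a", corr, ["a", "b", "c"], k=2) == ["b", "c"]

    def test_k_one_picks_the_strongest(self):
        corr = np.array([[1, 0.9, 0.5], [0.9, 1, 0.1], [0.5, 0.1, 1]])
        assert top_neighbors("g", corr, ["g", "a", "b"], k=1) == ["a"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        corr = symmetric(rng, 30)
        genes = [f"g{i:02d}" for i in range(30)]
        got = top_neighbors("g05", corr, genes, k=10)
        oracle = sorted(
            (g for g in genes if g != "g05"),
            key=lambda g: (-corr[5, genes.index(g)], g),
        )[:10]
        assert got == oracle

    def test_fewer_candidates_than_k_warns(self):
        corr = np.eye(3)
        with pytest.warns(UserWarning, match="candidate"):
            got = top_neighbors("a", corr, ["a", "b", "c"], k=15)
        assert len(got) == 2

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError, match="nope"):
            top_neighbors("nope", np.eye(2), ["a", "b"])


class TestTwoLayer:
    def test_disjoint_construction_reaches_theoretical_bound(self):
        corr, genes = disjoint_tree_correlation(k=15)
        sub = two_layer_subnetwork("g000", corr, genes, k=15)
        assert sub.size == 241  # 1 + 15 + 15^2

    def test_chain_closure_smaller_than_bound(self):
        corr = np.array([[1, 0.9, 0.0], [0.9, 1, 0.1], [0.0, 0.1, 1]])
        sub = two_layer_subnetwork("a", corr, ["a", "b", "c"], k=1)
        assert sub.union_list == {"a", "b"}

    def test_mutual_clique_stays_inside(self):
        n = 16
        corr = np.full((n, n), 0.9)
        np.fill_diagonal(corr, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        sub = two_layer_subnetwork("g00", corr, genes, k=15)
        assert sub.size == 16

    def test_size_bounded_over_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(20, 60))
            corr = symmetric(rng, n)
            genes = [f"g{i:02d}" for i in range(n)]
            k = int(rng.integers(1, 6))
            sub = two_layer_subnetwork("g00", corr, genes, k=k)
            assert sub.size <= 1 + k + k * k
            assert "g00" in sub.union_list
            assert set(sub.layer1) <= sub.union_list

    def test_union_grows_monotonically_with_k(self):
        rng = np.random.default_rng(2)
        corr = symmetric(rng, 40)
        genes = [f"g{i:02d}" for i in range(40)]
        previous: set[str] = set()
        for k in (1, 2, 4, 8):
            sub = two_layer_subnetwork("g00", corr, genes, k=k)
            assert previous <= sub.union_list
            previous = sub.union_list


class TestClassification:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (2, "none"), (3, "light"), (5, "light"), (6, "medium"),
         (11, "medium"), (12, "high"), (18, "high"), (25, "high")],
    )
    def test_category_boundaries(self, count, expected):
        assert classify_cw_enrichment(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_cw_enrichment(-1)

    def test_monotone_step_function(self):
        order = {"none": 0, "light": 1, "medium": 2, "high": 3}
        cats = [order[classify_cw_enrichment(c)] for c in range(0, 30)]
        assert cats == sorted(cats)


@pytest.fixture(scope="module")
def screened(small_dataset, small_config):
    """Full screen on the small synthetic dataset."""
    from stemnet.network import (
        NetworkModel,
        adjacency,
        apply_strong_correlation_filter,
        detect_modules,
        pearson_correlation,
        topological_overlap,
    )
    from stemnet.preprocess import filter_low_expression, normalize_counts

    filtered = filter_low_expression(small_dataset["counts"], 3, 10)
    expr = normalize_counts(filtered)
    corr, used = pearson_correlation(expr)
    expr = expr.__class__(expr.values.loc[used])
    model = NetworkModel(used, corr)
    tom = topological_overlap(adjacency(corr))
    ms = detect_modules(tom, expr, used, min_module_size=20)
    ms = apply_strong_correlation_filter(model, ms)
    screen = screen_baits(
        small_dataset["annotations"].bait_genes(),
        model, ms, small_dataset["annotations"], small_dataset["keywords"],
        filtered_genes=set(filtered.gene_ids),
    )
    return screen, filtered


class TestScreenBaits:
    def test_low_expression_bait_excluded(self, screened, small_dataset):
        screen, filtered = screened
        dropped = set(small_dataset["annotations"].bait_genes().index) - set(
            filtered.gene_ids
        )
        assert dropped  # the generator plants at least one such bait
        for bait in dropped:
            assert screen.loc[bait, "status"] == "excluded_low_expression"

    def test_planted_cw_module_baits_score_medium_or_high(
        self, screened, small_dataset, small_config
    ):
        screen, _ = screened
        from stemnet.simulate import planted_labels

        planted = planted_labels(small_config)
        scw_baits = [
            b for b in screen.index
            if planted.get(b) == "scw" and screen.loc[b, "status"] == "screened"
        ]
        assert scw_baits
        for bait in scw_baits:
            assert screen.loc[bait, "category"] in ("medium", "high")

    def test_row_order_invariance(self, screened, small_dataset):
        screen, filtered = screened
        from stemnet.network import (
            NetworkModel, adjacency, apply_strong_correlation_filter,
            detect_modules, pearson_correlation, topological_overlap,
        )
        from stemnet.preprocess import normalize_counts

        expr = normalize_counts(filtered)
        corr, used = pearson_correlation(expr)
        expr = expr.__class__(expr.values.loc[used])
        model = NetworkModel(used, corr)
        ms = detect_modules(topological_overlap(adjacency(corr)), expr, used,
                            min_module_size=20)
        ms = apply_strong_correlation_filter(model, ms)
        shuffled = small_dataset["annotations"].bait_genes().iloc[::-1]
        again = screen_baits(
            shuffled, model, ms, small_dataset["annotations"],
            small_dataset["keywords"], filtered_genes=set(filtered.gene_ids),
        )
        pd.testing.assert_frame_equal(screen, again)

    def test_unknown_bait_raises(self, screened, small_dataset):
        _, filtered = screened
        from stemnet.network import NetworkModel
        table = pd.DataFrame(
            {"tf_family": ["MYB"], "clade": ["4"]},
            index=pd.Index(["NOT_A_GENE"], name="gene_id"),
        )
        model = NetworkModel(["a", "b"], np.eye(2))
        from stemnet.network import ModuleSet
        ms = ModuleSet(labels=pd.Series(["m", "m"], index=["a", "b"]))
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            screen_baits(table, model, ms, small_dataset["annotations"],
                         small_dataset["keywords"])
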