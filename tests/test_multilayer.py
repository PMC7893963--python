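import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from oracles import fisher_enumeration

from nucleolong import (
    LayerMatrix,
    SimulationConfig,
    annotate_clusters,
    build_abundance_matrix,
    cluster_nuclei,
    enriched_genes,
    fisher_splicing_test,
    ks_ratio_test,
    normalize_and_merge,
    score_cell_types,
    simulate,
)


def dense_layer(X, layer="abundance", prefix="f"):
    n, p = X.shape
    return LayerMatrix(
        layer,
        [f"b{i}" for i in range(n)],
        [f"{prefix}{j}" for j in range(p)],
        sp.csr_matrix(np.asarray(X, dtype=np.int64)),
    )


@pytest.fixture(scope="module")
def marker_ds():
    return simulate(SimulationConfig(seed=3, n_nuclei=150, n_celltypes=3, reads_per_nucleus=40))


class TestNormalizeAndMerge:
    def test_single_layer_identity_shape(self):
        rng = np.random.default_rng(0)
        m = dense_layer(rng.integers(0, 6, size=(20, 10)))
        merged = normalize_and_merge([m])
        assert merged.shape == (20, 10)
        assert merged.layer_of_feature == ["abundance"] * 10

    def test_merged_width_is_sum_of_layer_widths(self):
        rng = np.random.default_rng(1)
        a = dense_layer(rng.integers(0, 6, size=(20, 10)), "abundance", "g")
        b = dense_layer(rng.integers(0, 4, size=(20, 7)), "splicing", "s")
        merged = normalize_and_merge([a, b])
        assert merged.shape == (20, 17)

    def test_features_standardized(self):
        rng = np.random.default_rng(2)
        merged = normalize_and_merge([dense_layer(rng.integers(0, 9, size=(30, 8)))])
        assert np.allclose(merged.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(merged.X.std(axis=0), 1, atol=1e-9)

    def test_nuclei_intersection(self):
        a = dense_layer(np.ones((3, 2)), "abundance", "g")
        b = LayerMatrix(
            "splicing", ["b1", "b2", "bX"], ["s0"], sp.csr_matrix(np.ones((3, 1), dtype=np.int64))
        )
        merged = normalize_and_merge([a, b])
        assert merged.nuclei == ["b1", "b2"]

    def test_disjoint_nuclei_is_an_error(self):
        a = dense_layer(np.ones((2, 2)))
        b = LayerMatrix(
            "splicing", ["x0", "x1"], ["s0"], sp.csr_matrix(np.ones((2, 1), dtype=np.int64))
        )
        with pytest.raises(ValueError):
            normalize_and_merge([a, b])


class TestClusterNuclei:
    def blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(60, 20))
        b = rng.normal(8, 1, size=(60, 20))
        return np.vstack([a, b]), np.array([0] * 60 + [1] * 60)

    def test_two_separated_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        X, truth = self.blobs()
        labels = cluster_nuclei(X, n_pcs=10, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_under_seed(self):
        X, _ = self.blobs(3)
        a = cluster_nuclei(X, n_pcs=10, seed=7)
        b = cluster_nuclei(X, n_pcs=10, seed=7)
        assert np.array_equal(a, b)

    def test_npcs_must_be_below_nucleus_count(self):
        X, _ = self.blobs()
        with pytest.raises(ValueError, match="n_pcs"):
            cluster_nuclei(X[:10], n_pcs=10, seed=0)

    def test_planted_celltypes_recovered(self, marker_ds):
        from sklearn.metrics import adjusted_rand_score

        ab = build_abundance_matrix(marker_ds.guide_records)
        labels = cluster_nuclei(normalize_and_merge([ab]), n_pcs=20, seed=0)
        truth = [marker_ds.celltypes[b] for b in ab.nuclei]
        assert adjusted_rand_score(truth, labels) >= 0.9


class TestScoreCellTypes:
    def test_planted_types_recovered_with_high_accuracy(self, marker_ds):
        ab = build_abundance_matrix(marker_ds.guide_records)
        gene_ids = sorted(marker_ds.models)
        m = marker_ds.config.marker_genes_per_type
        sets = {f"type{t}": gene_ids[t * m : (t + 1) * m] for t in range(3)}
        scores, assignment = score_cell_types(ab, sets, seed=0)
        truth = {b: f"type{marker_ds.celltypes[b]}" for b in ab.nuclei}
        acc = np.mean([assignment[b] == truth[b] for b in ab.nuclei])
        assert acc >= 0.9

    def test_marker_order_does_not_change_assignment(self, marker_ds):
        ab = build_abundance_matrix(marker_ds.guide_records)
        gene_ids = sorted(marker_ds.models)
        m = marker_ds.config.marker_genes_per_type
        sets = {f"type{t}": gene_ids[t * m : (t + 1) * m] for t in range(3)}
        _, a = score_cell_types(ab, sets, seed=0)
        permuted = {k: sets[k] for k in reversed(list(sets))}
        permuted = {k: list(reversed(v)) for k, v in permuted.items()}
        _, b = score_cell_types(ab, permuted, seed=0)
        assert (a == b).all()

    def test_all_nonpositive_scores_give_unknown(self):
        # the marker gene is silent in b0 while everything else is expressed
        X = np.array([[0, 5, 5, 5, 4, 6], [9, 1, 1, 1, 1, 1]])
        m = dense_layer(X)
        scores, assignment = score_cell_types(m, {"only": ["f0"]}, seed=0)
        assert assignment["b0"] == "unknown"
        assert assignment["b1"] == "only"

    def test_unresolvable_marker_set_skipped(self, caplog):
        X = np.array([[1, 2], [2, 1]])
        m = dense_layer(X)
        with pytest.raises(ValueError):
            score_cell_types(m, {"ghost": ["nope"]}, seed=0)

    def test_cluster_annotation_is_modal_type(self):
        import pandas as pd

        assignment = pd.Series(
            ["A", "A", "B", "B", "B"], index=[f"b{i}" for i in range(5)]
        )
        report = annotate_clusters([0, 0, 0, 1, 1], assignment)
        assert report.loc[0, "celltype"] == "A"
        assert report.loc[1, "celltype"] == "B"


class TestFisher:
    def test_perfect_association_matches_enumeration(self):
        table = ((10, 0), (0, 10))
        assert fisher_splicing_test(*table) == pytest.approx(fisher_enumeration(table), abs=1e-12)

    def test_no_association_gives_one(self):
        assert fisher_splicing_test((5, 5), (5, 5)) == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        a = fisher_splicing_test((3, 9), (7, 2))
        b = fisher_splicing_test((3, 7), (9, 2))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_margin_is_degenerate(self):
        assert fisher_splicing_test((0, 0), (3, 4)) == 1.0
        assert fisher_splicing_test((3, 0), (4, 0)) == 1.0

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            t = tuple(map(tuple, rng.integers(0, 15, size=(2, 2))))
            assert fisher_splicing_test(*t) == pytest.approx(fisher_enumeration(t), abs=1e-9)


class TestKS:
    def test_identical_samples(self):
        stat, p = ks_ratio_test([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert stat == 0.0 and p > 0.99

    def test_fully_separated_cluster_has_statistic_one(self):
        stat, _ = ks_ratio_test([0.8, 0.9, 0.95], [0.1, 0.2, 0.3])
        assert stat == 1.0

    def test_direction_is_one_sided_greater(self):
        # the *lower* sample must not be flagged
        _, p_low = ks_ratio_test([0.1, 0.15, 0.2] * 10, [0.7, 0.8, 0.9] * 10)
        _, p_high = ks_ratio_test([0.7, 0.8, 0.9] * 10, [0.1, 0.15, 0.2] * 10)
        assert p_high < 0.001 < p_low

    def test_agrees_with_permutation_estimate(self):
        rng = np.random.default_rng(12)
        a = rng.beta(4, 4, size=25) * 0.6 + 0.2
        b = rng.beta(2, 6, size=40) * 0.6
        stat, p = ks_ratio_test(a, b)

        def one_sided_stat(x, y):
            grid = np.sort(np.concatenate([x, y]))
            fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
            fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
            return np.max(fy - fx)

        pooled = np.concatenate([a, b])
        obs = one_sided_stat(a, b)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if one_sided_stat(pooled[: len(a)], pooled[len(a) :]) >= obs - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p - p_perm) < max(0.01, 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm))


class TestEnrichedGenes:
    def test_exclusive_gene_tops_its_cluster(self):
        rng = np.random.default_rng(4)
        X = rng.integers(1, 5, size=(40, 10))
        X[:20, 0] = 0  # f0 exclusive to cluster 1
        X[20:, 0] = rng.integers(5, 9, size=20)
        m = dense_layer(X)
        ranked = enriched_genes(m, [0] * 20 + [1] * 20)
        assert list(ranked[1].gene)[:1] == ["f0"]
        assert "f0" not in list(ranked[0].gene)

    def test_uniform_gene_filtered_out(self):
        rng = np.random.default_rng(5)
        X = rng.integers(3, 6, size=(40, 8))
        X[:20, 3] = 0
        X[20:, 3] = 9
        m = dense_layer(X)
        ranked = enriched_genes(m, [0] * 20 + [1] * 20)
        for df in ranked.values():
            assert set(df.gene) <= {"f3"}

    def test_filters_off_reduces_to_pure_ranking(self, marker_ds):
        ab = build_abundance_matrix(marker_ds.guide_records)
        labels = [marker_ds.celltypes[b] for b in ab.nuclei]
        ranked = enriched_genes(ab, labels, max_out_group_fraction=1.0, min_fold_change=0.0)
        gene_ids = sorted(marker_ds.models)
        m = marker_ds.config.marker_genes_per_type
        for t, df in ranked.items():
            assert set(df.gene.head(m)) == set(gene_ids[t * m : (t + 1) * m])

    def test_single_nucleus_cluster_skipped(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, size=(21, 6))
        ranked = enriched_genes(dense_layer(X), [0] * 10 + [1] * 10 + [2])
        assert set(ranked) == {0, 1}
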