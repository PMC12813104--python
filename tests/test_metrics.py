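"""Diversity, ordination, PERMANOVA, reproducibility and sharing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import kitbench as kb
from kitbench.metrics import DistanceMatrix
from kitbench.tables import ValidationError


def brute_force_bray_curtis(x, y):
    """Independent double-loop evaluation of 1 - 2 sum(min) / (sum + sum)."""
    shared = 0.0
    for xi, yi in zip(x, y):
        shared += min(xi, yi)
    return 1.0 - 2.0 * shared / (sum(x) + sum(y))


class TestShannon:
    def test_single_otu_zero(self):
        assert kb.shannon([0, 9, 0]) == 0.0

    def test_uniform_is_log_richness(self):
        assert kb.shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), abs=1e-12)

    def test_direct_evaluation(self):
        assert kb.shannon([1, 2, 3]) == pytest.approx(1.0114042647073518, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            kb.shannon([0, 0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=1, max_size=20).filter(
            lambda c: sum(c) > 0
        ),
        scale=st.integers(2, 9),
    )
    def test_bounded_by_log_richness_and_scale_invariant(self, counts, scale):
        h = kb.shannon(counts)
        richness = sum(1 for c in counts if c > 0)
        assert h <= np.log(richness) + 1e-12
        assert kb.shannon([c * scale for c in counts]) == pytest.approx(h)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        table = kb.OtuTable.from_counts([[3, 4], [3, 4]], ["a", "b"], ["o1", "o2"])
        assert kb.bray_curtis(table).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        table = kb.OtuTable.from_counts([[3, 0], [0, 4]], ["a", "b"], ["o1", "o2"])
        assert kb.bray_curtis(table).values[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        table = kb.OtuTable.from_counts([[1, 1], [1, 0]], ["a", "b"], ["o1", "o2"])
        assert kb.bray_curtis(table).values[0, 1] == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 50, size=(5, 8))
            counts[counts.sum(axis=1) == 0, 0] = 1
            table = kb.OtuTable.from_counts(
                counts, [f"s{i}" for i in range(5)], [f"o{j}" for j in range(8)]
            )
            got = kb.bray_curtis(table).values
            for i in range(5):
                for j in range(5):
                    expected = brute_force_bray_curtis(counts[i], counts[j])
                    assert got[i, j] == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        table = kb.OtuTable.from_counts([[0, 0], [1, 2]], ["a", "b"], ["o1", "o2"])
        with pytest.raises(ValidationError, match="zero total"):
            kb.bray_curtis(table)


def euclidean_distance_matrix(points):
    points = np.asarray(points, dtype=float)
    values = squareform(pdist(points))
    ids = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(values, ids)


class TestPcoa:
    def test_all_zero_distances(self):
        dist = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        coords, eigenvalues = kb.pcoa(dist, k=1)
        assert np.allclose(eigenvalues, 0.0, atol=1e-10)
        assert coords.shape[1] == 0

    def test_collinear_points_single_axis(self):
        points = [[0.0], [0.2], [0.5]]
        dist = euclidean_distance_matrix(points)
        coords, eigenvalues = kb.pcoa(dist, k=2)
        assert (eigenvalues > 1e-10).sum() == 1
        recovered = coords["PC1"].to_numpy()
        gaps = np.abs(np.subtract.outer(recovered, recovered))
        expected = np.abs(np.subtract.outer(np.ravel(points), np.ravel(points)))
        assert np.allclose(gaps, expected, atol=1e-9)

    def test_planar_cloud_two_positive_axes(self):
        rng = np.random.default_rng(3)
        points = rng.uniform(0, 0.3, size=(6, 2))
        dist = euclidean_distance_matrix(points)
        _, eigenvalues = kb.pcoa(dist, k=3)
        positive = eigenvalues[eigenvalues > 1e-10]
        assert len(positive) == 2
        assert positive[:2].sum() == pytest.approx(eigenvalues[eigenvalues > 0].sum())

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(5)
        points = rng.uniform(0, 0.25, size=(7, 3))
        dist = euclidean_distance_matrix(points)
        coords, _ = kb.pcoa(dist, k=6)
        reconstructed = squareform(pdist(coords.to_numpy()))
        assert np.allclose(reconstructed, dist.values, atol=1e-9)

    def test_matches_reference_implementation(self):
        """Cross-check eigenvalues against scikit-bio's PCoA."""
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        import skbio

        rng = np.random.default_rng(11)
        counts = rng.integers(1, 60, size=(6, 10))
        table = kb.OtuTable.from_counts(
            counts, [f"s{i}" for i in range(6)], [f"o{j}" for j in range(10)]
        )
        dist = kb.bray_curtis(table)
        _, eigenvalues = kb.pcoa(dist, k=2)
        reference = skbio_ordination.pcoa(
            skbio.DistanceMatrix(dist.values, dist.sample_ids)
        )
        assert np.allclose(
            eigenvalues[:3], reference.eigvals.to_numpy()[:3], atol=1e-9
        )

    def test_k_too_large_rejected(self):
        dist = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        with pytest.raises(ValidationError):
            kb.pcoa(dist, k=3)


class TestPermanova:
    def separated_clusters(self):
        # groups large enough that a random permutation essentially never
        # reproduces the planted two-cluster partition
        rng = np.random.default_rng(1)
        a = rng.normal(0.1, 0.01, size=(9, 2))
        b = rng.normal(0.6, 0.01, size=(9, 2))
        return euclidean_distance_matrix(np.vstack([a, b])), ["g1"] * 9 + ["g2"] * 9

    def test_complete_separation_minimal_p(self):
        dist, groups = self.separated_clusters()
        result = kb.permanova(dist, groups, n_permutations=199, seed=0)
        assert result.p_value == pytest.approx(1 / 200)
        assert result.pseudo_f > 10

    def test_duplicated_samples_zero_f(self):
        # both groups contain the same two points -> no between-group structure
        points = np.array([[0.0, 0.0], [0.3, 0.1], [0.0, 0.0], [0.3, 0.1]])
        dist = euclidean_distance_matrix(points)
        result = kb.permanova(dist, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert result.pseudo_f == pytest.approx(0.0, abs=1e-9)

    def test_matches_reference_pseudo_f(self):
        """Pseudo-F agrees with scikit-bio's PERMANOVA on the same input."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        import skbio

        rng = np.random.default_rng(9)
        counts = rng.integers(1, 80, size=(9, 12))
        table = kb.OtuTable.from_counts(
            counts, [f"s{i}" for i in range(9)], [f"o{j}" for j in range(12)]
        )
        dist = kb.bray_curtis(table)
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ours = kb.permanova(dist, groups, n_permutations=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio.DistanceMatrix(dist.values, dist.sample_ids),
            grouping=groups,
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_degenerate_groupings_rejected(self):
        dist = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.raises(ValidationError):
            kb.permanova(dist, ["g"] * 4)
        with pytest.raises(ValidationError, match="size 1"):
            kb.permanova(dist, ["g1", "g1", "g1", "g2"])


class TestReproducibility:
    def table(self, rows, ids):
        return kb.OtuTable.from_counts(rows, ids, ["A", "B", "C"])

    def test_identical_replicates_one(self):
        table = self.table([[1, 2, 0], [5, 9, 0]], ["r1", "r2"])
        assert kb.reproducibility_rate(table, ["r1", "r2"]) == 1.0

    def test_disjoint_replicates_zero(self):
        table = self.table([[1, 0, 0], [0, 2, 0]], ["r1", "r2"])
        assert kb.reproducibility_rate(table, ["r1", "r2"]) == 0.0

    def test_worked_example(self):
        # presence sets {A,B}, {A,C}, {A,B} -> |{A}| / |{A,B,C}| = 1/3
        table = self.table([[1, 1, 0], [1, 0, 1], [1, 1, 0]], ["r1", "r2", "r3"])
        assert kb.reproducibility_rate(table, ["r1", "r2", "r3"]) == pytest.approx(1 / 3)

    def test_empty_replicate_warns_and_zero(self, caplog):
        table = self.table([[1, 1, 0], [0, 0, 0]], ["r1", "r2"])
        rate = kb.reproducibility_rate(table, ["r1", "r2"])
        assert rate == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        presence=st.lists(
            st.lists(st.booleans(), min_size=4, max_size=4), min_size=2, max_size=4
        ),
        order=st.randoms(use_true_random=False),
        scale=st.integers(1, 50),
    )
    def test_invariant_to_order_and_magnitude(self, presence, order, scale):
        if not any(any(row) for row in presence):
            return
        counts = [[scale if p else 0 for p in row] for row in presence]
        ids = [f"r{i}" for i in range(len(presence))]
        table = kb.OtuTable.from_counts(counts, ids, ["A", "B", "C", "D"])
        baseline = kb.reproducibility_rate(table, ids)
        shuffled = list(ids)
        order.shuffle(shuffled)
        assert kb.reproducibility_rate(table, shuffled) == baseline


class TestOtuSharing:
    def records(self, kits):
        return [
            kb.SampleRecord(f"{kit}_r{i + 1}", "alga", kit, i + 1)
            for kit in kits
            for i in range(1)
        ]

    def test_all_universal(self):
        table = kb.OtuTable.from_counts(
            [[1, 1], [2, 3]], ["k1_r1", "k2_r1"], ["A", "B"]
        )
        sharing = kb.otu_sharing(table, self.records(["k1", "k2"]), "alga")
        assert sharing.counts == {1: 0, 2: 2}
        assert sharing.universal_fraction == 1.0

    def test_all_unique(self):
        table = kb.OtuTable.from_counts(
            [[1, 0], [0, 3]], ["k1_r1", "k2_r1"], ["A", "B"]
        )
        sharing = kb.otu_sharing(table, self.records(["k1", "k2"]), "alga")
        assert sharing.unique_fraction == 1.0

    def test_worked_example(self):
        # kit sets {A,B} and {B,C}: counts {1: 2, 2: 1}, universal 1/3
        table = kb.OtuTable.from_counts(
            [[1, 1, 0], [0, 1, 1]], ["k1_r1", "k2_r1"], ["A", "B", "C"]
        )
        sharing = kb.otu_sharing(table, self.records(["k1", "k2"]), "alga")
        assert sharing.counts == {1: 2, 2: 1}
        assert sharing.universal_fraction == pytest.approx(1 / 3)
        assert sharing.total_detected == 3

    def test_unknown_species_rejected(self):
        table = kb.OtuTable.from_counts([[1]], ["k1_r1"], ["A"])
        with pytest.raises(ValidationError, match="unknown species"):
            kb.otu_sharing(table, self.records(["k1"]), "kelp")


class TestAggregateTaxa:
    def test_single_taxon(self, tiny_taxonomy):
        table = kb.OtuTable.from_counts([[7]], ["s1"], ["bactB"])
        out = kb.aggregate_taxa(table, tiny_taxonomy, "order")
        assert out.loc["Flavobacteriales", "s1"] == pytest.approx(1.0)

    def test_threshold_zero_no_pooling(self, tiny_table, tiny_taxonomy):
        out = kb.aggregate_taxa(tiny_table, tiny_taxonomy, "order", min_display=0.0)
        assert "other" not in out.index or out.loc["other"].sum() == 0
        assert np.allclose(out.sum(axis=0), 1.0)

    def test_rare_taxon_pooled(self, tiny_taxonomy):
        # bactC at 0.5% in both samples, threshold 1% -> pooled into other
        table = kb.OtuTable.from_counts(
            [[995, 5], [995, 5]], ["s1", "s2"], ["bactB", "bactC"]
        )
        out = kb.aggregate_taxa(table, tiny_taxonomy, "order", min_display=0.01)
        assert "Rhodobacterales" not in out.index
        assert out.loc["other", "s1"] == pytest.approx(0.005)

    def test_unknown_rank_rejected(self, tiny_table, tiny_taxonomy):
        with pytest.raises(ValidationError):
            kb.aggregate_taxa(tiny_table, tiny_taxonomy, "strain")
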