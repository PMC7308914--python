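"""Mutual information, AMI, cluster matching, markers, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_mutual_info_score

from atacref.bus_ops import CountMatrix
from atacref.eval_metrics import (
    ami,
    ami_vs_cutoff,
    cluster_cells,
    jaccard_pairs,
    marker_concordance,
    marker_regions,
    match_clusters,
    mutual_information,
    read_labeling,
    write_labeling,
)
from atacref.reference import GenomicInterval, RegionSet

from conftest import permutation_ami


def labeling(values, cells=None):
    if cells is None:
        cells = [f"cell{i}" for i in range(len(values))]
    return pd.Series([str(v) for v in values], index=cells)


class TestMutualInformation:
    def test_identical_balanced_two_cluster_labeling(self):
        a = labeling([0, 0, 1, 1])
        assert mutual_information(a, a) == pytest.approx(math.log(2))

    def test_single_cluster_gives_zero(self):
        a = labeling([0, 0, 0, 0])
        b = labeling([0, 1, 0, 1])
        assert mutual_information(a, b) == pytest.approx(0.0)

    def test_uniform_contingency_gives_zero(self):
        a = labeling([0, 0, 1, 1])
        b = labeling([0, 1, 0, 1])
        assert mutual_information(a, b) == pytest.approx(0.0)

    def test_disjoint_cells_rejected(self):
        a = labeling([0, 1], cells=["x", "y"])
        b = labeling([0, 1], cells=["u", "v"])
        with pytest.raises(ValueError):
            mutual_information(a, b)


class TestAmi:
    def test_identical_labelings_give_one(self):
        a = labeling([0, 0, 1, 1, 2, 2])
        assert ami(a, a) == pytest.approx(1.0)

    def test_single_cluster_degenerate_gives_zero(self):
        a = labeling([0] * 6)
        b = labeling([0, 0, 1, 1, 2, 2])
        assert ami(a, b) == 0.0
        assert ami(b, a) == 0.0

    def test_matches_exhaustive_permutation_oracle(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 0, 1, 1, 1, 2]
        expected = permutation_ami(a, b)
        got = ami(labeling(a), labeling(b))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a = labeling(rng.integers(0, 4, 60))
        b = labeling(rng.integers(0, 3, 60))
        assert ami(a, b) == pytest.approx(ami(b, a), abs=1e-12)
        remap = {"0": "x", "1": "y", "2": "z", "3": "w"}
        assert ami(a.map(remap), b) == pytest.approx(ami(a, b), abs=1e-12)

    def test_agrees_with_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(20, 200))
            a = labeling(rng.integers(0, int(rng.integers(2, 7)), n))
            b = labeling(rng.integers(0, int(rng.integers(2, 7)), n))
            ref = adjusted_mutual_info_score(a.values, b.values)
            assert ami(a, b) == pytest.approx(ref, abs=1e-10)

    def test_independent_labelings_concentrate_near_zero(self):
        rng = np.random.default_rng(23)
        vals = []
        for _ in range(50):
            a = labeling(rng.integers(0, 4, 200))
            b = labeling(rng.integers(0, 4, 200))
            vals.append(ami(a, b))
        assert abs(np.mean(vals)) < 0.05


class TestMatchClusters:
    def test_identity_on_identical_labelings(self):
        a = labeling([0, 0, 1, 1, 2, 2])
        assert match_clusters(a, a) == {"0": "0", "1": "1", "2": "2"}

    def test_recovers_label_renaming(self):
        a = labeling([0, 0, 1, 1, 2, 2])
        b = a.map({"0": "x", "1": "y", "2": "z"})
        assert match_clusters(a, b) == {"0": "x", "1": "y", "2": "z"}

    def test_split_cluster_leaves_leftover_unmatched(self):
        a = labeling([0, 0, 0, 0, 1, 1, 2, 2])
        b = labeling([0, 0, 1, 1, 2, 2, 3, 3])
        m = match_clusters(a, b)
        # a0 splits evenly over b0/b1: tie broken to the smaller label b0;
        # verify by brute force that total matched overlap is maximal
        assert m["0"] == "0" and m["1"] == "2" and m["2"] == "3"
        from itertools import permutations

        av, bv = np.asarray(a.values), np.asarray(b.values)
        best = max(
            sum(
                ((av == x) & (bv == y)).sum()
                for x, y in zip(["0", "1", "2"], perm)
            )
            for perm in permutations(["0", "1", "2", "3"], 3)
        )
        got = sum(
            ((av == x) & (bv == y)).sum() for x, y in m.items() if y is not None
        )
        assert got == best


class TestJaccardPairs:
    def test_identical_labelings_have_unit_diagonal(self):
        a = labeling([0, 0, 1, 1])
        J = jaccard_pairs(a, a)
        assert J.loc["0", "0"] == 1.0 and J.loc["1", "1"] == 1.0
        assert J.loc["0", "1"] == 0.0

    def test_partial_overlap(self):
        a = labeling([0, 0, 0, 0, 1, 1], cells=list("abcdef"))
        b = labeling([0, 0, 1, 1, 0, 0], cells=list("abcdef"))
        # a-cluster 0 = {a,b,c,d}; b-cluster 0 = {a,b,e,f}: 2 shared of 6
        assert jaccard_pairs(a, b).loc["0", "0"] == pytest.approx(2 / 6)


class TestClusterCells:
    @pytest.fixture(scope="class")
    def block_matrix(self):
        rng = np.random.default_rng(3)
        # two cell blocks with disjoint accessible region sets
        a = rng.poisson(3.0, size=(30, 40))
        b = rng.poisson(3.0, size=(30, 40))
        X = np.zeros((60, 80), dtype=np.int64)
        X[:30, :40] = a
        X[30:, 40:] = b
        return CountMatrix(
            matrix=sp.csr_matrix(X),
            barcodes=[f"cb{i:03d}" for i in range(60)],
            features=[f"r{j:03d}" for j in range(80)],
        )

    def test_disjoint_blocks_separate_into_two_clusters(self, block_matrix):
        labels = cluster_cells(
            block_matrix, min_regions_per_cell=5, min_cells_per_region=2, seed=0
        )
        assert labels.nunique() == 2
        first = set(labels.iloc[:30].unique())
        second = set(labels.iloc[30:].unique())
        assert first.isdisjoint(second)

    def test_sparse_cells_filtered_out(self, block_matrix):
        labels = cluster_cells(
            block_matrix, min_regions_per_cell=5, min_cells_per_region=2, seed=0
        )
        m = block_matrix.matrix.copy().tolil()
        m[0, :] = 0
        m[0, 0] = 1  # one detected region, below threshold
        poor = CountMatrix(
            matrix=m.tocsr(),
            barcodes=block_matrix.barcodes,
            features=block_matrix.features,
        )
        labels2 = cluster_cells(
            poor, min_regions_per_cell=5, min_cells_per_region=2, seed=0
        )
        assert "cb000" in labels.index and "cb000" not in labels2.index

    def test_deterministic_under_fixed_seed(self, block_matrix):
        kw = dict(min_regions_per_cell=5, min_cells_per_region=2, seed=11)
        a = cluster_cells(block_matrix, **kw)
        b = cluster_cells(block_matrix, **kw)
        assert a.equals(b)

    def test_all_cells_filtered_is_an_error(self, block_matrix):
        with pytest.raises(ValueError):
            cluster_cells(block_matrix, min_regions_per_cell=10**6)


class TestMarkerRegions:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(8)
        n_a, n_b, n_regions = 25, 25, 30
        X = rng.poisson(1.0, size=(n_a + n_b, n_regions))
        X[:n_a, 0] += rng.poisson(20.0, size=n_a)  # r00 marks cluster A
        X[n_a:, 1] += rng.poisson(20.0, size=n_b)  # r01 marks cluster B
        matrix = CountMatrix(
            matrix=sp.csr_matrix(X),
            barcodes=[f"cb{i:03d}" for i in range(n_a + n_b)],
            features=[f"r{j:02d}" for j in range(n_regions)],
        )
        labels = labeling(["A"] * n_a + ["B"] * n_b,
                          cells=[f"cb{i:03d}" for i in range(n_a + n_b)])
        return matrix, labels

    def test_exclusive_region_ranks_first_and_is_significant(self, separable):
        matrix, labels = separable
        table = marker_regions(matrix, labels)
        top_a = table[table.cluster == "A"].iloc[0]
        assert top_a.region_id == "r00" and top_a.p_adj < 0.05

    def test_uninformative_regions_excluded(self, separable):
        matrix, labels = separable
        table = marker_regions(matrix, labels, top_n=1000)
        # regions 2.. have identical distributions across clusters
        assert len(table) < 2 * 30

    def test_top_n_truncation(self, separable):
        matrix, labels = separable
        table = marker_regions(matrix, labels, top_n=1)
        assert (table.groupby("cluster").size() <= 1).all()

    def test_single_cluster_rejected(self, separable):
        matrix, _ = separable
        only = labeling(["A"] * 50, cells=[f"cb{i:03d}" for i in range(50)])
        with pytest.raises(ValueError):
            marker_regions(matrix, only)


class TestMarkerConcordance:
    def regions(self, triples):
        return RegionSet([GenomicInterval(c, s, e) for c, s, e in triples])

    def test_identical_sets_all_overlap(self):
        rs = self.regions([("chr1", 100, 200), ("chr2", 0, 50)])
        assert marker_concordance(rs.ids, rs.ids, rs, rs) == (1.0, 0.0, 0.0)

    def test_different_chromosomes_are_none(self):
        a = self.regions([("chr1", 100, 200)])
        b = self.regions([("chr2", 100, 200)])
        assert marker_concordance(a.ids, b.ids, a, b) == (0.0, 0.0, 1.0)

    def test_near_threshold_binning(self):
        a = self.regions([("chr1", 100, 200)])
        b = self.regions([("chr1", 10200, 10300)])
        # gap = 10,000 bp
        assert marker_concordance(a.ids, b.ids, a, b, near=20000) == (0, 1.0, 0)
        assert marker_concordance(a.ids, b.ids, a, b, near=5000) == (0, 0, 1.0)

    def test_proportions_sum_to_one_and_degrade_with_jitter(self, rng):
        starts = rng.integers(0, 10**6, 50)
        a = self.regions([("chr1", int(s), int(s) + 100) for s in starts])
        overlaps = []
        for shift in (0, 50, 5000):
            b = self.regions(
                [("chr1", int(s) + shift, int(s) + shift + 100) for s in starts]
            )
            props = marker_concordance(a.ids, b.ids, a, b)
            assert sum(props) == pytest.approx(1.0)
            overlaps.append(props[0])
        assert overlaps[0] >= overlaps[1] >= overlaps[2]

    def test_empty_marker_set_rejected(self):
        rs = self.regions([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            marker_concordance([], rs.ids, rs, rs)


class TestAmiVsCutoff:
    def test_full_cutoff_matches_direct_ami(self, small_matrix, small_sim):
        ref = small_sim["truth"].labels
        kw = dict(min_regions_per_cell=50, min_cells_per_region=3)
        full_labels = cluster_cells(small_matrix, seed=4, **kw)
        curve = ami_vs_cutoff(
            small_matrix, ref, [len(small_matrix.features)], seed=4, **kw
        )
        assert len(curve) == 1
        assert curve.ami.iloc[0] == pytest.approx(ami(full_labels, ref), abs=1e-12)

    def test_cutoff_out_of_range_rejected(self, small_matrix, small_sim):
        with pytest.raises(ValueError):
            ami_vs_cutoff(small_matrix, small_sim["truth"].labels, [10**6])

    def test_reproducible_under_seed(self, small_matrix, small_sim):
        ref = small_sim["truth"].labels
        kw = dict(min_regions_per_cell=50, min_cells_per_region=3, seed=2)
        a = ami_vs_cutoff(small_matrix, ref, [100, 200], **kw)
        b = ami_vs_cutoff(small_matrix, ref, [100, 200], **kw)
        assert a.equals(b)


def test_labeling_tsv_round_trip(tmp_path):
    a = labeling([0, 1, 1], cells=["x", "y", "z"])
    p = write_labeling(a, tmp_path / "labels.tsv")
    assert read_labeling(p).equals(a)
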