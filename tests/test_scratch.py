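"""Transition points, the transition matrix and SCRATCH clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cnscratch import (BinGrid, default_grid, extract_transition_points,
                       build_transition_matrix, correlation_distance,
                       scratch_cluster, shared_transition_fraction,
                       pairwise_shared_matrix)
from cnscratch.profiles import SegmentProfile, DataError
from cnscratch.scratch import bin_shared_fraction


def seg_from_values(grid, chrom_values, sample_id="s"):
    """Build a SegmentProfile from {chrom: per-bin cn values}."""
    rows = []
    w = grid.bin_width
    for chrom, vals in chrom_values.items():
        vals = np.asarray(vals, dtype=float)
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                rows.append((chrom, start * w, i * w, start, i, i - start,
                             vals[start], vals[start]))
                start = i
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_bin",
                                     "end_bin", "n_bins", "ratio", "cn"])
    return SegmentProfile(sample_id, grid, df)


GRID2 = BinGrid(chrom_names=("chr1", "chr2"), chrom_bins=(40, 40))


class TestTransitionPoints:
    def test_single_boundary(self):
        grid = BinGrid(chrom_names=("chr1",), chrom_bins=(40,))
        seg = seg_from_values(grid, {"chr1": [2] * 20 + [3] * 20})
        tps = extract_transition_points(seg, "all")
        assert len(tps) == 1
        tp = tps[0]
        assert (tp.chrom, tp.pos, tp.left, tp.right) == ("chr1", 20 * grid.bin_width, 2, 3)
        assert tp.direction == 1

    def test_flat_chromosome_has_none(self):
        seg = seg_from_values(GRID2, {"chr1": [2] * 40, "chr2": [2] * 40})
        assert extract_transition_points(seg, "all") == []

    def test_k_segments_give_k_minus_1_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = np.repeat(rng.integers(0, 5, size=8), rng.integers(1, 6, size=8))[:40]
            vals = np.pad(vals, (0, 40 - len(vals)), constant_values=vals[-1])
            seg = seg_from_values(GRID2, {"chr1": vals, "chr2": [2] * 40})
            n_seg = len(seg.for_chrom("chr1"))
            assert len(extract_transition_points(seg, ["chr1"])) == n_seg - 1

    def test_brute_force_diff_oracle(self):
        # the extractor agrees with an adjacent-value diff over expanded bins
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = rng.integers(0, 4, size=40)
            seg = seg_from_values(GRID2, {"chr1": vals, "chr2": [2] * 40})
            tps = extract_transition_points(seg, ["chr1"])
            expect = [(i * GRID2.bin_width, vals[i - 1], vals[i])
                      for i in range(1, 40) if vals[i] != vals[i - 1]]
            assert [(tp.pos, tp.left, tp.right) for tp in tps] == expect

    def test_autosome_default_excludes_chrx(self):
        grid = default_grid()
        nx = grid.n_chrom_bins("chrX")
        seg = seg_from_values(grid, {c: [2] * grid.n_chrom_bins(c)
                                     for c in grid.chrom_names if c != "chrX"}
                              | {"chrX": [1] * (nx // 2) + [2] * (nx - nx // 2)})
        assert extract_transition_points(seg) == []
        assert len(extract_transition_points(seg, "chrX")) == 1


class TestTransitionMatrix:
    def test_identical_profiles_identical_rows(self):
        a = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "a")
        b = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "b")
        tm = build_transition_matrix([a, b], "all")
        np.testing.assert_array_equal(tm.values[0], tm.values[1])

    def test_covering_segment_value_used_without_own_boundary(self):
        a = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "a")
        b = seg_from_values(GRID2, {"chr1": [5] * 40, "chr2": [2] * 40}, "b")
        tm = build_transition_matrix([a, b], "all")
        assert tm.boundaries == [("chr1", 10 * GRID2.bin_width)]
        assert tm.values[0, 0] == 3  # value right of the boundary
        assert tm.values[1, 0] == 5  # covering segment of the other sample

    def test_matrix_matches_planted_events(self, default_tree, called_profiles):
        tm = build_transition_matrix(called_profiles, "autosomes")
        # every entry equals that sample's true copy number at the boundary
        grid = default_tree.grid
        errs = []
        for i, prof in enumerate(called_profiles):
            truth = default_tree.total_copies(prof.sample_id)
            for j, (chrom, pos) in enumerate(tm.boundaries):
                g = grid.offsets[chrom] + pos // grid.bin_width
                errs.append(abs(tm.values[i, j] - truth[g]))
        assert np.median(errs) < 0.25

    def test_grid_mismatch_raises(self):
        a = seg_from_values(GRID2, {"chr1": [2] * 40, "chr2": [2] * 40}, "a")
        other = BinGrid(chrom_names=("chr1", "chr2"), chrom_bins=(30, 30))
        b = seg_from_values(other, {"chr1": [2] * 30, "chr2": [2] * 30}, "b")
        with pytest.raises(DataError):
            build_transition_matrix([a, b], "all")


class TestCorrelationDistance:
    def _tm(self, rows):
        from cnscratch.scratch import TransitionMatrix
        rows = np.asarray(rows, dtype=float)
        return TransitionMatrix([f"s{i}" for i in range(len(rows))],
                                [("chr1", (j + 1) * 500_000) for j in range(rows.shape[1])],
                                rows)

    def test_identical_rows_zero(self):
        d = correlation_distance(self._tm([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == pytest.approx(0.0)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        d = correlation_distance(self._tm([x, 3 * x + 2]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_two(self):
        d = correlation_distance(self._tm([[1, 2, 3], [3, 2, 1]]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_zero_variance_row_warns_max_distance(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = correlation_distance(self._tm([[1, 2, 3], [2, 2, 2]]))
        assert d[0, 1] == 2.0


class TestScratchCluster:
    def test_recovers_planted_clusters(self, default_tree, called_profiles):
        tm = build_transition_matrix(called_profiles, "autosomes")
        tree = scratch_cluster(correlation_distance(tm), tm.sample_ids)
        truth = [default_tree.cluster_of[s] for s in tm.sample_ids]
        pred = [tree.labels[s] for s in tm.sample_ids]
        assert tree.k == 3
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_singleton_merged_into_sister_clade(self):
        # two tight pairs plus one outlier: the outlier joins its sister
        d = np.array([
            [0.0, 0.1, 0.9, 0.9, 0.8],
            [0.1, 0.0, 0.9, 0.9, 0.8],
            [0.9, 0.9, 0.0, 0.1, 0.5],
            [0.9, 0.9, 0.1, 0.0, 0.5],
            [0.8, 0.8, 0.5, 0.5, 0.0],
        ])
        tree = scratch_cluster(d, ["a", "b", "c", "d", "e"], k_max=4)
        sizes = {}
        for lab in tree.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        assert min(sizes.values()) >= 2
        assert tree.labels["e"] == tree.labels["c"] == tree.labels["d"]

    def test_all_identical_single_cluster(self):
        d = np.zeros((4, 4))
        tree = scratch_cluster(d, list("abcd"))
        assert tree.k == 1

    def test_small_n_single_cluster_with_warning(self):
        with pytest.warns(UserWarning):
            tree = scratch_cluster(np.zeros((2, 2)), ["a", "b"])
        assert tree.k == 1

    def test_input_order_invariance(self, default_tree, called_profiles):
        tm = build_transition_matrix(called_profiles, "autosomes")
        d = correlation_distance(tm)
        base = scratch_cluster(d, tm.sample_ids)
        base_map = {s: base.labels[s] for s in tm.sample_ids}
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = rng.permutation(len(tm.sample_ids))
            ids = [tm.sample_ids[i] for i in perm]
            dp = d[np.ix_(perm, perm)]
            t = scratch_cluster(dp, ids)
            # same partition up to label renaming
            pairs_base = {(a, b): base_map[a] == base_map[b]
                          for i, a in enumerate(tm.sample_ids)
                          for b in tm.sample_ids[i + 1:]}
            for (a, b), same in pairs_base.items():
                assert (t.labels[a] == t.labels[b]) == same


class TestSharing:
    def test_subset_query_full_sharing(self):
        q = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "q")
        t1 = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 20 + [4] * 10,
                                     "chr2": [2] * 40}, "t1")
        for mode in ("any", "all"):
            assert shared_transition_fraction(q, [t1], mode=mode) == 1.0

    def test_disjoint_boundaries_zero(self):
        q = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "q")
        t = seg_from_values(GRID2, {"chr1": [2] * 25 + [3] * 15, "chr2": [2] * 40}, "t")
        assert shared_transition_fraction(q, [t]) == 0.0

    def test_direction_matching(self):
        q = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "q")
        t = seg_from_values(GRID2, {"chr1": [3] * 10 + [2] * 30, "chr2": [2] * 40}, "t")
        assert shared_transition_fraction(q, [t], match_direction=True) == 0.0
        assert shared_transition_fraction(q, [t], match_direction=False) == 1.0

    def test_zero_tp_query_is_nan(self):
        q = seg_from_values(GRID2, {"chr1": [2] * 40, "chr2": [2] * 40}, "q")
        t = seg_from_values(GRID2, {"chr1": [2] * 40, "chr2": [2] * 40}, "t")
        with pytest.warns(UserWarning):
            assert np.isnan(shared_transition_fraction(q, [t]))

    def test_cumulative_union_detection_is_monotone(self, called_profiles):
        query, rest = called_profiles[0], called_profiles[1:]
        fracs = [shared_transition_fraction(query, rest[:k], mode="any")
                 for k in range(1, len(rest) + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    @pytest.mark.parametrize("f,expected", [
        (1.0, ">80%"), (0.81, ">80%"), (0.8, "20-80%"), (0.5, "20-80%"),
        (0.2, "20-80%"), (0.19, "<20%"), (0.0, "<20%")])
    def test_sharing_bins(self, f, expected):
        assert bin_shared_fraction(f) == expected

    def test_pairwise_matrix_symmetric_and_binned(self, called_profiles):
        frac, cats = pairwise_shared_matrix(called_profiles[:6])
        np.testing.assert_allclose(frac, frac.T)
        assert np.isin(cats, ["<20%", "20-80%", ">80%", "NA"]).all()
        a = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "a")
        b = seg_from_values(GRID2, {"chr1": [2] * 10 + [3] * 30, "chr2": [2] * 40}, "b")
        frac2, cats2 = pairwise_shared_matrix([a, b])
        assert frac2[0, 1] == 1.0 and cats2[0, 1] == ">80%"
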