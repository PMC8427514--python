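"""Cross-epigenome enhancer atlas: presence matrix, specificity, similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from epiatlas.chromatin import StateSegmentation
from epiatlas.enhancers import (
    PresenceMatrix,
    active_enhancer_bins,
    build_presence_matrix,
    epigenome_similarity,
    kmeans_enhancer_clusters,
    link_genes_to_enhancers,
    rpkm,
    shared_fraction,
    specific_enhancers,
)
from epiatlas.genome import GenomeAssembly, IntervalSet, bin_genome
from epiatlas.simulate import simulate_assembly, simulate_epigenome_panel

MN = ("9_EnhA1", "10_EnhA2", "7_EnhG1", "18_Quies")


def seg_from_labels(labels, bins):
    lookup = {m: i for i, m in enumerate(MN)}
    return StateSegmentation(np.array([lookup[v] for v in labels]), bins, MN)


@pytest.fixture
def small_bins():
    return bin_genome(GenomeAssembly(("c",), (2000,)), 200)


class TestActiveBins:
    def test_enhancer_interval_sets_bins(self, small_bins):
        labels = ["9_EnhA1"] * 3 + ["18_Quies"] * 7
        vec = active_enhancer_bins(seg_from_labels(labels, small_bins), small_bins)
        assert vec.tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_genic_enhancers_not_in_active_set(self, small_bins):
        labels = ["7_EnhG1"] * 10
        vec = active_enhancer_bins(seg_from_labels(labels, small_bins), small_bins)
        assert vec.sum() == 0

    def test_no_enhancer_states_zero_vector(self, small_bins):
        vec = active_enhancer_bins(seg_from_labels(["18_Quies"] * 10, small_bins), small_bins)
        assert vec.sum() == 0

    def test_unknown_mnemonic_rejected(self, small_bins):
        seg = seg_from_labels(["18_Quies"] * 10, small_bins)
        with pytest.raises(ValueError):
            active_enhancer_bins(seg, small_bins, states=("99_Nope",))


class TestPresenceMatrix:
    def panel(self, small_bins, columns):
        segs = {}
        for eid, active in columns.items():
            labels = ["9_EnhA1" if a else "18_Quies" for a in active]
            segs[eid] = seg_from_labels(labels, small_bins)
        return build_presence_matrix(segs, ("9_EnhA1",))

    def test_row_count_is_union_popcount(self, small_bins):
        pm = self.panel(
            small_bins,
            {"a": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0], "b": [0, 1, 1, 0, 0, 0, 0, 0, 0, 0]},
        )
        assert len(pm.bin_ordinals) == 3
        assert pm.values.sum() == 4

    def test_identical_epigenomes_identical_columns(self, small_bins):
        col = [1, 0, 1, 0, 0, 0, 0, 0, 1, 0]
        pm = self.panel(small_bins, {"a": col, "b": col})
        np.testing.assert_array_equal(pm.values[:, 0], pm.values[:, 1])

    def test_all_zero_rows_excluded_by_construction(self, small_bins):
        pm = self.panel(small_bins, {"a": [1] + [0] * 9, "b": [0] * 10})
        assert (pm.values.sum(axis=1) > 0).all()


class TestSpecificEnhancers:
    def test_planted_exclusive_bins_recovered_exactly(self):
        assembly = simulate_assembly()
        segs, truth, bins = simulate_epigenome_panel(
            assembly, n_epigenomes=20, seed=1, planted_specific=200
        )
        pm = build_presence_matrix(segs, ("9_EnhA1",))
        target = next(iter(truth.specific_bins))
        result = specific_enhancers(pm, target)
        mask = np.zeros(bins.n_bins, dtype=np.uint8)
        mask[truth.specific_bins[target]] = 1
        from epiatlas.genome import merge_bins

        assert result == merge_bins(mask, bins)

    def test_bin_shared_with_one_other_excluded(self, small_bins):
        pm = PresenceMatrix(
            np.array([0, 1]),
            ("a", "b"),
            np.array([[1, 1], [1, 0]], dtype=np.uint8),
            small_bins,
        )
        out = specific_enhancers(pm, "a")
        assert out.df.values.tolist() == [["c", 200, 400]]

    def test_reprojection_column_sum_is_one(self):
        assembly = simulate_assembly()
        segs, truth, bins = simulate_epigenome_panel(assembly, seed=2, planted_specific=50)
        pm = build_presence_matrix(segs, ("9_EnhA1",))
        target = next(iter(truth.specific_bins))
        out = specific_enhancers(pm, target)
        from epiatlas.genome import intervals_to_bins

        chosen = intervals_to_bins(out, bins).astype(bool)
        row_of = {o: i for i, o in enumerate(pm.bin_ordinals)}
        sums = [pm.values[row_of[o]].sum() for o in np.flatnonzero(chosen)]
        assert set(sums) == {1}

    def test_absent_target_rejected(self, small_bins):
        pm = PresenceMatrix(np.array([0]), ("a",), np.ones((1, 1), np.uint8), small_bins)
        with pytest.raises(KeyError):
            specific_enhancers(pm, "zzz")


class TestSharedFraction:
    def test_constructed_fraction(self, small_bins):
        values = np.ones((10, 3), dtype=np.uint8)
        values[3:, 0] = 1
        values[[4, 6, 8, 9, 0, 1, 2], 1] = 1
        values[:7, 2] = 0
        values[:, :] = 1
        values[:7, 2] = 0  # 3 of 10 rows all-one
        pm = PresenceMatrix(np.arange(10), ("a", "b", "c"), values, small_bins)
        assert shared_fraction(pm) == pytest.approx(0.3)

    def test_identical_and_disjoint_limits(self, small_bins):
        ones = PresenceMatrix(np.arange(4), ("a", "b"), np.ones((4, 2), np.uint8), small_bins)
        assert shared_fraction(ones) == 1.0
        disj = PresenceMatrix(
            np.arange(4), ("a", "b"),
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]], np.uint8), small_bins,
        )
        assert shared_fraction(disj) == 0.0


class TestSimilarity:
    def make_pm(self, values, small_bins):
        values = np.asarray(values, dtype=np.uint8)
        ids = tuple(f"e{i}" for i in range(values.shape[1]))
        return PresenceMatrix(np.arange(values.shape[0]), ids, values, small_bins)

    def test_correlation_symmetric_unit_diagonal(self, small_bins, rng):
        pm = self.make_pm(rng.integers(0, 2, (10, 4)), small_bins)
        # guard against all-zero rows
        pm.values[pm.values.sum(axis=1) == 0, 0] = 1
        r, _, _ = epigenome_similarity(pm)
        np.testing.assert_allclose(r.values, r.values.T)
        np.testing.assert_allclose(np.diag(r.values), 1.0)

    def test_planted_groups_recovered_at_cut(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(5)
        bins = bin_genome(GenomeAssembly(("c",), (200 * 300,)), 200)
        base = rng.integers(0, 2, (300, 3)).astype(np.uint8)
        cols, truth = [], []
        for g in range(3):
            for _ in range(4):
                col = base[:, g].copy()
                flip = rng.random(300) < 0.02
                col[flip] ^= 1
                cols.append(col)
                truth.append(g)
        values = np.stack(cols, axis=1)
        keep = values.sum(axis=1) > 0
        pm = PresenceMatrix(np.flatnonzero(keep), tuple(f"e{i}" for i in range(12)),
                            values[keep], bins)
        _, z, _ = epigenome_similarity(pm)
        labels = fcluster(z, 3, criterion="maxclust")
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_mds_distances_track_input(self):
        rng = np.random.default_rng(6)
        bins = bin_genome(GenomeAssembly(("c",), (200 * 500,)), 200)
        # planted 2-D structure: two anchor profiles and mixtures of them
        a = rng.integers(0, 2, 500)
        b = rng.integers(0, 2, 500)
        cols = []
        for w in np.linspace(0, 1, 8):
            mix = np.where(rng.random(500) < w, a, b)
            cols.append(mix)
        values = np.stack(cols, axis=1).astype(np.uint8)
        keep = values.sum(axis=1) > 0
        pm = PresenceMatrix(np.flatnonzero(keep), tuple(f"e{i}" for i in range(8)),
                            values[keep], bins)
        r, _, coords = epigenome_similarity(pm)
        d_in = 1 - r.values
        d_out = np.sqrt(
            ((coords.values[:, None, :] - coords.values[None, :, :]) ** 2).sum(-1)
        )
        iu = np.triu_indices(8, 1)
        rho = spearmanr(d_in[iu], d_out[iu]).statistic
        assert rho >= 0.9

    def test_constant_column_named_in_error(self, small_bins):
        pm = self.make_pm(np.ones((5, 3)), small_bins)
        with pytest.raises(ValueError, match="e0"):
            epigenome_similarity(pm)


class TestRPKM:
    def regions(self, lengths):
        rows, start = [], 0
        for ln in lengths:
            rows.append(("c", start, start + ln))
            start += ln + 100
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10]})
        out = rpkm(counts, self.regions([1000]), {"s": 1e7})
        assert out.loc[0, "s"] == pytest.approx(1.0)

    def test_scale_invariance_and_zero(self):
        counts = pd.DataFrame({"s": [10, 0]})
        r = self.regions([1000, 500])
        a = rpkm(counts, r, {"s": 1e7})
        b = rpkm(counts * 2, r, {"s": 2e7})
        pd.testing.assert_frame_equal(a, b)
        assert a.loc[1, "s"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s": [1]}), self.regions([100]), {"s": 0})


class TestKMeans:
    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(7)
        blocks = []
        truth = []
        for g in range(3):
            X = rng.normal(0, 0.1, (60, 3))
            X[:, g] += 5.0 + g  # tissue-exclusive high column, distinct means
            blocks.append(X)
            truth += [g] * 60
        sm = pd.DataFrame(np.vstack(blocks), columns=list("abc"))
        labels = kmeans_enhancer_clusters(sm, k=3, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_seed_deterministic_and_ordered_by_intensity(self):
        rng = np.random.default_rng(8)
        sm = pd.DataFrame(rng.random((40, 2)))
        a = kmeans_enhancer_clusters(sm, k=4, seed=3)
        b = kmeans_enhancer_clusters(sm, k=4, seed=3)
        np.testing.assert_array_equal(a, b)
        means = [sm.to_numpy()[a == c].mean() for c in sorted(set(a))]
        assert means == sorted(means, reverse=True)

    def test_k_equals_n_regions(self):
        sm = pd.DataFrame({"x": [0.0, 10.0, 20.0]})
        labels = kmeans_enhancer_clusters(sm, k=3, seed=0)
        assert len(set(labels)) == 3

    def test_bad_k_rejected(self):
        sm = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            kmeans_enhancer_clusters(sm, k=1)
        with pytest.raises(ValueError):
            kmeans_enhancer_clusters(sm, k=5)


class TestLinking:
    def genes(self, tss_list):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(tss_list))],
                "chrom": "c",
                "strand": "+",
                "tss": tss_list,
                "tes": [t + 100 for t in tss_list],
            }
        )

    def enh(self, rows):
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def test_window_boundary_half_open(self):
        genes = self.genes([50_000])
        # enhancer ending exactly at TSS-20000: no overlap with [30000, 70000)
        flags, frac = link_genes_to_enhancers(genes, self.enh([("c", 29_000, 30_000)]))
        assert not flags.iloc[0]
        flags, _ = link_genes_to_enhancers(genes, self.enh([("c", 29_000, 30_001)]))
        assert flags.iloc[0]

    def test_enhancer_containing_tss_links(self):
        flags, _ = link_genes_to_enhancers(
            self.genes([50_000]), self.enh([("c", 49_900, 50_100)])
        )
        assert flags.iloc[0]

    def test_fraction_89_of_103(self):
        # fixture shaped like the prostate-specific gene panel: 103 genes,
        # 89 with an enhancer in the TSS window
        tss = [100_000 + 50_000 * i for i in range(103)]
        genes = self.genes(tss)
        enh_rows = [("c", t - 1000, t - 500) for t in tss[:89]]
        flags, frac = link_genes_to_enhancers(genes, self.enh(enh_rows))
        assert flags.sum() == 89
        assert frac == pytest.approx(89 / 103, abs=1e-9)

    def test_fraction_monotone_in_flank(self):
        genes = self.genes([10_000, 80_000, 200_000])
        enh = self.enh([("c", 0, 500), ("c", 120_000, 120_400)])
        fracs = [
            link_genes_to_enhancers(genes, enh, flank=f)[1]
            for f in (1_000, 20_000, 50_000, 120_000)
        ]
        assert fracs == sorted(fracs)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            link_genes_to_enhancers(self.genes([]), self.enh([("c", 0, 100)]))
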