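"""Chromatin-state model: binarization, HMM inference, training, enrichment."""

import numpy as np
import pandas as pd
import pytest
import warnings

from epiatlas.chromatin import (
    BinnedTrack,
    HMMModel,
    StateSegmentation,
    aggregate_signal_by_state,
    binarize_track,
    load_chromhmm_model,
    load_model_tables,
    neighborhood_enrichment,
    overlap_enrichment,
    posterior_marginals,
    save_chromhmm_model,
    segment,
    state_coverage,
    train_model,
)
from epiatlas.genome import GenomeAssembly, IntervalSet, bin_genome
from epiatlas.simulate import example_model, simulate_assembly, simulate_marks
from .oracles import brute_force_posteriors, random_model, tracks_from_matrix


class TestBinarize:
    def make(self, values, length=2000):
        bins = bin_genome(GenomeAssembly(("c",), (length,)), 200)
        return BinnedTrack("H3K27ac", np.asarray(values), bins)

    def test_constant_background_never_called(self):
        # P(X >= 5 | lambda=5) ~ 0.56, far above 1e-4
        out = binarize_track(self.make(np.full(10, 5)))
        assert out.binary and out.values.sum() == 0

    def test_strong_spike_called(self):
        v = np.full(10, 5)
        v[4] = 40
        out = binarize_track(self.make(v))
        assert out.values.tolist() == [0, 0, 0, 0, 1, 0, 0, 0, 0, 0]

    def test_signal_equal_to_control_all_zero(self):
        sig = self.make(np.array([3, 8, 2, 9, 4, 5, 7, 1, 6, 5]))
        ctrl = self.make(sig.values.copy())
        # expectation is floored at the global mean, so nothing is enriched
        assert binarize_track(sig, ctrl).values.sum() == 0

    def test_all_zero_signal_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = binarize_track(self.make(np.zeros(10, dtype=int)))
        assert out.values.sum() == 0

    def test_monotone_in_count(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(5, 50)
        base = binarize_track(self.make(v, length=10_000)).values
        v2 = v.copy()
        v2[7] += 200
        bumped = binarize_track(self.make(v2, length=10_000)).values
        # raising a bin's count never flips an existing call off at that bin
        assert bumped[7] >= base[7]


class TestModelIO:
    def test_round_trip_at_10_digits(self, tmp_path, rng):
        model = random_model(rng, 3, 4)
        path = tmp_path / "model.txt"
        save_chromhmm_model(model, path)
        back = load_chromhmm_model(path, mnemonics=model.mnemonics)
        assert back.marks == model.marks
        np.testing.assert_allclose(back.transitions, model.transitions, rtol=1e-9)
        np.testing.assert_allclose(back.emissions, model.emissions, rtol=1e-9)
        np.testing.assert_allclose(back.initial, model.initial, rtol=1e-9)
        # writing again is byte-identical
        path2 = tmp_path / "model2.txt"
        save_chromhmm_model(back, path2)
        assert path.read_text() == path2.read_text()

    def test_missing_probinit_becomes_uniform(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "transitionprobs\t1\t1\t0.9\ntransitionprobs\t1\t2\t0.1\n"
            "transitionprobs\t2\t1\t0.2\ntransitionprobs\t2\t2\t0.8\n"
            "emissionprobs\t1\t0\tmark\t1\t0.7\nemissionprobs\t2\t0\tmark\t1\t0.2\n"
        )
        model = load_chromhmm_model(path)
        np.testing.assert_allclose(model.initial, [0.5, 0.5])
        np.testing.assert_allclose(model.transitions, [[0.9, 0.1], [0.2, 0.8]])

    def test_bad_emission_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "transitionprobs\t1\t1\t1.0\nemissionprobs\t1\t0\tmark\t1\t1.2\n"
        )
        with pytest.raises(ValueError):
            load_chromhmm_model(path)

    def test_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "transitionprobs\t1\t1\t0.5\ntransitionprobs\t1\t2\t0.4\n"
            "transitionprobs\t2\t1\t0.5\ntransitionprobs\t2\t2\t0.5\n"
            "emissionprobs\t1\t0\tmark\t1\t0.5\nemissionprobs\t2\t0\tmark\t1\t0.5\n"
        )
        with pytest.raises(ValueError, match="sum"):
            load_chromhmm_model(path)

    def test_paired_tsv_tables(self, tmp_path):
        em = pd.DataFrame([[0.9, 0.1], [0.2, 0.8]], index=["A", "B"], columns=["m1", "m2"])
        tr = pd.DataFrame([[0.95, 0.05], [0.1, 0.9]], index=["A", "B"], columns=["A", "B"])
        em.to_csv(tmp_path / "em.tsv", sep="\t")
        tr.to_csv(tmp_path / "tr.tsv", sep="\t")
        model = load_model_tables(tmp_path / "em.tsv", tmp_path / "tr.tsv")
        assert model.mnemonics == ("A", "B")
        np.testing.assert_allclose(model.emissions, em.values)


class TestPosteriorDecoding:
    def test_matches_exhaustive_enumeration(self):
        # small instances where every state path can be enumerated
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            model = random_model(rng)
            assembly = GenomeAssembly(("c",), (n * 200,))
            bins = bin_genome(assembly, 200)
            X = rng.integers(0, 2, (n, 2)).astype(np.uint8)
            tracks = tracks_from_matrix(X, bins, model.marks)
            post, _ = posterior_marginals(tracks, model)
            expected = brute_force_posteriors(X.astype(float), model.initial,
                                              model.transitions, model.emissions)
            assert np.abs(post - expected).max() < 1e-10

    def test_posteriors_sum_to_one(self, rng):
        model = random_model(rng, 4, 3)
        assembly = GenomeAssembly(("c1", "c2"), (20_000, 10_000))
        bins = bin_genome(assembly, 200)
        X = rng.integers(0, 2, (bins.n_bins, 3)).astype(np.uint8)
        post, _ = posterior_marginals(tracks_from_matrix(X, bins, model.marks), model)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_model_ties_break_low(self):
        # identical emissions + uniform transitions: every posterior uniform
        model = HMMModel(
            marks=("m",),
            initial=np.array([0.5, 0.5]),
            transitions=np.full((2, 2), 0.5),
            emissions=np.array([[0.3], [0.3]]),
            mnemonics=("A", "B"),
        )
        bins = bin_genome(GenomeAssembly(("c",), (1000,)), 200)
        X = np.array([[1], [0], [1], [1], [0]], dtype=np.uint8)
        seg = segment(tracks_from_matrix(X, bins, model.marks), model)
        assert (seg.states == 0).all()

    def test_well_separated_model_recovers_states(self):
        model = example_model(5)
        assembly = simulate_assembly(1, [2_000_000])
        tracks, truth, bins = simulate_marks(model, assembly, seed=7)
        seg = segment(tracks, model)
        assert (seg.states == truth).mean() >= 0.90

    def test_mark_mismatch_reported(self, rng):
        model = random_model(rng, 2, 2)
        bins = bin_genome(GenomeAssembly(("c",), (1000,)), 200)
        bad = [BinnedTrack("other", np.zeros(5, dtype=int), bins, binary=True)]
        with pytest.raises(ValueError, match="missing marks"):
            segment(bad, model)


class TestSegmentationObject:
    def test_intervals_tile_each_chromosome(self, rng):
        model = random_model(rng, 3, 2)
        assembly = GenomeAssembly(("c1", "c2"), (5000, 2100))
        bins = bin_genome(assembly, 200)
        X = rng.integers(0, 2, (bins.n_bins, 2)).astype(np.uint8)
        seg = segment(tracks_from_matrix(X, bins, model.marks), model)
        iv = seg.intervals()
        for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
            sub = iv.df[iv.df["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0 and sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_round_trip_through_bed_intervals(self, rng):
        model = random_model(rng, 3, 2)
        bins = bin_genome(GenomeAssembly(("c",), (4000,)), 200)
        X = rng.integers(0, 2, (bins.n_bins, 2)).astype(np.uint8)
        seg = segment(tracks_from_matrix(X, bins, model.marks), model)
        back = StateSegmentation.from_intervals(seg.intervals(), bins, model.mnemonics)
        assert (back.states == seg.states).all()


class TestTraining:
    def test_recovers_planted_two_state_model(self):
        truth = HMMModel(
            marks=("m1", "m2"),
            initial=np.array([0.5, 0.5]),
            transitions=np.array([[0.95, 0.05], [0.05, 0.95]]),
            emissions=np.array([[0.9, 0.9], [0.1, 0.1]]),
            mnemonics=("hot", "cold"),
        )
        assembly = simulate_assembly(1, [10_000_000])  # 50,000 bins
        tracks, _, _ = simulate_marks(truth, assembly, seed=3)
        model = train_model(tracks, 2, seed=0)
        # best state permutation
        direct = np.abs(model.emissions - truth.emissions).max()
        flipped = np.abs(model.emissions[::-1] - truth.emissions).max()
        assert min(direct, flipped) <= 0.05

    def test_loglik_monotone_and_seed_deterministic(self):
        model = example_model(3)
        tracks, _, _ = simulate_marks(model, simulate_assembly(1, [400_000]), seed=5)
        a = train_model(tracks, 3, seed=11, max_iter=30)
        b = train_model(tracks, 3, seed=11, max_iter=30)
        assert (np.diff(a.loglik_trace) >= -1e-9).all()
        np.testing.assert_array_equal(a.emissions, b.emissions)
        np.testing.assert_array_equal(a.transitions, b.transitions)

    def test_all_zero_observations_degenerate_but_stable(self):
        bins = bin_genome(GenomeAssembly(("c",), (20_000,)), 200)
        tracks = [BinnedTrack("m", np.zeros(100, dtype=int), bins, binary=True)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k-means convergence chatter on constant data
            model = train_model(tracks, 2, seed=0, max_iter=20)
        assert model.emissions.max() <= 1e-5

    def test_rejects_degenerate_requests(self):
        bins = bin_genome(GenomeAssembly(("c",), (1000,)), 200)
        tracks = [BinnedTrack("m", np.zeros(5, dtype=int), bins, binary=True)]
        with pytest.raises(ValueError):
            train_model(tracks, 1, seed=0)
        with pytest.raises(ValueError):
            train_model(tracks, 10, seed=0)


def make_labeled_segmentation():
    # 10 bins on one chromosome: states 0,0,0,1,1,1,1,2,2,2
    bins = bin_genome(GenomeAssembly(("c",), (2000,)), 200)
    states = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
    return StateSegmentation(states, bins, ("A", "B", "C")), bins


class TestEnrichment:
    def test_whole_genome_annotation_gives_unit_folds(self):
        seg, _ = make_labeled_segmentation()
        ann = IntervalSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000]}))
        folds = overlap_enrichment(seg, ann)
        np.testing.assert_allclose(folds.to_numpy(), 1.0)

    def test_state_own_bins_give_inverse_coverage(self):
        seg, _ = make_labeled_segmentation()
        ann = IntervalSet(pd.DataFrame({"chrom": ["c"], "start": [600], "end": [1400]}))
        folds = overlap_enrichment(seg, ann)
        assert folds["B"] == pytest.approx(1 / 0.4, abs=1e-9)
        assert folds["A"] == 0.0  # disjoint state

    def test_empty_annotation_rejected(self):
        seg, _ = make_labeled_segmentation()
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError):
            overlap_enrichment(seg, empty)

    def test_absent_state_is_nan_not_zero(self):
        bins = bin_genome(GenomeAssembly(("c",), (1000,)), 200)
        seg = StateSegmentation(np.zeros(5, dtype=int), bins, ("A", "B"))
        ann = IntervalSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]}))
        folds = overlap_enrichment(seg, ann)
        assert folds["A"] == 1.0 and np.isnan(folds["B"])

    def test_enrichment_invariant_to_chromosome_order(self, rng):
        a1 = GenomeAssembly(("c1", "c2"), (2000, 2000))
        a2 = GenomeAssembly(("c2", "c1"), (2000, 2000))
        states = rng.integers(0, 3, 20)
        ann_df = pd.DataFrame(
            {"chrom": ["c1", "c2"], "start": [200, 600], "end": [1000, 1600]}
        )
        folds = {}
        for asm in (a1, a2):
            bins = bin_genome(asm, 200)
            per_chrom = {"c1": states[:10], "c2": states[10:]}
            vec = np.concatenate([per_chrom[c] for c in asm.chrom_names])
            seg = StateSegmentation(vec, bins, ("A", "B", "C"))
            folds[asm.chrom_names] = overlap_enrichment(seg, IntervalSet(ann_df))
        pd.testing.assert_series_equal(folds[a1.chrom_names], folds[a2.chrom_names])


class TestNeighborhood:
    def test_single_state_genome_all_ones(self):
        bins = bin_genome(GenomeAssembly(("c",), (10_000,)), 200)
        seg = StateSegmentation(np.zeros(50, dtype=int), bins, ("A",))
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [5000], "strand": ["+"]})
        mat = neighborhood_enrichment(seg, anchors)
        np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_anchor_at_state_block_start(self):
        seg, _ = make_labeled_segmentation()
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [600], "strand": ["+"]})
        mat = neighborhood_enrichment(seg, anchors, flank=200, step=200)
        assert mat.loc["B", 0] == pytest.approx(1 / 0.4)

    def test_minus_strand_mirrors_plus(self):
        seg, _ = make_labeled_segmentation()
        plus = neighborhood_enrichment(
            seg, pd.DataFrame({"chrom": ["c"], "pos": [1000], "strand": ["+"]}),
            flank=400, step=200,
        )
        minus = neighborhood_enrichment(
            seg, pd.DataFrame({"chrom": ["c"], "pos": [1000], "strand": ["-"]}),
            flank=400, step=200,
        )
        np.testing.assert_allclose(plus.to_numpy(), minus.to_numpy()[:, ::-1])

    def test_no_anchors_rejected(self):
        seg, _ = make_labeled_segmentation()
        with pytest.raises(ValueError):
            neighborhood_enrichment(seg, pd.DataFrame(columns=["chrom", "pos", "strand"]))


class TestCoverageAndSignal:
    def test_coverage_fractions(self):
        seg, _ = make_labeled_segmentation()
        cov = state_coverage(seg)
        np.testing.assert_allclose(cov.to_numpy(), [0.3, 0.4, 0.3])
        assert cov.sum() == pytest.approx(1.0, abs=1e-9)

    def test_median_by_state_and_missing_state(self):
        seg, _ = make_labeled_segmentation()
        chroms = ["c"] * 4
        positions = np.array([100, 300, 700, 900])  # states A, A, B, B
        values = np.array([0.9, 0.8, 0.1, 0.2])
        out = aggregate_signal_by_state(seg, chroms, positions, values)
        assert out["A"] == pytest.approx(0.85)
        assert out["B"] == pytest.approx(0.15)
        assert np.isnan(out["C"])  # no CpGs in C: missing, not zero

    def test_matches_brute_force_filter(self, rng):
        seg, bins = make_labeled_segmentation()
        positions = rng.integers(0, 2000, 200)
        values = rng.random(200)
        out = aggregate_signal_by_state(seg, ["c"] * 200, positions, values, "mean")
        for s, name in enumerate(("A", "B", "C")):
            sel = [v for p, v in zip(positions, values) if seg.states[p // 200] == s]
            assert out[name] == pytest.approx(np.mean(sel))

    def test_invalid_statistic_rejected(self):
        seg, _ = make_labeled_segmentation()
        with pytest.raises(ValueError):
            aggregate_signal_by_state(seg, ["c"], np.array([0]), np.array([1.0]), "max")
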