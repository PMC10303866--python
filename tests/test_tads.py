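"""Insulation scores, boundary calling, TAD scores, ATA."""

import numpy as np
import pytest

from vermicelli.errors import DegenerateInputError, ParameterError
from vermicelli.hic import ContactMatrix, ice_balance
from vermicelli.io import make_bins
from vermicelli.simulate import HiCSimParams, simulate_contact_map
from vermicelli.tads import (
    TadSet,
    aggregate_tads,
    call_boundaries,
    insulation_score,
    tad_length_stats,
    tad_score,
    tads_from_boundaries,
)

BS = 40_000


def _matrix(counts):
    n = counts.shape[0]
    return ContactMatrix(counts, make_bins({"c": n * BS}, BS))


class TestInsulationScore:
    def test_uniform_matrix_scores_zero(self):
        prof = insulation_score(_matrix(np.ones((40, 40))), window=5 * BS)
        valid = ~np.isnan(prof.score)
        assert valid.sum() > 0
        assert np.allclose(prof.score[valid], 0.0, atol=1e-12)

    def test_two_tad_block_has_unique_minimum_at_boundary(self):
        n = 40
        m = np.ones((n, n))
        m[:20, :20] = 10.0
        m[20:, 20:] = 10.0
        prof = insulation_score(_matrix(m), window=5 * BS)
        assert np.nanargmin(prof.score) == 20
        # brute-force window means on the raw matrix
        w = 5
        raws = {i: m[i - w:i, i:i + w].mean() for i in range(w, n - w + 1)}
        chrom_mean = np.mean(list(raws.values()))
        for i, raw in raws.items():
            assert prof.score[i] == pytest.approx(np.log2(raw / chrom_mean),
                                                  abs=1e-12)

    def test_matches_brute_force_on_random_matrix(self, random_symmetric):
        cm = random_symmetric(60, seed=11)
        w = 6
        prof = insulation_score(cm, window=w * BS)
        n = 60
        raws = np.array([cm.counts[i - w:i, i:i + w].mean()
                         for i in range(w, n - w + 1)])
        expect = np.log2(raws / raws.mean())
        assert np.allclose(prof.score[w:n - w + 1], expect, atol=1e-12)

    def test_window_not_multiple_of_bin_rejected(self, random_symmetric):
        with pytest.raises(ParameterError):
            insulation_score(random_symmetric(40), window=BS + 1)

    def test_window_too_large_rejected(self, random_symmetric):
        with pytest.raises(ParameterError):
            insulation_score(random_symmetric(10), window=6 * BS)


class TestBoundaryCalling:
    def test_flat_profile_no_boundaries(self):
        prof = insulation_score(_matrix(np.ones((40, 40))), window=5 * BS)
        out = call_boundaries(prof, delta_window=3 * BS)
        assert len(out.boundaries) == 0

    def test_noise_free_boundaries_exact(self):
        m, truth = simulate_contact_map(HiCSimParams(
            n_bins=100, bin_size=BS, expected_only=True, epsilon=0.4,
            beta=1.0, gamma=0.2, tad_size=20, block_size=20))
        prof = call_boundaries(insulation_score(m, window=12 * BS),
                               delta_window=3 * BS, min_strength=0.1)
        assert np.array_equal(prof.boundaries, truth["boundaries"])

    def test_poisson_depth_5e5_recall_precision(self):
        recs, precs = [], []
        for seed in range(20):
            m, truth = simulate_contact_map(HiCSimParams(
                n_bins=100, bin_size=BS, depth=5e5, epsilon=0.4, beta=1.0,
                gamma=0.2, tad_size=20, block_size=20, seed=seed))
            b = ice_balance(m, min_coverage_mad=0)
            prof = call_boundaries(insulation_score(b, window=12 * BS),
                                   delta_window=3 * BS, min_strength=0.1)
            tb = set(truth["boundaries"].tolist())
            cb = set(prof.boundaries.tolist())
            recs.append(len(tb & cb) / len(tb))
            precs.append(len(tb & cb) / max(len(cb), 1))
        assert np.mean(recs) >= 0.9
        assert np.mean(precs) >= 0.9

    def test_boundary_strength_reported(self):
        m, _ = simulate_contact_map(HiCSimParams(
            n_bins=100, bin_size=BS, expected_only=True, beta=2.0,
            epsilon=0, gamma=0, tad_size=20))
        prof = call_boundaries(insulation_score(m, window=12 * BS),
                               delta_window=3 * BS, min_strength=0.1)
        assert len(prof.boundary_strength) == len(prof.boundaries)
        assert np.all(prof.boundary_strength >= 0.1)


class TestTadConstruction:
    def test_boundaries_tile_chromosome(self):
        bins = make_bins({"c": 30 * BS}, BS)
        ts = tads_from_boundaries(np.array([10, 20]), bins)
        assert np.array_equal(ts.intervals // BS,
                              [[0, 10], [10, 20], [20, 30]])

    def test_no_boundaries_single_tad(self):
        bins = make_bins({"c": 30 * BS}, BS)
        ts = tads_from_boundaries(np.array([], dtype=int), bins)
        assert len(ts.intervals) == 1
        assert ts.intervals[0, 1] == 30 * BS

    def test_round_trip_boundaries(self):
        bins = make_bins({"c": 50 * BS}, BS)
        b = np.array([7, 21, 33])
        ts = tads_from_boundaries(b, bins)
        assert np.array_equal(ts.boundaries_bins(), b)


class TestTadScore:
    def test_uniform_matrix_score_one(self):
        cm = _matrix(np.ones((30, 30)))
        ts = TadSet(np.array([[0, 10], [10, 20], [20, 30]]) * BS, BS)
        scores = tad_score(cm, ts)["score"]
        assert np.allclose(scores, 1.0)

    def test_block_matrix_score_ten_matches_brute_force(self):
        n = 30
        m = np.ones((n, n))
        for s, t in ((0, 10), (10, 20), (20, 30)):
            m[s:t, s:t] = 10.0
        cm = _matrix(m)
        ts = TadSet(np.array([[0, 10], [10, 20], [20, 30]]) * BS, BS)
        df = tad_score(cm, ts)
        assert np.allclose(df["score"], 10.0, atol=1e-12)
        # brute force for the middle TAD
        intra = [m[i, j] for i in range(10, 20) for j in range(10, 20)
                 if i != j]
        inter = [m[i, j] for i in range(10, 20)
                 for j in list(range(0, 10)) + list(range(20, 30))]
        assert df["score"][1] == pytest.approx(np.mean(intra)
                                               / np.mean(inter))

    def test_scale_invariance(self, random_symmetric):
        cm = random_symmetric(30, seed=13)
        ts = TadSet(np.array([[0, 10], [10, 20], [20, 30]]) * BS, BS)
        s1 = tad_score(cm, ts)["score"]
        s2 = tad_score(_matrix(cm.counts * 7.3), ts)["score"]
        assert np.allclose(s1, s2)

    def test_single_bin_tad_skipped(self):
        cm = _matrix(np.ones((10, 10)))
        ts = TadSet(np.array([[0, BS], [BS, 10 * BS]]), BS)
        df = tad_score(cm, ts)
        assert df["note"][0] == "too_small"
        assert np.isnan(df["score"][0])

    def test_median_score_monotone_in_beta(self):
        meds = []
        for beta in (0.5, 1.0, 2.0):
            m, truth = simulate_contact_map(HiCSimParams(
                n_bins=100, bin_size=BS, expected_only=True, epsilon=0,
                beta=beta, gamma=0.2, tad_size=10))
            ts = TadSet(np.asarray(truth["tads"]) * BS, BS)
            meds.append(tad_score(m, ts)["score"].median())
        assert meds[0] < meds[1] < meds[2]

    def test_median_score_decreases_with_inter_tad_contacts(self):
        meds = []
        for boost in (0.0, 0.5, 1.0):
            m, truth = simulate_contact_map(HiCSimParams(
                n_bins=100, bin_size=BS, expected_only=True, epsilon=0,
                beta=1.0, gamma=0.2, tad_size=10, inter_tad_boost=boost))
            ts = TadSet(np.asarray(truth["tads"]) * BS, BS)
            meds.append(tad_score(m, ts)["score"].median())
        assert meds[0] > meds[1] > meds[2]


class TestAggregateTads:
    def _map_with_corners(self, gamma=1.0, n=200, tad=20):
        m, truth = simulate_contact_map(HiCSimParams(
            n_bins=n, bin_size=BS, expected_only=True, epsilon=0, beta=1.0,
            gamma=gamma, tad_size=tad))
        ts = TadSet(np.asarray(truth["tads"]) * BS, BS)
        return m, ts

    def test_single_tad_is_identity(self):
        m, _ = self._map_with_corners()
        ts = TadSet(np.array([[40, 60]]) * BS, BS)
        grid, n_used = aggregate_tads(m, ts, out_pixels=60)
        assert n_used == 1
        from vermicelli.hic import observed_over_expected
        from skimage.transform import resize
        oe = observed_over_expected(m)
        window = oe[30:70, 30:70]
        expect = resize(np.nan_to_num(window), (60, 60), order=1,
                        mode="edge", anti_aliasing=False)
        assert np.allclose(grid, expect, atol=1e-10)

    def test_two_identical_tads_average_to_one_window(self):
        n = 60
        m = np.ones((n, n))
        for s, t in ((10, 25), (35, 50)):
            m[s:t, s:t] = 5.0
        cm = _matrix(m)
        ts = TadSet(np.array([[10, 25], [35, 50]]) * BS, BS)
        grid2, n2 = aggregate_tads(cm, ts, out_pixels=45)
        grid1, _ = aggregate_tads(cm, TadSet(np.array([[10, 25]]) * BS, BS),
                                  out_pixels=45)
        assert n2 == 2
        # distance decay is flat here, so both windows agree
        assert np.allclose(grid2, grid1, atol=1e-10)

    def test_corner_enrichment_and_differential_direction(self):
        from vermicelli.pipeline import compare_presets
        m, ts = self._map_with_corners(gamma=1.0)
        grid, _ = aggregate_tads(m, ts, out_pixels=90, flank_fraction=0.5)
        # TAD occupies pixels [30, 60); corners near (30, 59)
        corner = np.nanmean(grid[28:33, 57:62])
        border = np.nanmean(np.concatenate([
            grid[43:48, 28:31].ravel(), grid[28:31, 43:48].ravel()]))
        assert corner > border
        out = compare_presets(seed=2)
        assert out["corner_contacts_up"]

    def test_grid_symmetric_and_order_invariant(self):
        m, ts = self._map_with_corners()
        grid, _ = aggregate_tads(m, ts)
        assert np.allclose(grid, grid.T, equal_nan=True)
        rev = TadSet(ts.intervals, BS)
        grid_rev, _ = aggregate_tads(m, rev)
        assert np.allclose(grid, grid_rev, equal_nan=True)

    def test_no_qualifying_tad_rejected(self):
        m, _ = self._map_with_corners()
        tiny = TadSet(np.array([[0, 2 * BS]]), BS)
        with pytest.raises(DegenerateInputError):
            aggregate_tads(m, tiny, min_size=200_000)


class TestTadLengthStats:
    def test_long_short_split(self):
        ts = TadSet(np.array([[0, 400_000], [400_000, 1_000_000]]), BS)
        stats = tad_length_stats(ts, long_threshold=500_000)
        assert stats["n_short"] == 1 and stats["n_long"] == 1

    def test_median_matches_planted(self):
        sizes = [10, 14, 20, 26, 30]
        edges = np.cumsum([0] + sizes) * BS
        ts = TadSet(np.column_stack([edges[:-1], edges[1:]]), BS)
        stats = tad_length_stats(ts)
        assert stats["median_length"] == 20 * BS

    def test_identical_sets_zero_count_difference(self):
        m, truth = simulate_contact_map(HiCSimParams(
            n_bins=100, bin_size=BS, expected_only=True, tad_size=20))
        ts = TadSet(np.asarray(truth["tads"]) * BS, BS)
        s1 = tad_length_stats(ts)
        s2 = tad_length_stats(TadSet(ts.intervals.copy(), BS))
        assert s1["n_long"] == s2["n_long"]
        assert s1["n_short"] == s2["n_short"]
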