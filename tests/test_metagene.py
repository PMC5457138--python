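"""Smoothing, anchoring, length scaling, rescaling and heat binning."""

import numpy as np
import pytest

from parclip import (
    GenomeLayout,
    Transcript,
    anchor_matrix,
    average_and_rescale,
    heat_bin,
    length_scale_matrix,
    smooth,
)

from conftest import make_track, minus_transcript, plus_transcript


class TestSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth(np.full(200, 3.5)), 3.5)

    def test_impulse_spreads_to_plateau(self):
        v = np.zeros(301)
        v[150] = 1.0
        s = smooth(v, 61)
        np.testing.assert_allclose(s[120:181], 1 / 61)
        assert s[119] == 0 and s[181] == 0

    def test_window_one_is_identity(self):
        v = np.random.default_rng(0).random(50)
        np.testing.assert_array_equal(smooth(v, 1), v)

    def test_truncated_edges_average_available_values(self):
        # first output = mean of positions 0..30 under the truncated rule
        v = np.arange(100, dtype=float)
        s = smooth(v, 61)
        assert s[0] == pytest.approx(np.mean(v[:31]))
        assert s[-1] == pytest.approx(np.mean(v[-31:]))

    def test_missing_values_excluded_not_zeroed(self):
        v = np.full(100, 2.0)
        v[40:60] = np.nan
        s = smooth(v, 61)
        np.testing.assert_allclose(s[np.isfinite(s)], 2.0)

    def test_mean_preserved_on_long_vectors(self):
        v = np.random.default_rng(1).random(5000)
        assert smooth(v).mean() == pytest.approx(v.mean(), rel=1e-3)

    def test_empty_vector(self):
        assert smooth(np.array([])).size == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.ones(5), 10)


@pytest.fixture
def layout():
    return GenomeLayout({"chrI": 10_000})


class TestAnchorMatrix:
    def test_tss_anchor_plus_strand(self, layout):
        track = make_track(layout)
        track[("chrI", "+")][999:1002] = [7, 8, 9]
        t = plus_transcript(tss=1000, pa=2000)
        m = anchor_matrix(track, [t], "tss", up=1, down=2)
        assert m.tolist() == [[7, 8, 9]]

    def test_minus_strand_mirrors_plus(self, layout):
        rng = np.random.default_rng(2)
        vals = rng.random(10_000)
        track = {("chrI", "+"): vals, ("chrI", "-"): vals[::-1].copy()}
        tp = plus_transcript(tss=3000, pa=4000)
        # mirror transcript on the flipped genome
        tm = minus_transcript(tss=10_000 - 3000, pa=10_000 - 4000)
        mp = anchor_matrix(track, [tp], "tss", up=50, down=100)
        mm = anchor_matrix(track, [tm], "tss", up=50, down=100)
        np.testing.assert_allclose(mp, mm)

    def test_pa_anchor_window_convention(self, layout):
        track = make_track(layout)
        track[("chrI", "+")][2000] = 5.0  # the pA site itself (first base after)
        t = plus_transcript(tss=1000, pa=2000)
        m = anchor_matrix(track, [t], "pa", up=400, down=150)
        assert m.shape == (1, 550)
        assert m[0, 400] == 5.0  # offset 0 column

    def test_off_chromosome_positions_missing(self, layout):
        track = make_track(layout, fill=1.0)
        t = plus_transcript(tss=50, pa=900)
        m = anchor_matrix(track, [t], "tss", up=100, down=10)
        assert np.isnan(m[0, :50]).all() and np.isfinite(m[0, 50:]).all()

    def test_ss5_anchor_one_row_per_intron(self, layout):
        track = make_track(layout, fill=0.0)
        track[("chrI", "+")][1200] = 3.0
        t = plus_transcript(tss=1000, pa=2000, introns=((1200, 1400), (1600, 1800)))
        m = anchor_matrix(track, [t], "ss5", up=0, down=5)
        assert m.shape == (2, 5)
        assert m[0, 0] == 3.0  # first intronic base of intron 1

    def test_ss5_minus_strand_uses_high_coordinate_end(self, layout):
        track = make_track(layout, fill=0.0)
        track[("chrI", "-")][1399] = 4.0  # first intronic base in transcription dir
        t = minus_transcript(tss=2000, pa=1000, introns=((1200, 1400),))
        m = anchor_matrix(track, [t], "ss5", up=0, down=3)
        assert m[0, 0] == 4.0

    def test_no_transcripts_errors(self, layout):
        with pytest.raises(ValueError):
            anchor_matrix(make_track(layout), [], "tss", 10, 10)


class TestLengthScale:
    def test_ramp_stays_ramp(self, layout):
        track = make_track(layout)
        track[("chrI", "+")][1000:1100] = np.linspace(0, 1, 100)
        t = plus_transcript(tss=1000, pa=1100)
        m = length_scale_matrix(track, [t], target_len=200)
        np.testing.assert_allclose(m[0], np.linspace(0, 1, 200), atol=1e-12)

    def test_native_length_unchanged(self, layout):
        rng = np.random.default_rng(3)
        track = make_track(layout)
        vals = rng.random(100)
        track[("chrI", "+")][1000:1100] = vals
        t = plus_transcript(tss=1000, pa=1100)
        m = length_scale_matrix(track, [t], target_len=100)
        np.testing.assert_allclose(m[0], vals)

    def test_constant_stays_constant(self, layout):
        track = make_track(layout, fill=2.0)
        m = length_scale_matrix(track, [plus_transcript()], target_len=57)
        np.testing.assert_allclose(m, 2.0)

    def test_default_target_is_median_length(self, layout):
        track = make_track(layout, fill=1.0)
        ts = [plus_transcript(tid=f"t{i}", tss=100 * i, pa=100 * i + L)
              for i, L in [(1, 10), (20, 30), (60, 50)]]
        m = length_scale_matrix(track, ts)
        assert m.shape == (3, 30)


class TestAverageAndRescale:
    def test_rescale_to_unit_interval(self):
        prof = average_and_rescale(np.array([[2.0, 4.0, 6.0]]), smooth_window=1)
        np.testing.assert_allclose(prof.values, [0.0, 0.5, 1.0])

    def test_joint_mode_shares_the_maximum(self):
        a = np.array([[0.0, 1.0, 2.0]])
        b = np.array([[0.0, 2.0, 4.0]])
        profs = average_and_rescale({"A": a, "B": b}, smooth_window=1)
        assert profs["A"].values.max() == pytest.approx(0.5)
        assert profs["B"].values.max() == pytest.approx(1.0)

    def test_constant_profile_degenerates_to_zero(self):
        prof = average_and_rescale(np.full((3, 10), 5.0), smooth_window=1)
        np.testing.assert_allclose(prof.values, 0.0)

    def test_missing_columns_stay_missing(self):
        m = np.array([[1.0, np.nan], [3.0, np.nan]])
        prof = average_and_rescale(m, smooth_window=1)
        assert np.isnan(prof.values[1])
        assert prof.n_transcripts.tolist() == [2, 0]

    def test_invariant_to_positive_scaling(self):
        m = np.random.default_rng(4).random((5, 40))
        a = average_and_rescale(m).values
        b = average_and_rescale(m * 7.3).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_smooth_first_flag_changes_order(self):
        m = np.array([[0, 0, 9.0], [1, np.nan, np.nan]])
        after = average_and_rescale(m, smooth_window=3)
        before = average_and_rescale(m, smooth_window=3, smooth_first=True)
        assert not np.allclose(after.values, before.values, equal_nan=True)


class TestHeatBin:
    def test_uniform_matrix_maps_to_one(self):
        hm = heat_bin(np.full((50, 200), 3.0))
        np.testing.assert_allclose(hm.matrix, 1.0)

    def test_outlier_cell_saturates(self):
        m = np.ones((100, 400))
        m[:10, :20] = 100.0  # one 20x10 cell far above the 97% quantile
        hm = heat_bin(m, bin_x=20, bin_y=10, q=0.97)
        assert hm.matrix[0, 0] == 1.0
        interior = hm.matrix[2:, 2:]
        assert interior.max() <= 1.0 and interior.min() > 0

    def test_identity_binning_is_max_scaling(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        hm = heat_bin(m, bin_x=1, bin_y=1, q=1.0)
        np.testing.assert_allclose(hm.matrix, m / 4.0)

    def test_cells_average_defined_values_only(self):
        m = np.array([[1.0, np.nan], [3.0, np.nan]])
        hm = heat_bin(m, bin_x=2, bin_y=2, q=1.0)
        assert hm.matrix[0, 0] == 1.0  # mean(1,3)=2 scaled by itself
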