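"""Colocalization scores and UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from parclip import GenomeLayout, average_linkage, coloc_matrix, coloc_score
from parclip.coloc import linkage_to_newick
from parclip.normalize import OccupancyTrack

LAYOUT = GenomeLayout({"chrI": 10_000})


def occ_track(positions, values, strand="+"):
    df = pd.DataFrame({"chrom": "chrI", "pos": positions, "strand": strand,
                       "occupancy": values})
    return OccupancyTrack(df, "raw", 1.0)


def sites(positions, values, strand="+"):
    return pd.DataFrame({"chrom": "chrI", "pos": positions, "strand": strand,
                         "occupancy": values})


class TestColocScore:
    def test_constant_b_gives_zero_score(self):
        pos = np.arange(0, 5000, 7)
        b = occ_track(pos, np.full(len(pos), 2.5))
        res = coloc_score(sites([100, 500], [1.0, 2.0]), b, LAYOUT)
        assert (res.c, res.b, res.score) == (2.5, 2.5, 0.0)

    def test_window_max_brute_force_example(self):
        pos = np.arange(0, 200)
        vals = np.ones(200)
        vals[60] = 8.0
        b = occ_track(pos, vals)
        res = coloc_score(sites([50], [1.0]), b, LAYOUT, w=20)
        assert (res.c, res.b, res.score) == (8.0, 1.0, 3.0)

    def test_peak_outside_window_ignored(self):
        pos = np.arange(0, 200)
        vals = np.ones(200)
        vals[75] = 8.0  # 25 nt away: outside +-20
        res = coloc_score(sites([50], [1.0]), occ_track(pos, vals), LAYOUT, w=20)
        assert res.score == 0.0

    def test_fewer_sites_than_n_uses_all(self):
        b = occ_track(np.arange(100), np.ones(100))
        res = coloc_score(sites([10, 20], [1.0, 2.0]), b, LAYOUT, n=3000)
        assert res.n_sites == 2

    def test_top_n_selects_strongest_sites(self):
        pos = np.arange(0, 1000)
        vals = np.ones(1000)
        vals[500] = 10.0
        b = occ_track(pos, vals)
        s = sites([100, 500], [0.1, 5.0])  # only the strong A site is used
        res = coloc_score(s, b, LAYOUT, n=1)
        assert res.c == 10.0

    def test_opposite_strand_windows_never_leak(self):
        # all of B's occupancy is on the minus strand; A's plus-strand
        # windows must not see it (all-absent windows contribute 0)
        b_minus = occ_track(np.arange(100), np.full(100, 9.0), strand="-")
        res = coloc_score(sites([50], [1.0]), b_minus, LAYOUT)
        assert res.c == 0.0 and res.score == -np.inf

    def test_zero_median_background_errors(self):
        b = occ_track(np.arange(100), np.zeros(100))
        with pytest.raises(ValueError, match="median"):
            coloc_score(sites([50], [1.0]), b, LAYOUT)

    def test_invariant_to_scaling_occ_b(self):
        rng = np.random.default_rng(8)
        pos = np.arange(0, 2000)
        vals = rng.uniform(0.5, 1.5, len(pos))
        a = sites(rng.choice(pos, 50, replace=False), rng.random(50))
        s1 = coloc_score(a, occ_track(pos, vals), LAYOUT).score
        s2 = coloc_score(a, occ_track(pos, vals * 11.0), LAYOUT).score
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(8000), 1500, replace=False))
        vals = rng.uniform(0.2, 3.0, len(pos))
        a_pos = rng.choice(pos, 80, replace=False)
        a = sites(a_pos, rng.random(80))
        n, w = 30, 20
        res = coloc_score(a, occ_track(pos, vals), LAYOUT, n=n, w=w)

        occ_map = dict(zip(pos, vals))
        order = a.sort_values(["occupancy", "chrom", "strand", "pos"],
                              ascending=[False, True, True, True]).head(n)
        maxima = []
        for p in order["pos"]:
            window = [occ_map[q] for q in range(p - w, p + w + 1) if q in occ_map]
            maxima.append(max(window) if window else 0.0)
        c = float(np.mean(maxima))
        b = float(np.median(vals))
        assert res.c == pytest.approx(c, rel=1e-12)
        assert res.score == pytest.approx(np.log2(c / b), rel=1e-12)


class TestAverageLinkage:
    def test_hand_computed_three_leaf_merges(self):
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        link = average_linkage(d)
        assert link.shape == (2, 4)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == 1.0
        assert link[1, 2] == 10.0  # mean of d(1,3), d(2,3)

    def test_upgma_averages_cluster_sizes(self):
        # 4 leaves: merge (0,1)@1; then 2 joins at mean(4, 6) = 5; etc.
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 1.0
        d[0, 2] = d[2, 0] = 4.0
        d[1, 2] = d[2, 1] = 6.0
        d[0, 3] = d[3, 0] = 9.0
        d[1, 3] = d[3, 1] = 9.0
        d[2, 3] = d[3, 2] = 9.0
        link = average_linkage(d)
        assert link[0, 2] == 1.0
        assert link[1, 2] == pytest.approx(5.0)
        assert link[2, 2] == pytest.approx(9.0)

    def test_all_equal_distances_single_height(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        link = average_linkage(d)
        np.testing.assert_allclose(link[:, 2], 2.0)

    def test_two_leaves_one_merge(self):
        link = average_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert link.shape == (1, 4) and link[0, 2] == 3.0

    def test_non_finite_distances_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            average_linkage(d)


class TestColocMatrix:
    @staticmethod
    def _factor(rng, peak_positions=None):
        pos = np.arange(0, 6000, 3)
        vals = rng.uniform(0.8, 1.2, len(pos))
        if peak_positions is not None:
            idx = np.searchsorted(pos, peak_positions)
            vals[idx] = 6.0
        order = np.argsort(vals)[::-1][:50]
        return sites(pos[order], vals[order]), occ_track(pos, vals)

    def test_identical_factors_merge_first(self):
        rng = np.random.default_rng(10)
        peaks = np.arange(300, 3000, 300)
        shared = self._factor(np.random.default_rng(10), peaks)
        twin = self._factor(np.random.default_rng(10), peaks)
        other = self._factor(rng)
        result = coloc_matrix({"a": shared, "b": twin, "c": other}, LAYOUT, n=50)
        first = {int(result.linkage[0, 0]), int(result.linkage[0, 1])}
        assert first == {0, 1}  # the identical pair merges at minimal height

    def test_matrix_entries_are_directional_scores(self):
        rng = np.random.default_rng(11)
        f = {name: self._factor(rng) for name in ("x", "y", "z")}
        result = coloc_matrix(f, LAYOUT, n=50)
        for a in f:
            got = result.scores.loc[a, "y"]
            expect = coloc_score(f[a][0], f["y"][1], LAYOUT, n=50).score
            assert got == pytest.approx(expect)

    def test_fewer_than_three_factors_rejected(self):
        rng = np.random.default_rng(12)
        f = {name: self._factor(rng) for name in ("x", "y")}
        with pytest.raises(ValueError, match=">= 3"):
            coloc_matrix(f, LAYOUT)

    def test_leaf_order_invariance(self):
        f = {name: self._factor(np.random.default_rng(seed))
             for seed, name in zip((1, 2, 3, 4), "abcd")}
        r1 = coloc_matrix(f, LAYOUT, n=50)
        r2 = coloc_matrix(dict(reversed(list(f.items()))), LAYOUT, n=50)
        np.testing.assert_allclose(np.sort(r1.linkage[:, 2]),
                                   np.sort(r2.linkage[:, 2]), rtol=1e-9)

    def test_newick_export_parses(self):
        f = {name: self._factor(np.random.default_rng(seed))
             for seed, name in zip((5, 6, 7), "pqr")}
        result = coloc_matrix(f, LAYOUT, n=50)
        nwk = linkage_to_newick(result.linkage, list(f))
        assert nwk.endswith(";") and all(name in nwk for name in f)
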