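import numpy as np
import pytest

from tethermap import aggregate as ag
from tethermap.fragments import ChromSizes
from tethermap.tracks import GenomicTrack


def spike_track(positions, length=4000, chrom="chr1", values=None):
    t = GenomicTrack({chrom: np.zeros(length)})
    for i, p in enumerate(positions):
        t[chrom][p] = 1.0 if values is None else values[i]
    return t


def profile(values, start=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    positions = np.arange(-(n // 2), n - n // 2) if start is None else np.arange(start, start + n)
    return ag.AggregateProfile(positions=positions, values=values)


class TestSiteMatrix:
    def test_plus_strand_centering(self):
        t = spike_track([2000])
        m = ag.site_matrix(t, [("chr1", 2000, "+")], flank=100)
        assert m.values[0, m.column_index(0)] == 1.0
        assert m.values.sum() == 1.0

    def test_minus_strand_flip(self):
        # spike at center+5 appears at relative -6 after the minus-strand
        # mirror (genomic center-1-o mapping)
        t = spike_track([2005])
        m = ag.site_matrix(t, [("chr1", 2000, "-")], flank=100)
        rel = m.positions[np.flatnonzero(m.values[0])[0]]
        assert rel == -6

    def test_edge_sites_dropped(self):
        t = spike_track([50])
        m = ag.site_matrix(t, [("chr1", 10, "+"), ("chr1", 2000, "+")], flank=1000)
        assert len(m) == 1 and m.n_dropped == 1

    def test_no_survivors_errors(self):
        with pytest.raises(ValueError):
            ag.site_matrix(spike_track([0]), [("chr1", 5, "+")], flank=1000)

    def test_mirror_symmetry_of_mean_profile(self, small_sim):
        """Mirroring the genome and flipping strands leaves the mean
        profile unchanged."""
        from tethermap.tracks import end_density_track
        cs = small_sim["cs"]
        t = end_density_track(small_sim["primary"], cs)
        sites = small_sim["truth"].site_tuples("direct")
        m1 = ag.site_matrix(t, sites, flank=200)
        p1 = ag.mean_profile(m1)
        # mirrored genome: position x -> L-1-x; track reversed per chrom
        t2 = GenomicTrack({c: v[::-1].copy() for c, v in t.data.items()})
        # the mirror of a half-open window centered at pos is centered at L-pos
        sites2 = [(c, cs[c] - pos, {"+": "-", "-": "+"}[s]) for c, pos, s in sites]
        p2 = ag.mean_profile(ag.site_matrix(t2, sites2, flank=200))
        np.testing.assert_allclose(p1.values, p2.values)


class TestMeanProfile:
    def test_mean_median_pom(self):
        m = ag.ProfileMatrix(values=np.array([[0.0, 2, 0], [0, 4, 0]]),
                             positions=np.array([-1, 0, 1]),
                             sites=__import__("pandas").DataFrame({"chrom": ["c", "c"]}))
        assert list(ag.mean_profile(m).values) == [0, 3, 0]
        assert list(ag.mean_profile(m, "median").values) == [0, 3, 0]
        assert list(ag.mean_profile(m, "percent-of-max").values) == [0, 100, 0]

    def test_all_zero_pom_errors(self):
        import pandas as pd
        m = ag.ProfileMatrix(values=np.zeros((2, 3)), positions=np.array([-1, 0, 1]),
                             sites=pd.DataFrame({"chrom": ["c", "c"]}))
        with pytest.raises(ValueError):
            ag.mean_profile(m, "percent-of-max")


class TestSmooth:
    def test_constant_unchanged(self):
        p = profile(np.full(50, 3.3))
        np.testing.assert_allclose(ag.smooth(p, 11).values, 3.3)

    def test_unit_impulse_kernel(self):
        v = np.zeros(51); v[25] = 1.0
        sm = ag.smooth(profile(v), 11).values
        np.testing.assert_allclose(sm[20:31], 1 / 11)
        assert sm[19] == 0 and sm[31] == 0

    def test_window_one_identity(self):
        p = profile(np.arange(20, dtype=float))
        np.testing.assert_allclose(ag.smooth(p, 1).values, p.values)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ag.smooth(profile(np.zeros(10)), 10)

    def test_truncated_edges(self):
        v = np.ones(30); v[0] = 4.0
        sm = ag.smooth(profile(v), 3).values
        assert sm[0] == pytest.approx((4 + 1) / 2)  # shrunk to 2 positions


class TestPeriodicity:
    @pytest.mark.parametrize("period", [7, 10])
    def test_recovers_synthetic_period(self, period):
        x = np.arange(400)
        v = 5.0 + (x % period == 0) * 2.0
        ac = ag.periodicity_autocorrelation(profile(v), max_lag=50)
        assert ac.period == period

    def test_white_noise_band_exceedance_near_nominal(self):
        """On white noise no reproducible period emerges, and beyond the
        smoothing-window support (where the high-passed residual is
        uncorrelated) the fraction of lags above the ~95% band (2/sqrt(n))
        stays near its nominal 5% in expectation."""
        rng = np.random.default_rng(12345)
        frac, periods = [], []
        for _ in range(10):
            v = rng.normal(size=600)
            ac = ag.periodicity_autocorrelation(profile(v), max_lag=50)
            frac.append(np.mean(np.abs(ac.values[12:]) > ac.confidence_band))
            periods.append(ac.period)
        assert np.mean(frac) < 0.10
        found = [p for p in periods if p is not None]
        assert max([found.count(p) for p in set(found)], default=0) <= 3

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ag.periodicity_autocorrelation(profile(np.ones(400)))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            ag.periodicity_autocorrelation(profile(np.ones(60)), max_lag=50)


class TestGcProfile:
    def test_constant_genomes(self):
        sites = [("c", 50, "+")]
        assert np.all(ag.gc_profile({"c": "G" * 100}, sites, flank=20).values == 1.0)
        assert np.all(ag.gc_profile({"c": "A" * 100}, sites, flank=20).values == 0.0)

    def test_periodic_composition_positive_control(self):
        seq = ("GCGCGCGCGC" + "ATATATATAT") * 60
        p = ag.gc_profile({"c": seq}, [("c", 600, "+")], flank=250)
        ac = ag.periodicity_autocorrelation(p, max_lag=50)
        assert ac.period == 20


class TestFootprint:
    def test_constructed_hole(self):
        v = np.ones(2000)
        v[990:1010] = 0.0  # relative -10..+9
        assert ag.footprint_width(profile(v)) == 20

    def test_flat_profile_errors(self):
        with pytest.raises(ValueError, match="footprint"):
            ag.footprint_width(profile(np.ones(2000)))

    def test_simulator_recovery(self, small_sim):
        from tethermap.fragments import size_select
        from tethermap.tracks import end_density_track
        fs = size_select(small_sim["primary"], max_len=120)
        t = end_density_track(fs, small_sim["cs"])
        m = ag.site_matrix(t, small_sim["truth"].site_tuples("direct"), flank=1000)
        width = ag.footprint_width(ag.mean_profile(m))
        assert abs(width - 2 * small_sim["cfg"].protected_halfwidth) <= 2


class TestTramtracks:
    @pytest.mark.parametrize("lpos,rpos,expected", [(-22, 22, 44), (-10, 30, 40)])
    def test_constructed_spikes(self, lpos, rpos, expected):
        v = np.zeros(400)
        v[200 + lpos] = 5.0
        v[200 + rpos] = 5.0
        assert ag.tramtrack_separation(profile(v), search=100) == expected

    def test_flat_half_window_errors(self):
        with pytest.raises(ValueError):
            ag.tramtrack_separation(profile(np.ones(400)), search=100)


class TestOccupancyAndOrdering:
    def make_matrix(self, rows):
        import pandas as pd
        rows = np.asarray(rows, dtype=float)
        flank = rows.shape[1] // 2
        return ag.ProfileMatrix(values=rows, positions=np.arange(-flank, flank),
                                sites=pd.DataFrame({"chrom": ["c"] * len(rows)}))

    def test_span_mean_constant(self):
        m = self.make_matrix(np.ones((1, 2000)))
        assert ag.occupancy_scores(m, "span-mean")[0] == pytest.approx(1.0)

    def test_center_minus_flank(self):
        row = np.zeros(2000)
        row[1000 - 30:1000 + 30] = 1.0
        m = self.make_matrix([row])
        assert ag.occupancy_scores(m, "center-minus-flank")[0] == pytest.approx(60)
        row2 = np.zeros(2000)
        row2[:300] = 1.0   # -1000..-700
        row2[1700:] = 1.0  # +700..+1000
        m2 = self.make_matrix([row2])
        assert ag.occupancy_scores(m2, "center-minus-flank")[0] == pytest.approx(-600)

    def test_insufficient_flank_errors(self):
        m = self.make_matrix(np.ones((1, 200)))
        with pytest.raises(ValueError):
            ag.occupancy_scores(m, "center-minus-flank")

    def test_order_rows_descending_and_permutation(self):
        m = self.make_matrix(np.arange(6, dtype=float).reshape(3, 2))
        scores = np.array([1.0, 3.0, 2.0])
        ordered, perm = ag.order_rows(m, scores)
        assert list(perm) == [1, 2, 0]
        reordered = scores[perm]
        assert all(reordered[:-1] >= reordered[1:])

    def test_stable_on_ties(self):
        m = self.make_matrix(np.zeros((3, 2)))
        _, perm = ag.order_rows(m, np.array([1.0, 1.0, 1.0]))
        assert list(perm) == [0, 1, 2]

    def test_order_then_score_monotone(self, small_sim):
        from tethermap.tracks import coverage_track
        t = coverage_track(small_sim["primary"], small_sim["cs"])
        m = ag.site_matrix(t, small_sim["truth"].site_tuples("direct"), flank=1000)
        scores = ag.occupancy_scores(m, "span-mean")
        ordered, perm = ag.order_rows(m, scores)
        rescored = ag.occupancy_scores(ordered, "span-mean")
        assert np.all(np.diff(rescored) <= 1e-12)


class TestCumulativeCurve:
    def make_matrix(self, center_counts):
        import pandas as pd
        rows = []
        for c in center_counts:
            row = np.zeros(200)
            row[100] = c
            rows.append(row)
        return ag.ProfileMatrix(values=np.array(rows), positions=np.arange(-100, 100),
                                sites=pd.DataFrame({"chrom": ["c"] * len(rows)}))

    def test_arithmetic(self):
        m = self.make_matrix([2.0, 1.0, 1.0])
        curve = ag.cumulative_count_curve(m, rank_by=np.array([3.0, 2.0, 1.0]),
                                          center_halfwidth=30)
        assert list(curve["cumulative_percent"]) == [50.0, 75.0, 100.0]

    def test_uniform_is_linear_to_100(self):
        m = self.make_matrix([1.0] * 5)
        curve = ag.cumulative_count_curve(m, rank_by=np.arange(5.0))
        np.testing.assert_allclose(curve["cumulative_percent"], [20, 40, 60, 80, 100])
        assert curve["cumulative_percent"].iloc[-1] == pytest.approx(100.0)
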