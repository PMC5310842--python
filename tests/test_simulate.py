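import numpy as np
import pytest

from tethermap import simulate
from tethermap.fragments import length_distribution, size_select


@pytest.fixture(scope="module")
def sim(small_sim):
    return small_sim


class TestMakeGenome:
    def test_deterministic_under_seed(self, sim):
        cfg = sim["cfg"]
        g1, t1, _, _ = simulate.make_genome(cfg)
        assert g1 == sim["genome"]
        assert t1.sites.equals(sim["truth"].sites)

    def test_consensus_planted_at_direct_sites(self, sim):
        cfg, truth, genome = sim["cfg"], sim["truth"], sim["genome"]
        from tethermap.sites import reverse_complement
        for row in truth.of_class("direct").itertuples(index=False):
            seq = genome[row.chrom][row.start:row.end]
            expected = cfg.motif if row.strand == "+" else reverse_complement(cfg.motif)
            assert seq == expected

    def test_indirect_sites_motif_free(self, sim):
        cfg, truth, genome = sim["cfg"], sim["truth"], sim["genome"]
        from tethermap.sites import reverse_complement
        for row in truth.of_class("indirect").itertuples(index=False):
            window = genome[row.chrom][row.center - 100:row.center + 100]
            assert cfg.motif not in window
            assert reverse_complement(cfg.motif) not in window

    def test_site_spacing(self, sim):
        sites = sim["truth"].sites
        for _, sub in sites.groupby("chrom"):
            centers = np.sort(sub["center"].to_numpy())
            if len(centers) > 1:
                assert np.diff(centers).min() >= 2000

    def test_infeasible_count_errors(self):
        with pytest.raises(ValueError, match="at most"):
            simulate.make_genome(simulate.default_config(
                seed=0, genome_length=20000, n_chroms=1, n_direct_sites=500))

    def test_indirect_partners_are_direct(self, sim):
        truth = sim["truth"]
        direct_ids = set(truth.of_class("direct")["site_id"])
        for pid in truth.of_class("indirect")["partner_id"]:
            assert pid in direct_ids


class TestSimulateFragments:
    def test_deterministic(self, sim):
        p1, s1 = simulate.simulate_fragments(sim["cfg"], sim["truth"], sim["cs"],
                                             sim["spike_cs"], 0)
        assert p1.df.equals(sim["primary"].df)
        assert s1.df.equals(sim["spike"].df)

    def test_no_end_inside_protected_core(self, sim):
        """No fragment of any class has a terminal base inside a protected
        core — bound protein blocks cleavage."""
        cfg, truth = sim["cfg"], sim["truth"]
        blocked = simulate._blocked_masks(truth, sim["cs"], cfg.protected_halfwidth)
        df = sim["primary"].df
        for chrom, sub in df.groupby("chrom"):
            m = blocked[chrom]
            assert not m[sub["start"].to_numpy()].any()
            assert not m[sub["end"].to_numpy() - 1].any()

    def test_spike_count_constant_over_time(self, sim):
        counts = []
        for ti in range(len(sim["cfg"].timecourse_factors)):
            _, spk = simulate.simulate_fragments(sim["cfg"], sim["truth"], sim["cs"],
                                                 sim["spike_cs"], ti)
            counts.append(len(spk))
        assert len(set(counts)) == 1
        assert counts[0] == sim["cfg"].spike_fragments

    def test_primary_count_scales_with_timecourse(self, sim):
        cfg = sim["cfg"]
        first, _ = simulate.simulate_fragments(cfg, sim["truth"], sim["cs"],
                                               sim["spike_cs"], 0)
        last, _ = simulate.simulate_fragments(cfg, sim["truth"], sim["cs"],
                                              sim["spike_cs"],
                                              len(cfg.timecourse_factors) - 1)
        fold = cfg.timecourse_factors[-1] / cfg.timecourse_factors[0]
        assert len(last) / len(first) == pytest.approx(fold, rel=0.1)

    def test_zero_background_fragments_near_sites(self):
        cfg = simulate.default_config(seed=5, genome_length=80000, n_chroms=1,
                                      n_direct_sites=10, n_indirect_sites=0,
                                      n_centromere_sites=0, background_rate=0.0,
                                      nucs_per_site=0)
        genome, truth, cs, scs = simulate.make_genome(cfg)
        prim, _ = simulate.simulate_fragments(cfg, truth, cs, scs, 0)
        centers = truth.sites.set_index("chrom")["center"]
        mids = (prim.df["start"] + prim.df["end"]) // 2
        by_center = truth.sites["center"].to_numpy()
        for mid in mids:
            assert np.abs(by_center - mid).min() < 300

    def test_fragment_length_mode_matches_analytic_pmf(self, sim):
        """The sampled TF fragment-length mode equals the mode of the exact
        end-offset convolution, which is the configured value."""
        cfg = sim["cfg"]
        pmf = simulate.tf_length_pmf(cfg)
        assert pmf.idxmax() == cfg.tf_frag_len_mode
        tf = sim["primary"].df.query("frag_class == 'tf_direct'")
        lengths = (tf["end"] - tf["start"]).value_counts()
        assert abs(lengths.idxmax() - cfg.tf_frag_len_mode) <= 5

    def test_hotspot_template_end_offsets(self):
        cfg = simulate.default_config(seed=6, genome_length=100000, n_chroms=1,
                                      n_direct_sites=20, n_indirect_sites=0,
                                      n_centromere_sites=0, background_rate=0.0,
                                      nucs_per_site=0, hotspot_offsets=(-22, 22))
        genome, truth, cs, scs = simulate.make_genome(cfg)
        prim, _ = simulate.simulate_fragments(cfg, truth, cs, scs, 0)
        # most common start offset relative to site center should be the
        # left hotspot (oriented -22)
        offs = []
        for row in truth.sites.itertuples(index=False):
            sub = prim.df[(prim.df["chrom"] == row.chrom)
                          & (abs(prim.df["start"] - row.center) < 200)]
            for s, e in zip(sub["start"], sub["end"]):
                if row.strand == "+":
                    offs.extend([s - row.center, e - 1 - row.center])
                else:
                    offs.extend([row.center - 1 - s, row.center - 1 - (e - 1)])
        vals, counts = np.unique(offs, return_counts=True)
        top2 = set(vals[np.argsort(counts)[-2:]])
        assert top2 == {-22, 22}


class TestSimulateFractions:
    def test_boundary_rates(self, sim):
        cfg = simulate.default_config(
            seed=sim["cfg"].seed,
            soluble_fraction_by_class={"tf_direct": 1.0, "tf_indirect": 1.0,
                                       "nucleosome": 1.0, "background": 1.0,
                                       "centromere": 0.0})
        soluble, total = simulate.simulate_fractions(cfg, sim["primary"])
        assert "centromere" not in set(soluble.df["frag_class"])
        n_cen = (total.df["frag_class"] == "centromere").sum()
        assert len(soluble) == len(total) - n_cen

    def test_thinning_fraction_binomial(self, sim):
        cfg, frags = sim["cfg"], sim["primary"]
        soluble, total = simulate.simulate_fractions(cfg, frags)
        for cls, rate in cfg.soluble_fraction_by_class.items():
            n = (total.df["frag_class"] == cls).sum()
            if n < 200:
                continue
            k = (soluble.df["frag_class"] == cls).sum()
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(k / n - rate) < 5 * se + 1e-12

    def test_missing_class_rate_errors(self, sim):
        cfg = simulate.default_config(seed=0, soluble_fraction_by_class={"tf_direct": 1.0})
        with pytest.raises(ValueError, match="missing"):
            simulate.simulate_fractions(cfg, sim["primary"])

    def test_deterministic(self, sim):
        s1, _ = simulate.simulate_fractions(sim["cfg"], sim["primary"])
        s2, _ = simulate.simulate_fractions(sim["cfg"], sim["primary"])
        assert s1.df.equals(s2.df)


class TestFastaOutput:
    def test_write_read_round_trip(self, tmp_path, sim):
        from pyfaidx import Fasta
        path = tmp_path / "g.fa"
        simulate.write_fasta(sim["genome"], path)
        fa = Fasta(str(path))
        for chrom, seq in sim["genome"].items():
            assert str(fa[chrom][:]) == seq
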