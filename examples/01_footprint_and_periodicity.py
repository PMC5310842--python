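"""Protected footprint and flank cleavage periodicity.

Simulates a TF profiled by antibody-tethered nuclease cleavage, builds
the spike-normalized fragment-end density track from the <=120 bp size
class, aggregates it over the planted motif sites, and measures the
protected-footprint width and the periodicity of the flanking cleavage
comb.
"""

from tethermap import aggregate, fragments, simulate, tracks

cfg = simulate.default_config(seed=1, frags_per_site=60)
genome, truth, cs, spike_cs = simulate.make_genome(cfg)
primary, spike = simulate.simulate_fragments(cfg, truth, cs, spike_cs, time_index=0)

tf_class = fragments.size_select(primary, max_len=120)
ends = tracks.normalize_spikein(tracks.end_density_track(tf_class, cs), len(spike))

matrix = aggregate.site_matrix(ends, truth.site_tuples("direct"), flank=1000)
profile = aggregate.mean_profile(matrix)

width = aggregate.footprint_width(profile)
ac = aggregate.periodicity_autocorrelation(profile)

print(f"sites aggregated:        {len(matrix)}")
print(f"footprint width:         {width} bp")
print(f"dominant cleavage period: {ac.period} bp "
      f"(autocorrelation {ac.values[ac.period]:.2f})")
# The footprint width is the span of depleted cleavage where the bound
# factor protects DNA (generative truth: 20 bp); the ~10 bp period
# reflects helically phased nuclease access on the flanks.
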