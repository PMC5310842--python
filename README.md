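# tethermap

Analysis of antibody-tethered nuclease chromatin profiling (CUT&RUN-style)
data: from mapped paired-end fragment intervals to normalized cleavage
tracks, protected footprints, percentile-threshold peaks, occupancy
heat-map matrices, solubility log-ratios and direct/indirect 3D-contact
classification.

## The problem

In tethered-nuclease profiling, an antibody directs a Protein A–MNase
fusion to a chromatin-bound factor in situ; calcium-activated cleavage on
both sides of the factor releases the protein–DNA particle into the
soluble supernatant, which is sequenced paired-end. Each sequenced
fragment is therefore bounded by two cleavage events next to a bound
particle, which makes the *fragment ends* as informative as coverage:

* fragments protected by a transcription factor are short (length mode
  ~100 bp) and leave a sharp cleavage-free **footprint** (~20 bp) over the
  motif, flanked by cleavage with ~10 bp helical periodicity;
* nucleosomal fragments are longer (mode ~150 bp) and phased around sites;
* a constant amount of heterologous **spike-in** DNA per reaction lets
  samples be compared on an absolute scale: dividing a track by the
  spike-in read count preserves the true fold change along a digestion
  time course, where dividing by total sample reads (standard
  normalization) cancels it;
* the per-base log2(Total/Soluble) ratio of fractionated samples maps
  **insoluble** chromatin (e.g. centromeric particles that are cleaved but
  not released);
* cleavage peaks without a native-ChIP counterpart are **indirect** sites
  — 3D contact partners of directly bound sites — testable against
  ChIA-PET/Hi-C style contact-fragment pairs.

The package is aimed at computational biologists analysing such data or
developing methods for it. Because published analyses of this kind hinge
on external sequencing accessions, `tethermap` ships a first-class
synthetic-data generator (`tethermap.simulate`) that emulates the full
generative structure above with a planted ground truth, so every operator
is testable — and the package demonstrable — without downloads.

## Core quantities

With fragment set F over genome G, per-base tracks are

* end density `E(x) = #{f in F : x = start(f) or x = end(f) - 1}` (mass 2|F|),
* coverage `C(x) = #{f in F : start(f) <= x < end(f)}`,
* standard normalization `E(x) / N_ends`, spike-in normalization
  `E(x) * s / N_spike`.

Motif-centered aggregation builds the sites × relative-position matrix
`M[i, p] = T(c_i + p)` (minus-strand rows reversed), from which come mean
and median profiles, the footprint width (maximal central run below a
fraction of the distal flank level), the autocorrelation-based cleavage
period of the smoothed-residual profile, tram-track separation (distance
between flanking end-density maxima), occupancy scores
(`sum[-30,30) - sum flanks`) and cumulative count curves. Peaks are
maximal runs above a track-value percentile (default 99.5, nonzero
positions), merged across gaps < 100 bp and filtered to 50–1000 bp.

## Worked example

```python
from tethermap import aggregate, fragments, simulate, tracks

cfg = simulate.default_config(seed=1, frags_per_site=60)
genome, truth, cs, spike_cs = simulate.make_genome(cfg)
primary, spike = simulate.simulate_fragments(cfg, truth, cs, spike_cs, time_index=0)

tf_class = fragments.size_select(primary, max_len=120)        # TF size class
ends = tracks.normalize_spikein(tracks.end_density_track(tf_class, cs), len(spike))
matrix = aggregate.site_matrix(ends, truth.site_tuples("direct"), flank=1000)
profile = aggregate.mean_profile(matrix)

print(aggregate.footprint_width(profile))
print(aggregate.periodicity_autocorrelation(profile).period)
```

prints (run as `python examples/01_footprint_and_periodicity.py`):

```
sites aggregated:        200
footprint width:         20 bp
dominant cleavage period: 10 bp (autocorrelation 0.86)
```

i.e. the aggregated end-density profile over the 200 planted motif sites
shows a 20 bp cleavage-free protected span — the bound factor's footprint
— and the flanking cleavage comb repeats every 10 bp, the helical access
period of DNA. The other `examples/` scripts cover the spike-in time
course (the measured 4.06-fold change vs 1.02 under standard
normalization), peak calling with motif recovery, direct/indirect contact
classification, and insoluble-chromatin mapping.

A thin CLI mirrors the library (`tethermap simulate|tracks|aggregate|
peaks|run`); `tethermap run config.yaml` executes the YAML-driven
end-to-end pipeline and writes a provenance manifest.

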