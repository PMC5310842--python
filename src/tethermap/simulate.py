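"""Synthetic antibody-tethered nuclease profiling data.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without external downloads:

* a random genome with an exact consensus motif planted at *direct*
  sites (random strand), motif-free *indirect* sites that are 3D-contact
  partners of direct sites, and unoriented *centromere-like* sites whose
  cleavage products stay insoluble;
* TF-class fragments whose two ends are cleavage positions drawn from a
  flank distribution that is zero across a protected core (20 bp by
  default), carries a ~10 bp-periodic comb rising to a peak and decaying
  over ~100 bp — placing the fragment-length mode near 100 bp — and,
  for the CTCF-like template, concentrated cleavage hotspots at fixed
  offsets (+/-22 bp, i.e. tram-tracks 44 bp apart);
* nucleosome-class fragments (length mode ~150 bp) phased around sites;
* uniform background cleavage, excluded (like all cleavage) from
  protein-protected cores;
* a heterologous spike-in genome receiving a constant fragment yield
  while a digestion time course scales all primary cleavage;
* soluble/total fractionation by per-class release probabilities.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import ChromSizes, FragmentSet

__all__ = ["SimConfig", "TruthTable", "make_genome", "simulate_fragments",
           "simulate_fractions", "write_fasta", "default_config"]

SITE_CLASSES = ("direct", "indirect", "centromere")
FRAG_CLASSES = ("tf_direct", "tf_indirect", "centromere", "nucleosome", "background")


@dataclasses.dataclass
class SimConfig:
    """Generative parameters; defaults encode the canonical observations
    of tethered-nuclease profiling (fragment modes ~100/~150 bp, ~20 bp
    protected core, ~10 bp flank cleavage periodicity decaying over
    ~100 bp, 44 bp hotspot spacing for the CTCF-like template, constant
    spike-in yield along a digestion time course)."""

    seed: int = 0
    genome_length: int = 600_000          # summed over chromosomes
    n_chroms: int = 3
    motif: str = "ACGTGGACTCAT"           # planted consensus (non-palindromic)
    n_direct_sites: int = 200
    n_indirect_sites: int = 40
    n_centromere_sites: int = 8
    tf_frag_len_mode: int = 100
    nuc_frag_len_mode: int = 150
    nuc_frag_len_disp: float = 6.0
    protected_halfwidth: int = 10         # 20 bp protected core
    flank_period: int = 10
    flank_decay_span: int = 100
    comb_base: float = 0.15               # off-spike weight relative to spikes
    flank_sigma: float | None = None      # envelope width; default span / 7
    hotspot_offsets: tuple[int, int] | None = None   # e.g. (-22, 22) CTCF-like
    hotspot_weight: float = 0.6
    frags_per_site: int = 60              # Poisson mean, TF class
    nucs_per_site: int = 20               # Poisson mean, nucleosome class
    indirect_rate_range: tuple[float, float] = (0.3, 1.5)
    background_rate: float = 20.0         # fragments per kb of genome
    bg_len_mean: float = 120.0
    bg_len_sd: float = 40.0
    min_frag_len: int = 20
    max_frag_len: int = 500
    spike_genome_length: int = 50_000
    spike_fragments: int = 2000           # exact count, constant over time
    timecourse_factors: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    soluble_fraction_by_class: dict = dataclasses.field(default_factory=lambda: {
        "tf_direct": 0.95, "tf_indirect": 0.95, "nucleosome": 0.85,
        "background": 0.6, "centromere": 0.02})
    nucleosome_phasing: int = 165         # dyad-to-dyad spacing
    first_dyad_offset: int = 95           # first phased dyad from site center
    site_spacing: int = 2200              # grid spacing between planted sites
    edge_margin: int = 1100               # keep sites clear of chromosome ends

    def validate(self) -> None:
        if self.protected_halfwidth >= self.flank_decay_span:
            raise ValueError("protected_halfwidth must be < flank_decay_span")
        if any(f <= 0 for f in self.timecourse_factors):
            raise ValueError("timecourse_factors must be positive")
        if self.hotspot_offsets is not None:
            lo, hi = self.hotspot_offsets
            if not (lo < 0 < hi):
                raise ValueError("hotspot_offsets must straddle the center")
            if min(abs(lo), hi) <= self.protected_halfwidth:
                raise ValueError("hotspot offsets must lie outside the protected core")


def default_config(**overrides) -> SimConfig:
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


@dataclasses.dataclass
class TruthTable:
    """Planted ground truth: one row per site with class, strand, rate
    scale and contact partner; fragment provenance is carried on the
    fragment tables as a ``frag_class`` column."""

    sites: pd.DataFrame   # site_id chrom center start end strand site_class rate_scale partner_id

    def of_class(self, site_class: str) -> pd.DataFrame:
        return self.sites[self.sites["site_class"] == site_class].reset_index(drop=True)

    def site_tuples(self, site_class: str = "direct") -> list[tuple]:
        sub = self.of_class(site_class)
        return list(zip(sub["chrom"], sub["center"], sub["strand"]))

    def contact_pairs(self, anchor_halfwidth: int = 400,
                      score_scale: float = 20.0) -> pd.DataFrame:
        """BEDPE-style contact fragments linking each indirect site to its
        direct partner; interaction score proportional to the indirect
        site's planted cleavage rate."""
        ind = self.of_class("indirect")
        by_id = self.sites.set_index("site_id")
        rows = []
        for row in ind.itertuples(index=False):
            partner = by_id.loc[row.partner_id]
            rows.append((partner["chrom"],
                         int(partner["center"]) - anchor_halfwidth,
                         int(partner["center"]) + anchor_halfwidth,
                         row.chrom,
                         int(row.center) - anchor_halfwidth,
                         int(row.center) + anchor_halfwidth,
                         score_scale * row.rate_scale))
        return pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a",
                                           "chrom_b", "start_b", "end_b", "score"])

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.sites.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.site_class}_{row.site_id}\t{row.rate_scale:.3f}\t{row.strand}\n")


_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_genome(cfg: SimConfig
                ) -> tuple[dict[str, str], TruthTable, ChromSizes, ChromSizes]:
    """Random genome with planted sites; deterministic under cfg.seed.

    Direct sites carry the exact consensus motif (reverse-complemented on
    - strand); indirect and centromere-like sites are motif-free.  Sites
    sit on a jittered grid at least ~2 kb apart and clear of chromosome
    edges.  Returns (sequences, truth, primary ChromSizes, spike
    ChromSizes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.genome_length // cfg.n_chroms
    names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cs = ChromSizes({n: chrom_len for n in names}, label="primary")
    spike_cs = ChromSizes({"spike_1": cfg.spike_genome_length}, label="spike-in")

    # jittered grid of candidate site centers, >= site_spacing - 2*jitter apart
    jitter = 100
    slots = []
    for name in names:
        pos = cfg.edge_margin
        while pos < chrom_len - cfg.edge_margin:
            slots.append((name, pos))
            pos += cfg.site_spacing
    n_sites = cfg.n_direct_sites + cfg.n_indirect_sites + cfg.n_centromere_sites
    if n_sites > len(slots):
        raise ValueError(f"cannot place {n_sites} sites: at most {len(slots)} fit "
                         f"with spacing {cfg.site_spacing} on this genome")
    chosen = rng.choice(len(slots), size=n_sites, replace=False)
    classes = (["direct"] * cfg.n_direct_sites
               + ["indirect"] * cfg.n_indirect_sites
               + ["centromere"] * cfg.n_centromere_sites)
    rng.shuffle(classes)

    genome = {n: rng.choice(_BASES, size=chrom_len) for n in names}
    w = len(cfg.motif)
    rows = []
    for site_id, (slot_idx, site_class) in enumerate(zip(chosen, classes)):
        chrom, base_pos = slots[slot_idx]
        center = int(base_pos + rng.integers(-jitter, jitter + 1))
        strand = "+" if site_class == "centromere" else ("+" if rng.random() < 0.5 else "-")
        start, end = center - w // 2, center - w // 2 + w
        if site_class == "direct":
            motif = cfg.motif if strand == "+" else _revcomp(cfg.motif)
            genome[chrom][start:end] = list(motif)
        rate = 1.0
        if site_class == "indirect":
            lo, hi = cfg.indirect_rate_range
            rate = float(rng.uniform(lo, hi))
        rows.append((site_id, chrom, center, start, end, strand, site_class, rate, -1))
    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "center", "start", "end",
                                        "strand", "site_class", "rate_scale", "partner_id"])

    # pair each indirect site with a random direct partner (contact truth)
    direct_ids = sites.loc[sites["site_class"] == "direct", "site_id"].to_numpy()
    ind_mask = sites["site_class"] == "indirect"
    if ind_mask.any():
        if len(direct_ids) == 0:
            raise ValueError("indirect sites require at least one direct site")
        partners = rng.choice(direct_ids, size=int(ind_mask.sum()), replace=True)
        sites.loc[ind_mask, "partner_id"] = partners

    # avoid chance motif hits: re-randomize any accidental exact occurrence
    sequences = {n: "".join(v) for n, v in genome.items()}
    sequences = _scrub_chance_motifs(sequences, sites, cfg, rng)
    return sequences, TruthTable(sites=sites), cs, spike_cs


def _scrub_chance_motifs(sequences: dict[str, str], sites: pd.DataFrame,
                         cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Mutate one base of any consensus occurrence not planted at a direct
    site, so motif scans recover exactly the truth set."""
    motifs = {cfg.motif, _revcomp(cfg.motif)}
    planted = {(r.chrom, r.start) for r in
               sites[sites["site_class"] == "direct"].itertuples(index=False)}
    out = {}
    for chrom, seq in sequences.items():
        arr = list(seq)
        for m in motifs:
            pos = seq.find(m)
            while pos != -1:
                if (chrom, pos) not in planted:
                    i = pos + int(rng.integers(0, len(m)))
                    current = arr[i]
                    choices = [b for b in "ACGT" if b != current]
                    arr[i] = choices[int(rng.integers(0, 3))]
                pos = seq.find(m, pos + 1)
        out[chrom] = "".join(arr)
    return out


def _end_weights(cfg: SimConfig) -> np.ndarray:
    """Weight over cleavage distances d = 0..span-1 outside the core edge:
    a periodic comb (spikes every flank_period bp, phase chosen so the
    modal fragment length equals tf_frag_len_mode) under a symmetric
    bell envelope whose peak sits mid-flank and whose tails decay to
    background over flank_decay_span.  Envelope symmetry about the peak
    makes the mode of the end-offset convolution — the fragment-length
    mode — land exactly at the configured value."""
    span = cfg.flank_decay_span
    d = np.arange(span, dtype=float)
    mu = max(0.0, (cfg.tf_frag_len_mode - 2 * cfg.protected_halfwidth - 2) / 2.0)
    mu = min(mu, span - 1.0)
    sigma = cfg.flank_sigma if cfg.flank_sigma is not None else span / 7.0
    env = np.exp(-0.5 * ((d - mu) / sigma) ** 2)
    phase = cfg.flank_period - 1
    comb = np.where(d.astype(int) % cfg.flank_period == phase, 1.0, cfg.comb_base)
    wts = env * comb
    return wts / wts.sum()


def tf_length_pmf(cfg: SimConfig) -> pd.Series:
    """Exact fragment-length distribution implied by independent end
    sampling (no hotspots): length = 2*halfwidth + 2 + dL + dR."""
    w = _end_weights(cfg)
    conv = np.convolve(w, w)
    lengths = np.arange(len(conv)) + 2 * cfg.protected_halfwidth + 2
    return pd.Series(conv, index=lengths)


def _sample_tf_ends(cfg: SimConfig, rng: np.random.Generator, n: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Oriented cleavage offsets (left, right) for n TF-class fragments."""
    w = _end_weights(cfg)
    span = len(w)
    ph = cfg.protected_halfwidth
    left = -ph - 1 - rng.choice(span, size=n, p=w)
    right = ph + rng.choice(span, size=n, p=w)
    if cfg.hotspot_offsets is not None:
        lo, hi = cfg.hotspot_offsets
        left = np.where(rng.random(n) < cfg.hotspot_weight, lo, left)
        right = np.where(rng.random(n) < cfg.hotspot_weight, hi, right)
    return left, right


def _oriented_to_genomic(center: int, strand: str, offsets: np.ndarray) -> np.ndarray:
    """Map oriented offsets to genomic base positions.  The - strand
    mirror (center - 1 - o) keeps the protected core at the same genomic
    interval [center - hw, center + hw) for both strands, and oriented
    aggregation re-aligns features exactly."""
    if strand == "+":
        return center + offsets
    return center - 1 - offsets


def _blocked_masks(truth: TruthTable, cs: ChromSizes, ph: int) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in cs.items()}
    for row in truth.sites.itertuples(index=False):
        lo = max(0, row.center - ph)
        hi = min(cs[row.chrom], row.center + ph)
        masks[row.chrom][lo:hi] = True
    return masks


def simulate_fragments(cfg: SimConfig, truth: TruthTable, cs: ChromSizes,
                       spike_cs: ChromSizes, time_index: int = 0
                       ) -> tuple[FragmentSet, FragmentSet]:
    """Draw one time point's primary and spike-in fragment sets.

    Site-level fragment counts are Poisson with mean scaled by the time
    point's cleavage multiplier; spike-in yield is a constant fragment
    count.  No fragment end (of any class) falls inside a protected core
    — protein-bound DNA is not cleavable.  Deterministic under
    (cfg.seed, time_index).
    """
    if not 0 <= time_index < len(cfg.timecourse_factors):
        raise ValueError(f"time_index {time_index} outside timecourse_factors")
    factor = cfg.timecourse_factors[time_index]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919 + time_index]))
    blocked = _blocked_masks(truth, cs, cfg.protected_halfwidth)
    ph = cfg.protected_halfwidth

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    classes: list[str] = []

    def emit(chrom, start, end, frag_class):
        chroms.append(chrom)
        starts.append(int(start))
        ends.append(int(end))
        classes.append(frag_class)

    # --- TF-class fragments at direct, indirect and centromere-like sites
    for row in truth.sites.itertuples(index=False):
        rate = cfg.frags_per_site * factor * row.rate_scale
        n = int(rng.poisson(rate))
        if n == 0:
            continue
        left, right = _sample_tf_ends(cfg, rng, n)
        lengths = right - left + 1
        ok = (lengths >= cfg.min_frag_len) & (lengths <= cfg.max_frag_len)
        gl = _oriented_to_genomic(row.center, row.strand, left[ok])
        gr = _oriented_to_genomic(row.center, row.strand, right[ok])
        lo = np.minimum(gl, gr)
        hi = np.maximum(gl, gr)
        frag_class = {"direct": "tf_direct", "indirect": "tf_indirect",
                      "centromere": "centromere"}[row.site_class]
        for s, e in zip(lo, hi + 1):
            if s >= 0 and e <= cs[row.chrom]:
                emit(row.chrom, s, e, frag_class)

    # --- phased nucleosome-class fragments flanking every site
    dyad_ks = np.array([0, 1, 2])
    dyad_wts = np.array([0.5, 0.3, 0.2])
    for row in truth.sites.itertuples(index=False):
        n = int(rng.poisson(cfg.nucs_per_site * factor))
        if n == 0:
            continue
        k = rng.choice(dyad_ks, size=n, p=dyad_wts)
        side = rng.choice([-1, 1], size=n)
        dyad_off = side * (cfg.first_dyad_offset + k * cfg.nucleosome_phasing)
        dyad_off = dyad_off + rng.integers(-8, 9, size=n)
        lengths = np.rint(rng.normal(cfg.nuc_frag_len_mode,
                                     cfg.nuc_frag_len_disp, size=n)).astype(int)
        lengths = np.clip(lengths, cfg.min_frag_len, cfg.max_frag_len)
        dyads = _oriented_to_genomic(row.center, row.strand, dyad_off)
        s_arr = dyads - lengths // 2
        e_arr = s_arr + lengths
        m = blocked[row.chrom]
        for s, e in zip(s_arr, e_arr):
            if s < 0 or e > cs[row.chrom] or m[s] or m[e - 1]:
                continue  # drop fragments cut inside a protected core
            emit(row.chrom, s, e, "nucleosome")

    # --- uniform background, excluded from protected cores
    chrom_names = list(cs.sizes)
    clens = np.array([cs[c] for c in chrom_names], dtype=float)
    n_bg = int(rng.poisson(cfg.background_rate * cs.total_length() / 1000.0 * factor))
    bg_chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=clens / clens.sum())
    bg_len = np.clip(np.rint(rng.normal(cfg.bg_len_mean, cfg.bg_len_sd, size=n_bg)),
                     cfg.min_frag_len, cfg.max_frag_len).astype(int)
    for ci, ln in zip(bg_chrom_idx, bg_len):
        chrom = chrom_names[ci]
        m = blocked[chrom]
        for _ in range(10):  # resample cleavage blocked by bound protein
            s = int(rng.integers(0, cs[chrom] - ln + 1))
            e = s + int(ln)
            if not (m[s] or m[e - 1]):
                emit(chrom, s, e, "background")
                break

    primary = FragmentSet(
        df=pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                         "frag_class": classes}),
        genome="primary",
        meta={"time_index": time_index, "timecourse_factor": factor,
              "fraction": "total", "seed": cfg.seed})

    # --- spike-in genome: constant yield regardless of digestion time
    sp_chrom = list(spike_cs.sizes)[0]
    sp_len = np.clip(np.rint(rng.normal(120, 30, size=cfg.spike_fragments)),
                     cfg.min_frag_len, cfg.max_frag_len).astype(int)
    sp_start = rng.integers(0, spike_cs[sp_chrom] - sp_len + 1)
    spike = FragmentSet(
        df=pd.DataFrame({"chrom": sp_chrom, "start": sp_start,
                         "end": sp_start + sp_len}),
        genome="spike-in",
        meta={"time_index": time_index, "fraction": "total", "seed": cfg.seed})
    return primary.sort(), spike.sort()


def simulate_fractions(cfg: SimConfig, fragments: FragmentSet
                       ) -> tuple[FragmentSet, FragmentSet]:
    """Split a total fragment set into (soluble, total) by per-class
    Bernoulli release; centromere-like particles stay insoluble (release
    probability near zero) so they appear only in total DNA."""
    if "frag_class" not in fragments.df.columns:
        raise ValueError("fragment set lacks frag_class provenance")
    rates = cfg.soluble_fraction_by_class
    missing = set(fragments.df["frag_class"]) - set(rates)
    if missing:
        raise ValueError(f"soluble_fraction_by_class missing classes {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed, 104729, int(fragments.meta.get("time_index", 0))]))
    p = fragments.df["frag_class"].map(rates).to_numpy(dtype=float)
    keep = rng.random(len(p)) < p
    soluble = FragmentSet(df=fragments.df[keep].reset_index(drop=True),
                          genome=fragments.genome,
                          meta={**fragments.meta, "fraction": "soluble"})
    total = FragmentSet(df=fragments.df.copy(),
                        genome=fragments.genome,
                        meta={**fragments.meta, "fraction": "total"})
    return soluble, total
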