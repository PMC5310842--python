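"""Per-base genomic signal tracks and their normalization.

Two raw track types are built from a fragment set:

* end-density — each fragment contributes +1 at both of its terminal bases
  (two cleavage events per released fragment), total mass ``2 * n``;
* coverage — each base covered by a fragment gains +1, total mass equal to
  the summed fragment lengths.

Two normalizations are provided.  Standard normalization divides every
base by the total number of mapped read ends of the sample (one constant
per sample, shared by its end and coverage tracks).  Spike-in
normalization divides by the number of fragments mapped to a heterologous
spike-in genome carried through the reaction at constant yield, which
preserves absolute between-sample scale (e.g. along a digestion
time course) where standard normalization cancels it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import ChromSizes, FragmentSet

__all__ = [
    "GenomicTrack",
    "NormalizationStats",
    "end_density_track",
    "coverage_track",
    "normalize_standard",
    "normalize_spikein",
    "split_by_genome",
    "percent_release",
    "write_bedgraph",
    "read_bedgraph",
]


class GenomicTrack:
    """Dense per-base float signal, one vector per chromosome.

    ``semantics`` labels the value scale: ``raw-count``, ``per-total-ends``,
    ``per-spike-read``, or a derived label such as ``log2-ratio``.
    """

    def __init__(self, data: dict[str, np.ndarray], semantics: str = "raw-count"):
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in data.items()}
        self.semantics = semantics

    @classmethod
    def zeros(cls, cs: ChromSizes, semantics: str = "raw-count") -> "GenomicTrack":
        return cls({c: np.zeros(n) for c, n in cs.items()}, semantics=semantics)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data

    def chroms(self):
        return list(self.data)

    def sum(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self, semantics: str | None = None) -> "GenomicTrack":
        return GenomicTrack({c: v.copy() for c, v in self.data.items()},
                            semantics=semantics or self.semantics)

    def scaled(self, factor: float, semantics: str) -> "GenomicTrack":
        return GenomicTrack({c: v * factor for c, v in self.data.items()},
                            semantics=semantics)

    def values_concat(self) -> np.ndarray:
        return np.concatenate([v for v in self.data.values()]) if self.data else np.array([])

    def __repr__(self):
        return f"GenomicTrack({len(self.data)} chroms, semantics={self.semantics!r})"


@dataclasses.dataclass
class NormalizationStats:
    primary_mapped_ends: int = 0
    spike_reads: int = 0
    factor: float = float("nan")


def end_density_track(fs: FragmentSet, cs: ChromSizes) -> GenomicTrack:
    """Count fragment termini per base: +1 at ``start`` and at ``end - 1``.

    A length-1 fragment contributes 2 to its single base; the track sum is
    always twice the fragment count.
    """
    fs.validate(cs)
    track = GenomicTrack.zeros(cs)
    for chrom, sub in fs.df.groupby("chrom", sort=False):
        n = cs[chrom]
        left = np.bincount(sub["start"].to_numpy(), minlength=n)
        right = np.bincount(sub["end"].to_numpy() - 1, minlength=n)
        track.data[chrom] += left + right
    return track


def coverage_track(fs: FragmentSet, cs: ChromSizes) -> GenomicTrack:
    """Fragment occupancy per base over each ``[start, end)`` interval."""
    fs.validate(cs)
    track = GenomicTrack.zeros(cs)
    for chrom, sub in fs.df.groupby("chrom", sort=False):
        n = cs[chrom]
        delta = np.zeros(n + 1)
        np.add.at(delta, sub["start"].to_numpy(), 1.0)
        np.add.at(delta, sub["end"].to_numpy(), -1.0)
        track.data[chrom] += np.cumsum(delta[:-1])
    return track


def normalize_standard(t: GenomicTrack, total_mapped_ends: int) -> GenomicTrack:
    """Divide every base by the sample's total mapped read ends."""
    if total_mapped_ends <= 0:
        raise ValueError("total_mapped_ends must be > 0")
    return t.scaled(1.0 / total_mapped_ends, "per-total-ends")


def normalize_spikein(t: GenomicTrack, spike_reads: int, scale: float = 1.0) -> GenomicTrack:
    """Scale every base by ``scale / spike_reads`` (spike-in normalization)."""
    if spike_reads <= 0:
        raise ValueError(
            "spike_reads must be > 0: no spike-in fragments were detected; "
            "check that spike-in chromosomes are present in the alignment")
    return t.scaled(scale / spike_reads, "per-spike-read")


def split_by_genome(fs: FragmentSet, primary_cs: ChromSizes,
                    spike_cs: ChromSizes) -> tuple[FragmentSet, FragmentSet, NormalizationStats]:
    """Partition fragments between the primary and spike-in genome namespaces.

    Fragments on chromosomes known to neither genome are rejected and
    counted.  The returned stats carry the standard-normalization
    denominator (2 ends per primary fragment) and the spike read count.
    """
    overlap = set(primary_cs.sizes) & set(spike_cs.sizes)
    if overlap:
        raise ValueError(f"chromosome namespaces overlap: {sorted(overlap)[:3]}")
    chroms = fs.df["chrom"]
    in_primary = chroms.isin(primary_cs.sizes).to_numpy()
    in_spike = chroms.isin(spike_cs.sizes).to_numpy()
    rejected = int((~in_primary & ~in_spike).sum())
    primary = FragmentSet(df=fs.df[in_primary].reset_index(drop=True),
                          genome=primary_cs.label, meta=dict(fs.meta))
    spike = FragmentSet(df=fs.df[in_spike].reset_index(drop=True),
                        genome=spike_cs.label, meta=dict(fs.meta),
                        n_rejected=rejected)
    stats = NormalizationStats(primary_mapped_ends=2 * len(primary),
                               spike_reads=len(spike))
    if stats.spike_reads > 0:
        stats.factor = 1.0 / stats.spike_reads
    return primary, spike, stats


def percent_release(supernatant_amount: float, pellet_amount: float) -> float:
    """Percent of material released into the supernatant:
    ``100 * supn / (supn + pellet)``."""
    if supernatant_amount < 0 or pellet_amount < 0:
        raise ValueError("amounts must be >= 0")
    total = supernatant_amount + pellet_amount
    if total == 0:
        raise ValueError("both amounts are zero")
    return 100.0 * supernatant_amount / total


def write_bedgraph(t: GenomicTrack, path: str | Path, decimals: int | None = None) -> None:
    """Write a run-length-compressed 4-column bedGraph; zero runs omitted.

    ``decimals`` switches from full float repr to fixed-point formatting
    for bit-exact file diffs.
    """
    with open(path, "w") as fh:
        for chrom in t.chroms():
            v = t.data[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                if decimals is None:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(val)!r}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:.{decimals}f}\n")


def read_bedgraph(path: str | Path, cs: ChromSizes,
                  semantics: str = "raw-count") -> GenomicTrack:
    """Read a 4-column bedGraph into a dense track; overlapping intervals
    are an error."""
    track = GenomicTrack.zeros(cs, semantics=semantics)
    last_end: dict[str, int] = {}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str},
                     comment="#")
    if len(df) == 0:
        return track
    df = df.sort_values(["chrom", "start"], kind="stable")
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in cs:
            raise ValueError(f"unknown chromosome {chrom!r} in bedGraph")
        if start < last_end.get(chrom, 0) and chrom in last_end:
            raise ValueError(f"overlapping bedGraph intervals on {chrom} at {start}")
        if end > cs[chrom] or start < 0 or end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        track.data[chrom][start:end] = value
        last_end[chrom] = max(last_end.get(chrom, 0), end)
    return track
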