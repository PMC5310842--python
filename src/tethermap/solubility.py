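"""Insoluble-chromatin inference from fractionated cleavage tracks.

Tethered-nuclease digestion releases most particles into the soluble
supernatant, but large or anchored complexes (e.g. centromeric
kinetochores) stay in the pellet and appear only when total DNA is
extracted.  The per-base log2 ratio of total over soluble signal,
log2(Insoluble) = log2(Total) - log2(Soluble), therefore maps insoluble
occupancy.  Fraction tracks should share normalization semantics
(spike-in normalized by default, so the ratio reflects absolute
recovery).
"""

from __future__ import annotations

import numpy as np

from .aggregate import AggregateProfile
from .tracks import GenomicTrack

__all__ = [
    "insoluble_log_ratio",
    "high_vs_low_salt_ratio",
    "median_midpoint_profile",
]


def _log_ratio(numer: GenomicTrack, denom: GenomicTrack,
               pseudocount: float, semantics: str) -> GenomicTrack:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(numer.data) != set(denom.data):
        raise ValueError("tracks cover different chromosomes")
    out = {}
    for chrom, nv in numer.data.items():
        dv = denom.data[chrom]
        if len(nv) != len(dv):
            raise ValueError(f"track shapes differ on {chrom}")
        out[chrom] = np.log2((nv + pseudocount) / (dv + pseudocount))
    return GenomicTrack(out, semantics=semantics)


def insoluble_log_ratio(total: GenomicTrack, soluble: GenomicTrack,
                        pseudocount: float = 1.0) -> GenomicTrack:
    """Per-base log2((total + pc) / (soluble + pc)); positive values mark
    spans recovered only by total DNA extraction, i.e. insoluble
    chromatin."""
    return _log_ratio(total, soluble, pseudocount, "log2-total-over-soluble")


def high_vs_low_salt_ratio(high: GenomicTrack, low: GenomicTrack,
                           pseudocount: float = 1.0) -> GenomicTrack:
    """Per-base log2 ratio of high-salt over low-salt extracted signal;
    same contract as :func:`insoluble_log_ratio` with the fraction roles
    renamed."""
    return _log_ratio(high, low, pseudocount, "log2-high-over-low-salt")


def median_midpoint_profile(t: GenomicTrack, midpoints, flank: int) -> AggregateProfile:
    """Columnwise median over midpoint-centered windows.

    Midpoints are (chrom, position) pairs; windows are *not* strand
    oriented (the anchors — e.g. centromeres — are unoriented features).
    Midpoints whose window crosses a chromosome edge are dropped; at
    least one must survive.
    """
    rows = []
    for chrom, pos in midpoints:
        if chrom not in t:
            continue
        vec = t.data[chrom]
        lo, hi = int(pos) - flank, int(pos) + flank
        if lo < 0 or hi > len(vec):
            continue
        rows.append(vec[lo:hi])
    if not rows:
        raise ValueError("no midpoints survive boundary clipping")
    vals = np.median(np.vstack(rows), axis=0)
    return AggregateProfile(positions=np.arange(-flank, flank), values=vals,
                            provenance="median")
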