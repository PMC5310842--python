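"""Percentile-threshold peak calling.

Sparse tethered-nuclease tracks need no background model: the threshold
is a high percentile (default 99.5) of the per-base normalized counts at
nonzero positions, computed genome-wide.  Above-threshold runs are
merged across gaps shorter than the interpeak distance and then filtered
by width.  The percentile uses linear interpolation between order
statistics (numpy's default, the "type 7" convention) so calls are
bit-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import GenomicTrack

__all__ = [
    "call_peaks",
    "peak_motif_fraction",
    "threshold_for_peak_count",
    "peaks_to_bed",
]

PEAK_COLUMNS = ["chrom", "start", "end", "score", "summit"]


def _runs_at_or_above(v: np.ndarray, theta: float) -> list[tuple[int, int]]:
    mask = v >= theta
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(v))
    return list(zip(starts, ends))


def peak_threshold(t: GenomicTrack, percentile: float = 99.5,
                   nonzero_only: bool = True) -> float:
    """Percentile threshold over per-base values; by default only nonzero
    positions enter the percentile, since the zero-dominated remainder of
    the genome would otherwise pin a high percentile near zero."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    vals = t.values_concat()
    if nonzero_only:
        vals = vals[vals > 0]
    if len(vals) == 0:
        raise ValueError("track has no nonzero values")
    return float(np.percentile(vals, percentile))


def call_peaks(t: GenomicTrack, percentile: float = 99.5, interpeak: int = 100,
               min_width: int = 50, max_width: int = 1000,
               nonzero_only: bool = True,
               merge_before_filter: bool = True) -> pd.DataFrame:
    """Threshold-method peak calling.

    1. theta = the given percentile of per-base values (nonzero positions,
       genome-wide); 2. maximal runs with value >= theta are candidates;
    3. candidates separated by gaps < ``interpeak`` are merged; 4. merged
    intervals narrower than ``min_width`` or wider than ``max_width`` are
    discarded; 5. score = sum of track values and summit = leftmost
    maximum position within each final interval.

    Returns a DataFrame with columns chrom, start, end, score, summit,
    sorted by coordinate.
    """
    theta = peak_threshold(t, percentile, nonzero_only)
    rows = []
    for chrom in t.chroms():
        v = t.data[chrom]
        runs = _runs_at_or_above(v, theta)
        if not merge_before_filter:
            runs = [(s, e) for s, e in runs if min_width <= e - s <= max_width]
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < interpeak:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        if merge_before_filter:
            merged = [r for r in merged if min_width <= r[1] - r[0] <= max_width]
        for s, e in merged:
            seg = v[s:e]
            rows.append((chrom, s, e, float(seg.sum()), s + int(np.argmax(seg))))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def peak_motif_fraction(peaks: pd.DataFrame, sites, slop: int = 0) -> float:
    """Fraction of peaks whose (slop-extended) interval overlaps at least
    one motif site by >= 1 bp."""
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    site_iv: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        if isinstance(s, (tuple, list)):
            chrom, start, end = s[0], int(s[1]), int(s[2])
        else:
            chrom, start, end = s.chrom, s.start, s.end
        site_iv.setdefault(chrom, []).append((start, end))
    starts_by, ends_by = {}, {}
    for chrom, ivs in site_iv.items():
        ivs.sort()
        starts_by[chrom] = np.array([i[0] for i in ivs])
        ends_by[chrom] = np.maximum.accumulate(np.array([i[1] for i in ivs]))
    n_hit = 0
    for chrom, pstart, pend in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in starts_by:
            continue
        lo, hi = pstart - slop, pend + slop
        starts = starts_by[chrom]
        idx = np.searchsorted(starts, hi)  # sites starting before peak end
        if idx > 0 and ends_by[chrom][idx - 1] > lo:
            n_hit += 1
    return n_hit / len(peaks)


def threshold_for_peak_count(t: GenomicTrack, target_n: int,
                             interpeak: int = 100, min_width: int = 50,
                             max_width: int = 1000, nonzero_only: bool = True,
                             iterations: int = 40) -> float:
    """Percentile whose peak count is closest to ``target_n``.

    Binary search over the percentile; peak count is (essentially)
    non-increasing in the threshold, so bisection converges; the closest
    achievable count is returned when the target is unreachable.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")

    def count(pct: float) -> int:
        return len(call_peaks(t, pct, interpeak, min_width, max_width, nonzero_only))

    lo, hi = 1.0, 99.999
    best = (abs(count(lo) - target_n), lo)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        n = count(mid)
        if abs(n - target_n) < best[0]:
            best = (abs(n - target_n), mid)
        if n > target_n:
            lo = mid        # too many peaks -> raise threshold
        elif n < target_n:
            hi = mid
        else:
            return mid
    return best[1]


def peaks_to_bed(peaks: pd.DataFrame, path: str | Path,
                 integer_scores: bool = False) -> None:
    """Write peaks as BED6 (name = index, strand '.')."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            score = int(round(row.score)) if integer_scores else row.score
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak_{i}\t{score}\t.\n")
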