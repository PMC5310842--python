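"""Oriented motif sites and log-odds matrix scanning.

Motif occurrences are represented in + strand coordinates with an
explicit strand; a site's center base is ``start + width // 2``.
Position frequency matrices (JASPAR text format, parsed with
``Bio.motifs``) are converted to log-odds with a configurable
pseudocount.  Significance is a plain log-odds threshold: deterministic
site lists are what downstream aggregation needs, and simulated genomes
provide ground truth for choosing it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PSSM",
    "MotifSite",
    "score_window",
    "scan_pssm",
    "best_motif_score",
    "remove_cross_proximal",
    "site_center",
    "sites_to_bed",
    "read_sites_bed",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PSSM:
    """Log-odds position-specific scoring matrix.

    ``matrix`` has shape (width, 4) in A, C, G, T column order.  ``N``
    bases score the background-weighted mean of their column.
    """

    def __init__(self, matrix: np.ndarray, background: np.ndarray | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise ValueError("PSSM matrix must have shape (width, 4)")
        if not np.isfinite(matrix).all():
            raise ValueError("PSSM scores must be finite")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if not np.isclose(background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        self.matrix = matrix
        self.background = background
        # column score assigned to N: background expectation of the column
        self._n_scores = matrix @ background

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.matrix[::-1, ::-1].copy(), self.background[::-1].copy())

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> "PSSM":
        """Log2-odds from a position count/frequency matrix with pseudocount
        added per base."""
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        probs = counts + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(np.log2(probs / background), background)

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.91,
                       pseudocount: float = 0.25) -> "PSSM":
        """A sharp matrix for an exact consensus: the stated probability on
        the consensus base, the remainder split among the other three."""
        counts = np.zeros((len(consensus), 4))
        n_virtual = 100.0
        off = (1.0 - match_prob) / 3.0
        for i, base in enumerate(consensus.upper()):
            counts[i] = off * n_virtual
            counts[i, _CODE[base]] = match_prob * n_virtual
        return cls.from_counts(counts, pseudocount=pseudocount)

    @classmethod
    def from_jaspar(cls, path: str | Path, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> "PSSM":
        """Read a JASPAR-format PFM text file."""
        from Bio import motifs

        with open(path) as fh:
            motif = motifs.read(fh, "jaspar")
        counts = np.array([[motif.counts[b][i] for b in _ALPHABET]
                           for i in range(motif.length)], dtype=float)
        return cls.from_counts(counts, pseudocount=pseudocount, background=background)


@dataclasses.dataclass(frozen=True)
class MotifSite:
    """One oriented motif occurrence; ``end - start`` equals the matrix
    width and coordinates are always on the + strand frame."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2


def site_center(site) -> int:
    """Center base of a site: ``start + width // 2`` (even widths round
    toward ``end``)."""
    return site.start + (site.end - site.start) // 2


def encode(seq: str) -> np.ndarray:
    """DNA string to integer codes A=0 C=1 G=2 T=3, N(or other)=4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def score_window(seq: str, pssm: PSSM) -> float:
    """Log-odds score of one window of exactly the matrix width."""
    if len(seq) != pssm.width:
        raise ValueError(f"window length {len(seq)} != PSSM width {pssm.width}")
    codes = encode(seq)
    score = 0.0
    for i, c in enumerate(codes):
        score += pssm._n_scores[i] if c == 4 else pssm.matrix[i, c]
    return float(score)


def _score_all_windows(codes: np.ndarray, pssm: PSSM) -> np.ndarray:
    """Vector of scores for every window start on the + strand of *codes*."""
    w = pssm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    ext = np.hstack([pssm.matrix, pssm._n_scores[:, None]])  # column 4 = N
    for i in range(w):
        scores += ext[i, codes[i:i + n]]
    return scores


def scan_pssm(genome: dict[str, str], pssm: PSSM, min_score: float) -> list[MotifSite]:
    """Report every window on either strand scoring >= ``min_score``.

    The - strand is scored via the reverse-complement matrix so that all
    coordinates stay on the + strand frame.  Output is sorted by
    (chrom, start), + strand first at equal coordinates.
    """
    rc = pssm.reverse_complement()
    hits: list[MotifSite] = []
    for chrom in genome:
        seq = str(genome[chrom])
        codes = encode(seq)
        fwd = _score_all_windows(codes, pssm)
        rev = _score_all_windows(codes, rc)
        for start in np.flatnonzero(fwd >= min_score):
            hits.append(MotifSite(chrom, int(start), int(start) + pssm.width, "+",
                                  float(fwd[start])))
        for start in np.flatnonzero(rev >= min_score):
            hits.append(MotifSite(chrom, int(start), int(start) + pssm.width, "-",
                                  float(rev[start])))
    hits.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return hits


def best_motif_score(chrom: str, start: int, end: int, genome: dict[str, str],
                     pssm: PSSM, extend: int = 100) -> tuple[float, int, str]:
    """Best log-odds match in ``[start - extend, end + extend)`` over both
    strands.

    Returns ``(score, window_start, strand)``; ties resolve to the
    leftmost window, then the + strand.  The window set is clipped at
    chromosome bounds.
    """
    seq = str(genome[chrom])
    lo = max(0, start - extend)
    hi = min(len(seq), end + extend)
    codes = encode(seq[lo:hi])
    fwd = _score_all_windows(codes, pssm)
    rev = _score_all_windows(codes, pssm.reverse_complement())
    if len(fwd) == 0:
        raise ValueError("interval (after extension/clipping) shorter than motif width")
    best = (-np.inf, -1, "+")
    for pos in range(len(fwd)):
        for strand, sc in (("+", fwd[pos]), ("-", rev[pos])):
            if sc > best[0]:
                best = (float(sc), lo + pos, strand)
    return best


def remove_cross_proximal(sites_a: list, sites_b: list,
                          dist: int = 50) -> tuple[list, list]:
    """Reciprocally drop sites whose centers lie within ``dist`` bp of a
    center in the other list (used to keep two factors' site sets
    non-confounded before aggregation)."""
    if not sites_a or not sites_b:
        return list(sites_a), list(sites_b)

    def near(site, others_by_chrom):
        c = site_center(site)
        arr = others_by_chrom.get(site.chrom)
        if arr is None or len(arr) == 0:
            return False
        idx = np.searchsorted(arr, c)
        for j in (idx - 1, idx):
            if 0 <= j < len(arr) and abs(int(arr[j]) - c) <= dist:
                return True
        return False

    def by_chrom(sites):
        out: dict[str, np.ndarray] = {}
        df = pd.DataFrame({"chrom": [s.chrom for s in sites],
                           "center": [site_center(s) for s in sites]})
        for chrom, sub in df.groupby("chrom"):
            out[chrom] = np.sort(sub["center"].to_numpy())
        return out

    a_centers, b_centers = by_chrom(sites_a), by_chrom(sites_b)
    kept_a = [s for s in sites_a if not near(s, b_centers)]
    kept_b = [s for s in sites_b if not near(s, a_centers)]
    return kept_a, kept_b


def sites_to_bed(sites: list, path: str | Path) -> None:
    """Write sites as BED6 (score column = raw log-odds)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i}\t{s.score:.4f}\t{s.strand}\n")


def read_sites_bed(path: str | Path) -> list[MotifSite]:
    """Read a BED6 site list (strand in column 6, score in column 5)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                f = line.split()
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5].strip() if len(f) > 5 else "+"
            sites.append(MotifSite(f[0], int(f[1]), int(f[2]), strand, score))
    return sites
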