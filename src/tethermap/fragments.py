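"""Mapped paired-end fragment collections.

The sequencing unit throughout this package is the *fragment*: the genomic
interval spanned by one sequenced paired-end insert, in 0-based half-open
(BED) coordinates.  Fragment length is ``end - start``, i.e. the insert
length.  Duplicate fragments are retained by default; tethered-nuclease
protocols release each cleaved particle once and no deduplication step is
assumed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "FragmentSet",
    "read_fragments",
    "read_chrom_sizes",
    "size_select",
    "length_distribution",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


class ChromSizes:
    """Chromosome name -> length mapping for one genome namespace.

    ``label`` distinguishes the primary genome from a heterologous
    spike-in genome; the two namespaces must not share chromosome names.
    """

    def __init__(self, sizes: Mapping[str, int], label: str = "primary"):
        for name, length in sizes.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length} < 1")
        if len(set(sizes)) != len(sizes):
            raise ValueError("duplicate chromosome names")
        self.sizes: dict[str, int] = dict(sizes)
        self.label = label

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def items(self):
        return self.sizes.items()

    def total_length(self) -> int:
        return sum(self.sizes.values())

    def __repr__(self) -> str:
        return f"ChromSizes({len(self.sizes)} chroms, label={self.label!r})"

    @classmethod
    def from_file(cls, path: str | Path, label: str = "primary") -> "ChromSizes":
        """Read a two-column ``chrom.sizes`` TSV."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"].astype(int))), label=label)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path, label: str = "primary") -> ChromSizes:
    return ChromSizes.from_file(path, label=label)


@dataclasses.dataclass
class FragmentSet:
    """An ordered collection of mapped fragments plus sample metadata.

    ``df`` holds columns ``chrom``, ``start``, ``end`` and optionally
    ``frag_class`` (simulator provenance).  ``meta`` carries free-form
    sample annotations such as digestion time or fraction
    (soluble | total | high-salt).
    """

    df: pd.DataFrame
    genome: str = "primary"
    meta: dict = dataclasses.field(default_factory=dict)
    n_rejected: int = 0

    def __post_init__(self):
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def sort(self) -> "FragmentSet":
        out = self.df.sort_values(FRAGMENT_COLUMNS, kind="stable").reset_index(drop=True)
        return dataclasses.replace(self, df=out)

    def validate(self, cs: ChromSizes) -> None:
        """Raise if any fragment violates coordinate invariants against *cs*."""
        df = self.df
        bad = df[~(df["start"] < df["end"]) | (df["start"] < 0)]
        if len(bad):
            raise ValueError(f"{len(bad)} fragments with invalid coordinates")
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in cs:
                raise ValueError(f"chromosome {chrom!r} not in ChromSizes")
            if (sub["end"] > cs[chrom]).any():
                raise ValueError(f"fragment beyond end of {chrom}")

    def to_bed(self, path: str | Path) -> None:
        self.df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_records(cls, records: Iterable[tuple], **kw) -> "FragmentSet":
        df = pd.DataFrame(list(records), columns=FRAGMENT_COLUMNS)
        return cls(df=df, **kw)


class BedParseError(ValueError):
    pass


def _read_bed_fragments(path: str | Path, cs: ChromSizes) -> FragmentSet:
    rows = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0 or chrom not in cs or end > cs[chrom]:
                rejected += 1
                continue
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return FragmentSet(df=df, genome=cs.label, n_rejected=rejected)


def _read_paired_alignments(path: str | Path, cs: ChromSizes) -> FragmentSet:
    """Derive one fragment per properly paired alignment (outer mate span).

    Uses the leftmost mate's record: fragment = [pos, pos + TLEN) with
    TLEN > 0, the standard insert interval for FR paired-end data.
    """
    import pysam

    rows = []
    rejected = 0
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.mate_is_unmapped or not read.is_paired
                    or read.is_secondary or read.is_supplementary):
                continue
            tlen = read.template_length
            if tlen <= 0:  # keep only the leftmost mate of each pair
                continue
            chrom = read.reference_name
            start = read.reference_start
            end = start + tlen
            if chrom not in cs or end > cs[chrom] or end <= start:
                rejected += 1
                continue
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return FragmentSet(df=df, genome=cs.label, n_rejected=rejected)


def read_fragments(path: str | Path, cs: ChromSizes,
                   format: str = "bed") -> FragmentSet:
    """Read mapped paired-end fragments from BED3+ or a paired alignment file.

    Fragments on unknown chromosomes, with ``end <= start``, or running off
    the chromosome end are rejected and counted in ``FragmentSet.n_rejected``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        return _read_bed_fragments(path, cs)
    if format in ("paired-alignment", "sam", "bam"):
        return _read_paired_alignments(path, cs)
    raise ValueError(f"unknown fragment format {format!r}")


def size_select(fs: FragmentSet, min_len: int | None = None,
                max_len: int | None = None) -> FragmentSet:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive bounds).

    The defaults for the two canonical size classes of tethered-nuclease
    data are <=120 bp (TF-protected) and >=150 bp (nucleosomal); both are
    caller-supplied here, not constants.
    """
    if min_len is not None and max_len is not None and min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    lengths = fs.df["end"] - fs.df["start"]
    keep = pd.Series(True, index=fs.df.index)
    if min_len is not None:
        keep &= lengths >= min_len
    if max_len is not None:
        keep &= lengths <= max_len
    return dataclasses.replace(fs, df=fs.df[keep].reset_index(drop=True))


def length_distribution(fs: FragmentSet, normalize: bool = False) -> pd.Series:
    """Fragment-length histogram over 1-bp bins.

    With ``normalize`` the values are fractions summing to 1 (the
    convention used for comparing size distributions between samples at
    each length step).
    """
    if normalize and len(fs) == 0:
        raise ValueError("cannot normalize an empty fragment set")
    counts = pd.Series(fs.lengths).value_counts().sort_index()
    counts.index.name = "length"
    if normalize:
        return counts / counts.sum()
    return counts.astype(float)
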