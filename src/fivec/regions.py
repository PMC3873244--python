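"""Genomic intervals, in-silico restriction digestion, and interval algebra.

Coordinates are 0-based half-open throughout the package.  Published
chromosome-conformation coordinates are conventionally 1-based inclusive
(e.g. mm9 chr6:52,099,908-53,050,000); use :meth:`GenomicInterval.from_one_based`
when ingesting such spans.  Restriction digestion places every fragment
boundary at the first base of a recognition-site occurrence
(:data:`CUT_OFFSET`); all downstream logic keys on fragment identity, so any
fixed offset convention would serve, but this one makes a fragment's leading
bases reconstitute the site, which is what ligation-junction reads look like.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

#: EcoRI recognition sequence; the enzyme used for both the 3C and 5C maps.
ECORI_SITE = "GAATTC"

#: Offset of the fragment boundary within a recognition-site occurrence.
CUT_OFFSET = 0

#: Fragments longer than this (bp) cannot host 5C primers.
MAX_FRAGMENT_LENGTH = 20_000
#: Fragments shorter than this (bp) cannot host 5C primers.
MIN_FRAGMENT_LENGTH = 100

_VALID_STRANDS = {"+", "-", "."}
_SEQ_RE = re.compile(r"^[ACGTN]+$")
_SITE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @classmethod
    def from_one_based(cls, seq_name: str, start: int, end: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (the printed-table convention)."""
        return cls(seq_name, start - 1, end, strand)

    def to_one_based(self) -> tuple[str, int, int]:
        return self.seq_name, self.start + 1, self.end

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return overlaps(self, other, min_bp=min_bp)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def padded(self, pad: int) -> "GenomicInterval":
        return replace(self, start=max(0, self.start - pad), end=self.end + pad)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.seq_name}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases.

    Intervals on different sequences never overlap.  ``min_bp`` must be >= 1
    (half-open adjacency is not overlap).
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return a.overlap_length(b) >= min_bp


@dataclass
class RestrictionFragment:
    """One fragment of an in-silico digest.

    Consecutive fragments abut exactly; every internal boundary coincides
    with a recognition-site occurrence (at :data:`CUT_OFFSET`).
    """

    interval: GenomicInterval
    index: int
    eligible: bool = True
    exclusion_reason: str = "none"  # none | too_large | too_small

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint


def find_sites(sequence: str, site: str = ECORI_SITE) -> list[int]:
    """Start offsets of non-overlapping ``site`` occurrences, left-to-right greedy.

    Overlapping occurrences (impossible for GAATTC, possible for user sites)
    are resolved by accepting the leftmost and resuming the scan after it.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    if not _SITE_RE.match(site):
        raise ValueError(f"recognition site must be A/C/G/T only, got {site!r}")
    positions: list[int] = []
    pos = sequence.find(site)
    while pos != -1:
        positions.append(pos)
        pos = sequence.find(site, pos + len(site))
    return positions


def digest(sequence: str, site: str = ECORI_SITE, seq_name: str = "region") -> list[RestrictionFragment]:
    """In-silico restriction digest.

    Fragments tile ``[0, len(sequence))`` with a boundary at the start of
    every (non-overlapping) site occurrence.  A site starting at offset 0
    yields no cut, since a zero-length leading fragment cannot exist;
    this also makes re-digestion of any fragment a no-op.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if not _SEQ_RE.match(sequence):
        raise ValueError("sequence must be uppercase A/C/G/T/N")
    cuts = [p + CUT_OFFSET for p in find_sites(sequence, site) if p + CUT_OFFSET > 0]
    edges = [0, *cuts, len(sequence)]
    fragments = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        fragments.append(
            RestrictionFragment(interval=GenomicInterval(seq_name, lo, hi), index=i)
        )
    return fragments


def filter_fragments(
    fragments: list[RestrictionFragment],
    max_len: int = MAX_FRAGMENT_LENGTH,
    min_len: int = MIN_FRAGMENT_LENGTH,
) -> list[RestrictionFragment]:
    """Flag fragments too large (> max_len) or too small (< min_len) for primers.

    Thresholds are read strictly, so fragments of exactly ``min_len`` or
    ``max_len`` remain eligible.  Coordinates and ordering are untouched;
    the input list is updated in place and returned.
    """
    for frag in fragments:
        if frag.length > max_len:
            frag.eligible = False
            frag.exclusion_reason = "too_large"
        elif frag.length < min_len:
            frag.eligible = False
            frag.exclusion_reason = "too_small"
        else:
            frag.eligible = True
            frag.exclusion_reason = "none"
    return fragments


def eligible_fragments(fragments: Iterable[RestrictionFragment]) -> list[RestrictionFragment]:
    return [f for f in fragments if f.eligible]


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fragments_bed(fragments: Iterable[RestrictionFragment], path: str | Path) -> None:
    """Write a fragment map as BED6 (name = index, score = length, strand '.')."""
    with open(path, "w") as fh:
        for frag in fragments:
            iv = frag.interval
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{frag.index}\t{frag.length}\t.\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED file (first three columns; native 0-based)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path,
                        names: Iterable[str] | None = None) -> None:
    names_it: Iterator[str] = iter(names) if names is not None else iter(())
    with open(path, "w") as fh:
        for iv in intervals:
            name = next(names_it, ".")
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{name}\n")
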