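"""Junction-read mapping, filtering, and interaction tallies.

A junction read is one sequenced ligation product.  Reads are mapped
against the junction reference (all forward x reverse primer-pair
sequences) and then pass three filters before entering the interaction
frequency list:

* mapping quality at least ``min_quality`` (default 30),
* alignment starting no more than ``max_offset`` nucleotides away from the
  reference start (default 2; absolute value, direction is not penalised),
* presence of the restriction site in the read (ligation junctions
  reconstitute it; reads without it are artefacts).

Mapping here is a deterministic stand-in for an external aligner: a read
maps to the unique reference it matches allowing a start shift of up to
``max_scan`` nucleotides and up to ``max_mismatch`` substitutions.  An
exact-match hash over all shifted reference suffixes handles the bulk of
reads; a vectorised Hamming scan covers substituted ones.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .design import JunctionReference
from .regions import ECORI_SITE

DEFAULT_MAX_SCAN = 5
DEFAULT_MAX_MISMATCH = 2

#: Rejection reasons, in tally order.
REASONS = ("low_quality", "unmapped", "offset", "no_site")


@dataclass
class JunctionRead:
    sequence: str
    quality: int
    mapped_pair: tuple[str, str] | None = None
    offset: int | None = None

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")


@dataclass(frozen=True)
class InteractionRecord:
    forward_id: str
    reverse_id: str
    raw_count: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.forward_id, self.reverse_id)


class ReferenceIndex:
    """Maps read sequences to primer pairs.

    Stage 1 is an exact dictionary over every reference suffix obtained by
    trimming 0..max_scan leading bases (the only shifts the aligner model
    allows).  Stage 2, for reads that miss it, is a byte-level Hamming
    comparison of the read against every reference at every shift,
    vectorised over references.  A read maps only if exactly one reference
    matches within tolerance; ambiguous or unmatched reads stay unmapped.
    """

    def __init__(self, references: Sequence[JunctionReference],
                 max_scan: int = DEFAULT_MAX_SCAN,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH) -> None:
        if not references:
            raise ValueError("empty reference list")
        self.max_scan = max_scan
        self.max_mismatch = max_mismatch
        self.pairs = [r.pair for r in references]
        self._exact: dict[str, list[tuple[int, int]]] = {}
        for idx, ref in enumerate(references):
            for shift in range(max_scan + 1):
                suffix = ref.sequence[shift:]
                if not suffix:
                    break
                self._exact.setdefault(suffix, []).append((idx, shift))
        self._lengths = np.array([len(r.sequence) for r in references])
        width = int(self._lengths.max())
        mat = np.zeros((len(references), width), dtype=np.uint8)
        for i, ref in enumerate(references):
            mat[i, : len(ref.sequence)] = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        self._matrix = mat

    def map_sequence(self, sequence: str) -> tuple[tuple[str, str] | None, int | None]:
        hits = self._exact.get(sequence)
        if hits is not None:
            ref_ids = {idx for idx, _ in hits}
            if len(ref_ids) == 1:
                idx, shift = min(hits, key=lambda t: t[1])
                return self.pairs[idx], shift
            return None, None  # ambiguous
        return self._scan(sequence)

    def _scan(self, sequence: str) -> tuple[tuple[str, str] | None, int | None]:
        read = np.frombuffer(sequence.encode(), dtype=np.uint8)
        n = len(read)
        if n == 0:
            return None, None
        width = self._matrix.shape[1]
        best: dict[int, int] = {}  # ref index -> smallest matching shift
        for shift in range(self.max_scan + 1):
            avail = width - shift
            k = min(n, avail)
            if k <= 0:
                break
            mism = (self._matrix[:, shift: shift + k] != read[:k]).sum(axis=1)
            # Read bases beyond the end of a reference count as mismatches.
            overhang = np.maximum(0, (shift + n) - self._lengths)
            mism = mism + overhang
            for idx in np.nonzero(mism <= self.max_mismatch)[0]:
                best.setdefault(int(idx), shift)
        if len(best) != 1:
            return None, None
        idx, shift = next(iter(best.items()))
        return self.pairs[idx], shift


def map_read(read: JunctionRead,
             references: Sequence[JunctionReference] | ReferenceIndex) -> JunctionRead:
    """Set ``mapped_pair`` and ``offset`` on a read (None/None if unmappable)."""
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    pair, offset = index.map_sequence(read.sequence)
    read.mapped_pair = pair
    read.offset = offset
    return read


def map_reads(reads: Iterable[JunctionRead],
              references: Sequence[JunctionReference] | ReferenceIndex) -> list[JunctionRead]:
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    return [map_read(r, index) for r in reads]


def filter_reads(
    reads: Sequence[JunctionRead],
    min_quality: int = 30,
    max_offset: int = 2,
    site: str = ECORI_SITE,
) -> tuple[list[JunctionRead], Counter]:
    """Apply the three junction-read filters.

    A read is kept iff quality >= min_quality, |offset| <= max_offset, and
    the recognition site occurs in its sequence.  Rejected reads are
    tallied by the first failing rule, in the order quality, offset, site;
    reads without a mapping are rejected as ``unmapped`` (their offset is
    undefined).  Kept + rejected always partitions the input.
    """
    kept: list[JunctionRead] = []
    tally: Counter = Counter({reason: 0 for reason in REASONS})
    for read in reads:
        if read.quality < min_quality:
            tally["low_quality"] += 1
        elif read.mapped_pair is None or read.offset is None:
            tally["unmapped"] += 1
        elif abs(read.offset) > max_offset:
            tally["offset"] += 1
        elif site not in read.sequence:
            tally["no_site"] += 1
        else:
            kept.append(read)
    return kept, tally


def tally(kept: Sequence[JunctionRead]) -> tuple[list[InteractionRecord], int]:
    """Collapse kept reads into the interaction frequency list (IFL).

    Returns one record per observed primer pair (raw_count >= 1) plus the
    total number of used reads.  Order-invariant; records are sorted by pair.
    """
    counts: Counter = Counter()
    for read in kept:
        if read.mapped_pair is None:
            raise ValueError("tally requires mapped reads")
        counts[read.mapped_pair] += 1
    records = [
        InteractionRecord(fwd, rev, n) for (fwd, rev), n in sorted(counts.items())
    ]
    return records, sum(counts.values())


# ---------------------------------------------------------------------------
# I/O

def read_fastq(path: str | Path) -> list[JunctionRead]:
    """Read FASTQ into junction reads.

    The read's mapping-quality stand-in is the per-read minimum Phred base
    quality (documented convention; the assay's aligner reports a mapping
    quality the simulator models directly).
    """
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        reads.append(JunctionRead(sequence=str(rec.seq).upper(), quality=int(min(quals))))
    return reads


def write_ifl_tsv(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("forward_id\treverse_id\traw_count\n")
        for rec in records:
            fh.write(f"{rec.forward_id}\t{rec.reverse_id}\t{rec.raw_count}\n")


def read_ifl_tsv(path: str | Path) -> list[InteractionRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("forward_id"):
            raise ValueError(f"not an IFL table: {path}")
        for line in fh:
            fwd, rev, count = line.rstrip("\n").split("\t")
            records.append(InteractionRecord(fwd, rev, int(count)))
    return records
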