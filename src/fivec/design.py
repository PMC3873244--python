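"""5C primer designs and the junction reference they imply.

Two experimental layouts are supported.  In the anchored ("cluster R")
scheme, reverse primers cover an anchor region (a gene cluster) and forward
primers tile every other eligible fragment, yielding a genes-versus-region
matrix.  In the alternating ("FR") scheme, forward and reverse primers
alternate along the region, yielding an all-versus-all style matrix.

Primer cores are taken from the fragment end abutting a cut: the forward
core is the last ``primer_len`` bases of its fragment, the reverse core the
first ``primer_len`` bases.  A ligation junction read (forward core followed
by reverse core) therefore contains the restriction site, carried by the
leading bases of the reverse fragment.  Sequencing tails follow the
ligation-mediated-amplification convention: forward primers are prefixed
with the universal A-key, reverse primers suffixed with the P1-key and
phosphorylated at their 5' ends so that they can be ligated.

Thermodynamic melting-temperature optimisation and genome-wide uniqueness
screening belong to external primer designers and are not modelled; an
``excluded`` set of fragment indices lets callers remove fragments such
screens would reject.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .regions import GenomicInterval, RestrictionFragment, overlaps

logger = logging.getLogger(__name__)

#: Universal forward sequencing tail (prefixed to forward primer cores).
A_KEY = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
#: Universal reverse sequencing tail (suffixed to reverse primer cores).
P1_KEY = "ATCACCGACTGCCCATAGAGAGG"

#: Optimal 5C primer core length in nucleotides.
DEFAULT_PRIMER_LENGTH = 30

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class FivecPrimer:
    fragment_index: int
    orientation: str  # forward | reverse
    core_sequence: str
    full_sequence: str
    phosphorylated_5prime: bool
    interval: GenomicInterval

    @property
    def primer_id(self) -> str:
        prefix = "F" if self.orientation == FORWARD else "R"
        return f"{prefix}{self.fragment_index}"


@dataclass(frozen=True)
class JunctionReference:
    """The expected sequence of one forward/reverse ligation product."""

    forward_id: str
    reverse_id: str
    sequence: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.forward_id, self.reverse_id)


@dataclass
class FivecDesign:
    scheme: str  # anchored | alternating
    primers: list[FivecPrimer]
    region: GenomicInterval
    anchor_region: GenomicInterval | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.primers:
            if p.fragment_index in seen:
                raise ValueError(f"fragment {p.fragment_index} carries more than one primer")
            seen.add(p.fragment_index)
        if self.scheme == "anchored" and self.anchor_region is None:
            raise ValueError("anchored scheme requires an anchor_region")

    @property
    def forward_primers(self) -> list[FivecPrimer]:
        return [p for p in self.primers if p.orientation == FORWARD]

    @property
    def reverse_primers(self) -> list[FivecPrimer]:
        return [p for p in self.primers if p.orientation == REVERSE]

    def primer_by_id(self, primer_id: str) -> FivecPrimer:
        for p in self.primers:
            if p.primer_id == primer_id:
                return p
        raise KeyError(primer_id)


def _make_primer(fragment: RestrictionFragment, orientation: str, sequence: str,
                 primer_len: int) -> FivecPrimer:
    iv = fragment.interval
    if orientation == FORWARD:
        core = sequence[iv.end - primer_len: iv.end]
        full = A_KEY + core
        phos = False
        piv = GenomicInterval(iv.seq_name, iv.end - primer_len, iv.end, "+")
    else:
        core = sequence[iv.start: iv.start + primer_len]
        full = core + P1_KEY
        phos = True
        piv = GenomicInterval(iv.seq_name, iv.start, iv.start + primer_len, "-")
    return FivecPrimer(fragment.index, orientation, core, full, phos, piv)


def design_primers(
    fragments: Sequence[RestrictionFragment],
    sequence: str,
    scheme: str,
    anchor_region: GenomicInterval | None = None,
    primer_len: int = DEFAULT_PRIMER_LENGTH,
    excluded: Iterable[int] = (),
) -> FivecDesign:
    """Assign at most one primer per eligible fragment under one scheme.

    anchored
        Eligible fragments overlapping ``anchor_region`` receive reverse
        primers; all other eligible fragments receive forward primers.
    alternating
        Eligible fragments receive forward/reverse primers alternately in
        genomic order, starting forward.

    Fragments shorter than ``primer_len``, listed in ``excluded``, or — for
    reverse primers — not starting at a cut (the region's first fragment)
    are skipped with a warning.
    """
    if scheme not in ("anchored", "alternating"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "anchored" and anchor_region is None:
        raise ValueError("anchored scheme requires an anchor_region")
    excluded = set(excluded)
    ordered = sorted((f for f in fragments if f.eligible), key=lambda f: f.start)
    usable = []
    for frag in ordered:
        if frag.index in excluded:
            continue
        if frag.length < primer_len:
            logger.warning(
                "fragment %d (%d bp) shorter than primer length %d; skipped",
                frag.index, frag.length, primer_len,
            )
            continue
        usable.append(frag)
    if not usable:
        raise ValueError("no eligible fragments can host primers")

    region_start = min(f.start for f in fragments)
    primers: list[FivecPrimer] = []

    def want_reverse_ok(frag: RestrictionFragment) -> bool:
        # The first fragment of the region does not start at a cut, so a
        # reverse primer there would not reconstitute the site at junctions.
        if frag.start == region_start:
            logger.warning(
                "fragment %d starts the region (no upstream cut); reverse primer skipped",
                frag.index,
            )
            return False
        return True

    if scheme == "anchored":
        assert anchor_region is not None
        anchored = [f for f in usable if overlaps(f.interval, anchor_region)]
        if not anchored:
            raise ValueError("anchor region overlaps no eligible fragment")
        for frag in usable:
            if frag in anchored:
                if want_reverse_ok(frag):
                    primers.append(_make_primer(frag, REVERSE, sequence, primer_len))
            else:
                primers.append(_make_primer(frag, FORWARD, sequence, primer_len))
    else:
        orientation = FORWARD
        for frag in usable:
            if orientation == REVERSE and not want_reverse_ok(frag):
                continue  # orientation is not consumed by a skipped fragment
            primers.append(_make_primer(frag, orientation, sequence, primer_len))
            orientation = REVERSE if orientation == FORWARD else FORWARD

    region = GenomicInterval(
        fragments[0].interval.seq_name,
        min(f.start for f in fragments),
        max(f.end for f in fragments),
    )
    return FivecDesign(scheme=scheme, primers=primers, region=region, anchor_region=anchor_region)


def junction_reference(design: FivecDesign) -> list[JunctionReference]:
    """All possible forward x reverse ligation-product sequences.

    One entry per (forward, reverse) primer pair; the reference sequence is
    the forward core followed by the reverse core and contains the
    restriction site at the junction by the core-placement convention.
    """
    fwd = design.forward_primers
    rev = design.reverse_primers
    if not fwd or not rev:
        raise ValueError("design must contain at least one forward and one reverse primer")
    return [
        JunctionReference(f.primer_id, r.primer_id, f.core_sequence + r.core_sequence)
        for f in fwd
        for r in rev
    ]


# ---------------------------------------------------------------------------
# I/O

def write_primers_fasta(design: FivecDesign, path: str | Path) -> None:
    """FASTA of full primer sequences; ids encode fragment, orientation, coords."""
    with open(path, "w") as fh:
        for p in sorted(design.primers, key=lambda p: p.interval.start):
            iv = p.interval
            fh.write(f">{p.primer_id}|{p.orientation}|{iv.seq_name}:{iv.start}-{iv.end}\n")
            fh.write(p.full_sequence + "\n")


def write_design_table(design: FivecDesign, path: str | Path) -> None:
    """TSV design table: one primer per row."""
    cols = "primer_id\tfragment_index\torientation\tchrom\tstart\tend\tcore_sequence\tfull_sequence\tphosphorylated_5prime\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for p in sorted(design.primers, key=lambda p: p.interval.start):
            iv = p.interval
            fh.write(
                f"{p.primer_id}\t{p.fragment_index}\t{p.orientation}\t{iv.seq_name}\t"
                f"{iv.start}\t{iv.end}\t{p.core_sequence}\t{p.full_sequence}\t"
                f"{int(p.phosphorylated_5prime)}\n"
            )
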