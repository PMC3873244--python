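"""Candidate-enhancer calling from multi-mark ChIP peak sets.

A locus is nominated as a candidate enhancer when it is distinct from
proximal promoters and either (branch A) bound by RNA polymerase II plus at
least one other assayed mark, or (branch B) bound by both p300 and
H3K27Ac.  The candidate interval is the union of the seed peak and its
overlapping supporting peaks; candidates within ``promoter_pad`` of an
annotated promoter are removed, and overlapping candidates are merged with
their supporting marks unioned.

Peak calling itself (and its significance thresholds) is upstream of this
module: peaks arrive as BED-style intervals per mark.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .regions import GenomicInterval, overlaps, read_bed_intervals

BRANCH_RNAP2 = "rnap2_plus_one"
BRANCH_PAIR = "p300_h3k27ac"

DEFAULT_PROMOTER_PAD = 1_000


@dataclass
class PeakSet:
    mark: str
    peaks: list[GenomicInterval]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        order = sorted(range(len(self.peaks)), key=lambda i: (self.peaks[i].seq_name,
                                                              self.peaks[i].start))
        self.peaks = [self.peaks[i] for i in order]
        if self.scores is not None:
            if len(self.scores) != len(self.peaks):
                raise ValueError("scores length mismatch")
            if any(s < 0 for s in self.scores):
                raise ValueError("peak scores must be non-negative")
            self.scores = [self.scores[i] for i in order]


@dataclass
class EnhancerCandidate:
    interval: GenomicInterval
    supporting_marks: set[str]
    rule_branch: str


def _span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    return GenomicInterval(
        intervals[0].seq_name,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def call_candidates(
    peaksets: Mapping[str, PeakSet],
    promoters: Sequence[GenomicInterval] = (),
    rnap2_mark: str = "RNAP2",
    pair: tuple[str, str] = ("p300", "H3K27Ac"),
    promoter_pad: int = DEFAULT_PROMOTER_PAD,
) -> list[EnhancerCandidate]:
    """Nominate candidate enhancers from per-mark peak sets.

    Branch A seeds on each RNAP2 peak overlapping at least one peak of any
    other mark; branch B seeds on each p300 peak overlapping an H3K27Ac
    peak.  Overlap means >= 1 bp.  Seeds overlapping a promoter padded by
    ``promoter_pad`` bp are dropped; surviving overlapping seeds merge into
    one candidate whose branch is the first applicable in order (A, B).
    """
    if not peaksets:
        raise ValueError("empty peak-set map")

    seeds: list[EnhancerCandidate] = []

    rnap2 = peaksets.get(rnap2_mark)
    if rnap2 is not None:
        others = {m: ps for m, ps in peaksets.items() if m != rnap2_mark}
        for peak in rnap2.peaks:
            support = [peak]
            marks = {rnap2_mark}
            for mark, ps in others.items():
                hit = [q for q in ps.peaks if overlaps(peak, q)]
                if hit:
                    marks.add(mark)
                    support.extend(hit)
            if len(marks) > 1:
                seeds.append(EnhancerCandidate(_span(support), marks, BRANCH_RNAP2))

    p300 = peaksets.get(pair[0])
    k27 = peaksets.get(pair[1])
    if p300 is not None and k27 is not None:
        for peak in p300.peaks:
            hit = [q for q in k27.peaks if overlaps(peak, q)]
            if hit:
                seeds.append(
                    EnhancerCandidate(_span([peak, *hit]), {pair[0], pair[1]}, BRANCH_PAIR)
                )

    padded = [p.padded(promoter_pad) for p in promoters]
    seeds = [s for s in seeds if not any(overlaps(s.interval, p) for p in padded)]

    seeds.sort(key=lambda s: (s.interval.seq_name, s.interval.start, s.rule_branch))
    merged: list[EnhancerCandidate] = []
    for seed in seeds:
        if merged and overlaps(merged[-1].interval, seed.interval):
            prev = merged[-1]
            branch = BRANCH_RNAP2 if BRANCH_RNAP2 in (prev.rule_branch, seed.rule_branch) else BRANCH_PAIR
            merged[-1] = EnhancerCandidate(
                _span([prev.interval, seed.interval]),
                prev.supporting_marks | seed.supporting_marks,
                branch,
            )
        else:
            merged.append(seed)
    return merged


# ---------------------------------------------------------------------------
# I/O

def load_peakset_bed(mark: str, path: str | Path) -> PeakSet:
    return PeakSet(mark=mark, peaks=read_bed_intervals(path))


def load_peak_table(mark: str, path: str | Path) -> PeakSet:
    """Loader for supplementary-style peak tables: chrom, start, end per row.

    Accepts an optional header line and tab- or whitespace-separated
    columns; coordinates are taken as written (0-based half-open).
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                continue  # header
            peaks.append(GenomicInterval(parts[0], start, end))
    return PeakSet(mark=mark, peaks=peaks)


def write_candidates_bed(candidates: Sequence[EnhancerCandidate], path: str | Path) -> None:
    """BED output: name = rule branch, score = number of supporting marks."""
    with open(path, "w") as fh:
        for c in candidates:
            iv = c.interval
            fh.write(
                f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{c.rule_branch}\t{len(c.supporting_marks)}\t.\n"
            )
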