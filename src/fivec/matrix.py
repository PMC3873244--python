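"""Interaction-frequency matrices: build, normalize, bin, smooth, subtract, compare.

The matrix is the central container of the analysis: rows are forward-primer
fragments (or bins), columns reverse-primer fragments (or bins), values are
interaction frequencies.  Missing cells are NaN and stay missing through
every operation — they are never silently imputed as zero.

Normalization divides each raw count by the total number of reads of the
sequencing run and multiplies by 10^3, so values are reads per thousand.
Binning averages fragment-pair cells per 20 kb bin pair (assignment by
fragment midpoint); smoothing is a uniform 2-D boxcar mean over an 8 kb
genomic-distance window on each axis.  Tissue-differential maps are the
element-wise difference of two identically-shaped normalized matrices
(e.g. limb minus head).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .design import FivecDesign
from .reads import InteractionRecord
from .regions import GenomicInterval, RestrictionFragment

#: Normalized scale: interaction frequencies are reads per this many run reads.
SCALE = 1000.0
#: Pseudo-frequency for log-correlations: one read at the per-1000 scale.
LOG_EPSILON = 1.0 / SCALE

DEFAULT_BIN_SIZE = 20_000
DEFAULT_SMOOTH_WINDOW = 8_000

_STATES = ("raw", "normalized", "binned", "smoothed", "differential", "expected")


@dataclass
class ContactMatrix:
    row_intervals: list[GenomicInterval]
    col_intervals: list[GenomicInterval]
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # float64, NaN = missing
    state: str
    total_run_reads: int | None = None
    genome: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_intervals), len(self.col_intervals)):
            raise ValueError("values shape does not match axes")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        for ivs in (self.row_intervals, self.col_intervals):
            starts = [iv.start for iv in ivs]
            if starts != sorted(starts):
                raise ValueError("axis intervals must be sorted by genomic start")
        if self.state not in ("differential",):
            with np.errstate(invalid="ignore"):
                if np.nanmin(self.values, initial=0.0) < 0:
                    raise ValueError(f"negative values in {self.state} matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def row_midpoints(self) -> np.ndarray:
        return np.array([iv.midpoint for iv in self.row_intervals])

    @property
    def col_midpoints(self) -> np.ndarray:
        return np.array([iv.midpoint for iv in self.col_intervals])

    def same_axes(self, other: "ContactMatrix") -> bool:
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and self.row_intervals == other.row_intervals
            and self.col_intervals == other.col_intervals
        )

    def copy_with(self, values: np.ndarray, state: str) -> "ContactMatrix":
        return ContactMatrix(
            row_intervals=list(self.row_intervals),
            col_intervals=list(self.col_intervals),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            values=values,
            state=state,
            total_run_reads=self.total_run_reads,
            genome=self.genome,
        )


def build(records: Sequence[InteractionRecord], design: FivecDesign,
          fragments: Sequence[RestrictionFragment]) -> ContactMatrix:
    """Raw forward x reverse count matrix from an interaction list.

    Designed pairs that were never observed are 0; fragments without a
    primer have no row/column at all.  A record naming a primer absent from
    the design is an error.
    """
    frag_by_index = {f.index: f for f in fragments}
    fwd = sorted(design.forward_primers, key=lambda p: p.interval.start)
    rev = sorted(design.reverse_primers, key=lambda p: p.interval.start)
    row_ids = [p.primer_id for p in fwd]
    col_ids = [p.primer_id for p in rev]
    row_pos = {pid: i for i, pid in enumerate(row_ids)}
    col_pos = {pid: j for j, pid in enumerate(col_ids)}
    values = np.zeros((len(fwd), len(rev)))
    for rec in records:
        if rec.forward_id not in row_pos or rec.reverse_id not in col_pos:
            raise KeyError(f"record names unknown primer pair {rec.pair}")
        values[row_pos[rec.forward_id], col_pos[rec.reverse_id]] = rec.raw_count
    return ContactMatrix(
        row_intervals=[frag_by_index[p.fragment_index].interval for p in fwd],
        col_intervals=[frag_by_index[p.fragment_index].interval for p in rev],
        row_ids=row_ids,
        col_ids=col_ids,
        values=values,
        state="raw",
    )


def normalize(matrix: ContactMatrix, total_run_reads: int) -> ContactMatrix:
    """Reads-per-thousand normalization: cell * 1000 / total_run_reads.

    ``total_run_reads`` is the number of reads passing filters in the whole
    sequencing run, including control-region contacts.
    """
    if matrix.state != "raw":
        raise ValueError(f"normalize expects a raw matrix, got {matrix.state}")
    if total_run_reads <= 0:
        raise ValueError(f"total_run_reads must be > 0, got {total_run_reads}")
    out = matrix.copy_with(matrix.values * (SCALE / total_run_reads), "normalized")
    out.total_run_reads = total_run_reads
    return out


def _bin_axis(intervals: Sequence[GenomicInterval], origin: int, n_bins: int,
              bin_size: int, end: int, seq_name: str) -> tuple[np.ndarray, list[GenomicInterval], list[str]]:
    assignment = np.array([
        int((iv.midpoint - origin) // bin_size) for iv in intervals
    ])
    assignment = np.clip(assignment, 0, n_bins - 1)
    bins = [
        GenomicInterval(seq_name, origin + k * bin_size, min(origin + (k + 1) * bin_size, end))
        for k in range(n_bins)
    ]
    ids = [f"bin{k}" for k in range(n_bins)]
    return assignment, bins, ids


def bin_matrix(matrix: ContactMatrix, bin_size: int = DEFAULT_BIN_SIZE) -> ContactMatrix:
    """Mean interaction frequency per bin pair.

    Bins tile the matrix extent in ``bin_size`` steps on a grid shared by
    both axes (so symmetric-region designs yield square binned matrices).
    Each fragment pair contributes to exactly one bin pair, chosen by the
    fragment midpoints; bin pairs receiving no non-missing cell are missing.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    if matrix.state not in ("normalized", "raw", "expected"):
        raise ValueError(f"bin expects a fragment-level matrix, got {matrix.state}")
    all_ivs = list(matrix.row_intervals) + list(matrix.col_intervals)
    seq_name = all_ivs[0].seq_name
    origin = min(iv.start for iv in all_ivs)
    end = max(iv.end for iv in all_ivs)
    n_bins = max(1, math.ceil((end - origin) / bin_size))
    row_asg, bins, ids = _bin_axis(matrix.row_intervals, origin, n_bins, bin_size, end, seq_name)
    col_asg, _, _ = _bin_axis(matrix.col_intervals, origin, n_bins, bin_size, end, seq_name)

    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins))
    vals = matrix.values
    nr, nc = vals.shape
    for i in range(nr):
        bi = row_asg[i]
        for j in range(nc):
            v = vals[i, j]
            if not np.isnan(v):
                sums[bi, col_asg[j]] += v
                counts[bi, col_asg[j]] += 1
    with np.errstate(invalid="ignore"):
        binned = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return ContactMatrix(
        row_intervals=bins,
        col_intervals=list(bins),
        row_ids=ids,
        col_ids=list(ids),
        values=binned,
        state="binned",
        total_run_reads=matrix.total_run_reads,
        genome=matrix.genome,
    )


def smooth(matrix: ContactMatrix, window: int = DEFAULT_SMOOTH_WINDOW) -> ContactMatrix:
    """2-D boxcar mean over a genomic-distance window.

    Each output cell is the mean of all non-missing input cells whose row
    and column midpoints lie within +/- window/2 (inclusive) of the target
    cell's midpoints.  Cells whose window holds no data remain missing.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    if matrix.state not in ("normalized", "binned", "expected"):
        raise ValueError(f"smooth expects a normalized or binned matrix, got {matrix.state}")
    half = window / 2.0
    rmid = matrix.row_midpoints
    cmid = matrix.col_midpoints
    rnb = (np.abs(rmid[:, None] - rmid[None, :]) <= half).astype(float)
    cnb = (np.abs(cmid[:, None] - cmid[None, :]) <= half).astype(float)
    mask = ~np.isnan(matrix.values)
    filled = np.where(mask, matrix.values, 0.0)
    sums = rnb @ filled @ cnb.T
    counts = rnb @ mask.astype(float) @ cnb.T
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return matrix.copy_with(out, "smoothed")


def differential(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Tissue-differential map ``a - b`` (e.g. limb minus head).

    Both matrices must be normalized (optionally binned/smoothed) on
    identical axes; raw counts are refused because run depths differ.
    Missing in either input is missing in the output.
    """
    if a.state != b.state:
        raise ValueError(f"state mismatch: {a.state} vs {b.state}")
    if a.state not in ("normalized", "binned", "smoothed"):
        raise ValueError(f"differential requires normalized inputs, got {a.state}")
    if not a.same_axes(b):
        raise ValueError("axis mismatch between matrices")
    out = a.copy_with(a.values - b.values, "differential")
    out.total_run_reads = None
    return out


def replicate_agreement(a: ContactMatrix, b: ContactMatrix,
                        epsilon: float = LOG_EPSILON) -> float:
    """Pearson correlation of log(IF + epsilon) over shared non-missing cells.

    Quantifies biological-replicate reproducibility.  ``epsilon`` defaults
    to one read at the per-1000 scale.  Requires >= 3 shared cells and
    non-constant values.
    """
    if not a.same_axes(b):
        raise ValueError("axis mismatch between matrices")
    shared = ~np.isnan(a.values) & ~np.isnan(b.values)
    if shared.sum() < 3:
        raise ValueError(f"only {int(shared.sum())} shared cells; need >= 3")
    x = np.log(a.values[shared] + epsilon)
    y = np.log(b.values[shared] + epsilon)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant matrices")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# I/O — TSV dialect mirroring published supplementary matrices: axis labels
# are "name|genome|chrom:start-end" with 1-based inclusive coordinates on
# disk, converted on read; values at the per-1000 scale.

def _format_label(name: str, genome: str, iv: GenomicInterval) -> str:
    chrom, start1, end1 = iv.to_one_based()
    return f"{name}|{genome}|{chrom}:{start1}-{end1}"


def _parse_label(label: str) -> tuple[str, str, GenomicInterval]:
    name, genome, span = label.split("|")
    chrom, rng = span.split(":")
    start1, end1 = rng.split("-")
    return name, genome, GenomicInterval.from_one_based(chrom, int(start1), int(end1))


def write_matrix_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = [f"state={matrix.state}"]
        if matrix.total_run_reads is not None:
            header.append(f"total_run_reads={matrix.total_run_reads}")
        fh.write(";".join(header))
        for cid, civ in zip(matrix.col_ids, matrix.col_intervals):
            fh.write("\t" + _format_label(cid, matrix.genome, civ))
        fh.write("\n")
        for i, (rid, riv) in enumerate(zip(matrix.row_ids, matrix.row_intervals)):
            fh.write(_format_label(rid, matrix.genome, riv))
            for v in matrix.values[i]:
                fh.write("\tNA" if np.isnan(v) else f"\t{v:.6g}")
            fh.write("\n")


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    head = lines[0].split("\t")
    meta = dict(
        item.split("=", 1) for item in head[0].split(";") if "=" in item
    )
    col_ids, col_ivs = [], []
    genome = "synthetic"
    for label in head[1:]:
        name, genome, iv = _parse_label(label)
        col_ids.append(name)
        col_ivs.append(iv)
    row_ids, row_ivs, rows = [], [], []
    for line in lines[1:]:
        parts = line.split("\t")
        name, genome, iv = _parse_label(parts[0])
        row_ids.append(name)
        row_ivs.append(iv)
        rows.append([np.nan if p == "NA" else float(p) for p in parts[1:]])
    total = meta.get("total_run_reads")
    return ContactMatrix(
        row_intervals=row_ivs,
        col_intervals=col_ivs,
        row_ids=row_ids,
        col_ids=col_ids,
        values=np.array(rows, dtype=float),
        state=meta.get("state", "normalized"),
        total_run_reads=int(total) if total is not None else None,
        genome=genome,
    )
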