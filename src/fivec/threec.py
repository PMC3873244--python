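"""3C interaction-frequency quantification with BAC-control correction.

Each chromatin contact is quantified by PCR in triplicate from the tissue
3C library (template) and in triplicate from a control library made by
randomly ligating BAC clones covering the region.  Because the control
library contains every possible ligation junction at equimolar ratio, the
control signal measures only primer-pair efficiency, and the ratio
template/control cancels it.  The interaction frequency (IF) of a pair is
the mean of the nine pairwise template/control ratios; biological
replicates are averaged after normalization; and libraries are put on a
common scale with a compaction-profile factor computed over a control
region (a housekeeping locus plus an intergenic reference).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ThreeCMeasurement:
    pair: tuple[str, str]
    template_values: tuple[float, float, float]
    control_values: tuple[float, float, float]

    @property
    def interaction_frequency(self) -> float:
        return compute_if(self.template_values, self.control_values)[0]


def compute_if(template_values: Sequence[float],
               control_values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the nine template/control ratios.

    Exactly three template and three control values are required; controls
    must be strictly positive (the control library is equimolar by
    construction, so a zero control indicates a failed reaction, not
    absence of contact).  Zero templates are fine and give IF = 0.
    """
    if len(template_values) != 3 or len(control_values) != 3:
        raise ValueError("compute_if requires exactly 3 template and 3 control values")
    t = np.asarray(template_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if np.any(t < 0):
        raise ValueError("template values must be non-negative")
    if np.any(c <= 0):
        raise ValueError("control values must be strictly positive")
    ratios = (t[:, None] / c[None, :]).ravel()
    if_ = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / math.sqrt(ratios.size))
    return if_, sem


def average_replicates(
    replicates: Sequence[Mapping[tuple[str, str], float]],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-pair mean and standard error of the mean across replicates.

    All replicates must cover identical pair lists.  With a single
    replicate the mean is the identity and the SEM is reported as 0.0
    (documented convention; a one-point SEM is undefined).
    """
    if not replicates:
        raise ValueError("no replicates given")
    pairs = list(replicates[0])
    for rep in replicates[1:]:
        if set(rep) != set(pairs):
            raise ValueError("replicate pair lists differ")
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for pair in pairs:
        vals = np.array([rep[pair] for rep in replicates], dtype=float)
        if len(vals) == 1:
            out[pair] = (float(vals[0]), 0.0)
        else:
            out[pair] = (float(vals.mean()),
                         float(vals.std(ddof=1) / math.sqrt(len(vals))))
    return out


def cross_library_factor(
    profile: Mapping[tuple[str, str], float],
    reference_profile: Mapping[tuple[str, str], float],
) -> float:
    """Scale factor putting a library onto a reference compaction profile.

    The factor is the mean, over pairs shared with the reference (>= 3
    required), of reference/profile; multiplying the library's IFs by it
    aligns its control-region level with the reference's.
    """
    shared = sorted(set(profile) & set(reference_profile))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared pairs; need >= 3")
    ratios = []
    for pair in shared:
        ref = reference_profile[pair]
        val = profile[pair]
        if ref <= 0:
            raise ValueError(f"non-positive reference IF for pair {pair}")
        if val <= 0:
            raise ValueError(f"non-positive profile IF for pair {pair}")
        ratios.append(ref / val)
    return float(np.mean(ratios))


def apply_factor(profile: Mapping[tuple[str, str], float],
                 factor: float) -> dict[tuple[str, str], float]:
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return {pair: v * factor for pair, v in profile.items()}


# ---------------------------------------------------------------------------
# I/O

def read_triplicates_tsv(path: str | Path) -> list[ThreeCMeasurement]:
    """TSV input: anchor, test, t1, t2, t3, c1, c2, c3."""
    df = pd.read_csv(path, sep="\t")
    required = ["anchor", "test", "t1", "t2", "t3", "c1", "c2", "c3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ThreeCMeasurement(
                    pair=(str(row["anchor"]), str(row["test"])),
                    template_values=(float(row.t1), float(row.t2), float(row.t3)),
                    control_values=(float(row.c1), float(row.c2), float(row.c3)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed triplicate row {i} in {path}: {exc}") from exc
    return out


def write_if_table(ifs: Mapping[tuple[str, str], tuple[float, float]],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor\ttest\tinteraction_frequency\tsem\n")
        for (anchor, test), (if_, sem) in sorted(ifs.items()):
            fh.write(f"{anchor}\t{test}\t{if_:.6g}\t{sem:.6g}\n")


def write_anchor_profile_bedgraph(
    ifs: Mapping[tuple[str, str], float],
    midpoints: Mapping[str, tuple[str, int]],
    path: str | Path,
) -> None:
    """Anchor profile as bedGraph keyed on test-fragment midpoints.

    ``midpoints`` maps test-fragment ids to (chrom, midpoint bp).
    """
    rows = []
    for (_, test), value in ifs.items():
        chrom, mid = midpoints[test]
        rows.append((chrom, mid, value))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, mid, value in rows:
            fh.write(f"{chrom}\t{mid}\t{mid + 1}\t{value:.6g}\n")
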