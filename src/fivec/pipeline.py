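"""Workflow orchestration: the 5C heatmap pipeline and the 3C anchor-profile pipeline.

``run_5c`` executes design -> read simulation -> mapping/filtering -> tally
-> raw matrix -> per-1000 normalization -> binning -> smoothing for two
tissues, then the limb-minus-head differential and the insulation-based
boundary calls.  ``run_3c`` simulates PCR triplicates with primer biases,
computes nine-ratio interaction frequencies, averages replicates, and
applies the cross-library compaction-profile factor.

Every artifact is written deterministically (fixed float formats, sorted
keys, no timestamps) and accompanied by a provenance JSON recording the
configuration and SHA-256 checksums of the numeric artifacts, so a rerun
with the same seed is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .matrix import (
    DEFAULT_BIN_SIZE,
    DEFAULT_SMOOTH_WINDOW,
    bin_matrix,
    build,
    differential,
    normalize,
    smooth,
    write_matrix_tsv,
)
from .reads import ReferenceIndex, filter_reads, map_reads, tally, write_ifl_tsv
from .regions import ECORI_SITE
from .segmentation import (
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_WINDOW_BINS,
    boundary_positions,
    call_boundaries,
    domains,
    insulation_profile,
    write_domains_bed,
    write_insulation_bedgraph,
)
from .simulate import (
    ContactModelParams,
    build_scenario,
    mini_hoxa_params,
    simulate_3c,
    simulate_reads,
    write_scenario,
)
from .threec import (
    apply_factor,
    average_replicates,
    compute_if,
    cross_library_factor,
    write_if_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters; defaults are the assay's published operating point.

    min_quality 30, max_offset 2 nt, EcoRI site, per-1000 scale, 20 kb
    bins, 8 kb smoothing, >20 kb / <100 bp fragment exclusions, 30 nt
    primers.
    """

    outdir: str = "fivec_run"
    seed: int = 0
    scheme: str = "alternating"
    min_quality: int = 30
    max_offset: int = 2
    site: str = ECORI_SITE
    bin_size: int = DEFAULT_BIN_SIZE
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    bin_before_smooth: bool = True
    window_bins: int = DEFAULT_WINDOW_BINS
    min_prominence: float = DEFAULT_MIN_PROMINENCE
    noise_cv: float = 0.1
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_quality < 0:
            raise ValueError(f"min_quality must be >= 0, got {self.min_quality}")
        if self.max_offset < 0:
            raise ValueError(f"max_offset must be >= 0, got {self.max_offset}")
        if self.bin_size <= 0 or self.smooth_window <= 0:
            raise ValueError("bin_size and smooth_window must be positive")
        if self.scheme not in ("anchored", "alternating"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(outdir: Path, config: RunConfig,
                      params: ContactModelParams | None,
                      artifacts: dict[str, str]) -> str:
    prov = {
        "tool": f"fivec {__version__}",
        "config": dataclasses.asdict(config),
        "params": repr(params) if params is not None else None,
        "artifacts": {name: _sha256(Path(p)) for name, p in sorted(artifacts.items())},
    }
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return str(path)


def run_5c(config: RunConfig, params: ContactModelParams | None = None) -> dict[str, str]:
    """Full 5C workflow on the demo scenario; returns artifact paths."""
    config.validate()
    params = params or mini_hoxa_params()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    ss = np.random.SeedSequence(config.seed)
    seed_region, seed_limb, seed_head = ss.spawn(3)
    scenario = build_scenario(params, seed=seed_region, scheme=config.scheme)
    artifacts.update(write_scenario(scenario, outdir / "scenario"))
    index = ReferenceIndex(scenario.references)

    normalized = {}
    filter_stats = {}
    binned = {}
    for tissue, seed in (("limb", seed_limb), ("head", seed_head)):
        reads, planted = simulate_reads(
            scenario.expected[tissue], scenario.design, scenario.references,
            params, seed,
        )
        map_reads(reads, index)
        kept, rejected = filter_reads(reads, min_quality=config.min_quality,
                                      max_offset=config.max_offset, site=config.site)
        records, total = tally(kept)
        filter_stats[tissue] = {
            "kept": len(kept),
            "rejected": dict(sorted(rejected.items())),
            "planted": dataclasses.asdict(planted),
        }
        ifl_path = outdir / f"{tissue}_ifl.tsv"
        write_ifl_tsv(records, ifl_path)
        artifacts[f"{tissue}_ifl"] = str(ifl_path)
        raw = build(records, scenario.design, scenario.region.fragments)
        norm = normalize(raw, total)
        normalized[tissue] = norm
        path = outdir / f"{tissue}_normalized.tsv"
        write_matrix_tsv(norm, path)
        artifacts[f"{tissue}_normalized"] = str(path)
        b = bin_matrix(norm, config.bin_size)
        binned[tissue] = b
        sm = smooth(b if config.bin_before_smooth else norm, config.smooth_window)
        for label, m in (("binned", b), ("smoothed", sm)):
            path = outdir / f"{tissue}_{label}.tsv"
            write_matrix_tsv(m, path)
            artifacts[f"{tissue}_{label}"] = str(path)

    diff = differential(normalized["limb"], normalized["head"])
    diff_path = outdir / "limb_minus_head.tsv"
    write_matrix_tsv(diff, diff_path)
    artifacts["differential"] = str(diff_path)

    if config.scheme == "alternating":
        profile = insulation_profile(binned["limb"], config.window_bins)
        calls = call_boundaries(profile, config.min_prominence)
        ins_path = outdir / "insulation.bedgraph"
        write_insulation_bedgraph(binned["limb"], profile, ins_path)
        artifacts["insulation"] = str(ins_path)
        dom_path = outdir / "domains.bed"
        write_domains_bed(domains(binned["limb"], calls), dom_path)
        artifacts["domains"] = str(dom_path)
        filter_stats["boundaries_bp"] = boundary_positions(binned["limb"], calls)

    stats_path = outdir / "filter_stats.json"
    with open(stats_path, "w") as fh:
        json.dump(filter_stats, fh, indent=2, sort_keys=True)
    artifacts["filter_stats"] = str(stats_path)
    artifacts["provenance"] = _write_provenance(outdir, config, params, artifacts)
    return artifacts


def run_3c(config: RunConfig, n_pairs: int = 15, n_control_pairs: int = 10,
           n_replicates: int = 3) -> dict[str, str]:
    """3C anchor-profile workflow on simulated triplicates.

    An anchor fragment is profiled against ``n_pairs`` test fragments with
    distance-decaying true contacts; a separate control-region profile of
    ``n_control_pairs`` pairs (shared with a reference library) provides the
    cross-library factor.  Replicate IFs are averaged after normalization.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    ss = np.random.SeedSequence(config.seed)
    truth = {("anchor", f"t{k:02d}"): float(5.0 / (1.0 + k)) for k in range(n_pairs)}
    control_truth = {("usp", f"u{k:02d}"): float(3.0 / (1.0 + 0.5 * k))
                     for k in range(n_control_pairs)}

    replicate_ifs = []
    for rep, seed in enumerate(ss.spawn(n_replicates)):
        sims, _ = simulate_3c({**truth, **control_truth}, noise_cv=config.noise_cv,
                              seed=seed)
        ifs = {pair: compute_if(v["template"], v["control"])[0]
               for pair, v in sims.items()}
        replicate_ifs.append(ifs)
    averaged = average_replicates(replicate_ifs)

    profile = {p: v for p, (v, _) in averaged.items() if p[0] == "usp"}
    factor = cross_library_factor(profile, control_truth)
    logger.info("cross-library factor %.4f", factor)
    anchor_profile = {p: v for p, (v, _) in averaged.items() if p[0] == "anchor"}
    scaled = apply_factor(anchor_profile, factor)

    if_path = outdir / "if_table.tsv"
    write_if_table(averaged, if_path)
    artifacts["if_table"] = str(if_path)
    profile_path = outdir / "anchor_profile.tsv"
    with open(profile_path, "w") as fh:
        fh.write("anchor\ttest\tscaled_if\n")
        for (anchor, test), v in sorted(scaled.items()):
            fh.write(f"{anchor}\t{test}\t{v:.6g}\n")
    artifacts["anchor_profile"] = str(profile_path)
    summary_path = outdir / "threec_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({"cross_library_factor": factor,
                   "n_pairs": n_pairs, "n_replicates": n_replicates},
                  fh, indent=2, sort_keys=True)
    artifacts["summary"] = str(summary_path)
    artifacts["provenance"] = _write_provenance(outdir, config, None, artifacts)
    return artifacts
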