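"""Synthetic-data generator with planted ground truth for every pipeline stage.

The generator emulates a ~1 Mb regulatory landscape assayed by 5C/3C:

* a random sequence whose restriction sites are placed by a seeded point
  process, so the in-silico digest reproduces a known fragment map;
* a contact model combining power-law distance decay, TAD and sub-TAD
  block structure (cross-boundary contact depletion), and tissue-specific
  enhancer-promoter enrichments;
* multinomially sampled junction reads with exactly-counted planted
  contaminant classes (low mapping quality, shifted alignment start,
  ablated restriction site) so filter tests are exact rather than
  statistical;
* ChIP peak tracks over planted enhancers and promoters with per-mark
  dropout and decoy peaks;
* 3C template/control triplicates with per-pair primer-efficiency bias and
  log-normal PCR noise (the control expectation carries the bias only, as
  an equimolar control library would).

All generators are pure functions of their parameters and a seed.
The default parameter set (:func:`mini_hoxa_params`) mirrors the
qualitative architecture of a limb regulatory landscape: a gene cluster
split by a TAD boundary, two upstream enhancer sub-TADs, and six
limb-specific enhancer-promoter contacts absent in head tissue.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .design import FivecDesign, JunctionReference, design_primers, junction_reference
from .enhancers import PeakSet
from .matrix import ContactMatrix, build
from .reads import InteractionRecord, JunctionRead
from .regions import (
    ECORI_SITE,
    GenomicInterval,
    RestrictionFragment,
    digest,
    eligible_fragments,
    filter_fragments,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpecificContact:
    """A planted tissue-specific contact between two loci."""

    a: GenomicInterval
    b: GenomicInterval
    enrichment: float
    tissue: str

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must be > 1")


@dataclass(frozen=True)
class ContaminationRates:
    low_quality: float = 0.012
    offset_shift: float = 0.008
    site_ablated: float = 0.005

    def __post_init__(self) -> None:
        rates = (self.low_quality, self.offset_shift, self.site_ablated)
        if any(r < 0 for r in rates):
            raise ValueError("contamination rates must be >= 0")
        if sum(rates) >= 1:
            raise ValueError("contamination rates must sum to < 1")


@dataclass(frozen=True)
class ContactModelParams:
    """Planted truth for the contact-map simulation.

    Distances decay as (d + decay_offset) ** -decay_exponent; every crossed
    TAD boundary multiplies the expected contact by cross_tad_multiplier
    and every crossed sub-TAD boundary by cross_subtad_multiplier; pairs
    hit by a specific contact whose tissue matches gain its enrichment.
    """

    region_length: int = 1_000_000
    site_density: float = 0.25  # expected recognition sites per kb
    decay_exponent: float = 1.0
    decay_offset: int = 10_000
    tad_boundaries: tuple[int, ...] = (880_000,)
    subtad_boundaries: tuple[int, ...] = (240_000, 500_000, 760_000)
    cross_tad_multiplier: float = 0.2
    cross_subtad_multiplier: float = 0.5
    specific_contacts: tuple[SpecificContact, ...] = ()
    contamination: ContaminationRates = field(default_factory=ContaminationRates)
    n_reads: int = 100_000
    seq_name: str = "chrS"
    gene_promoter_positions: tuple[int, ...] = tuple(range(800_000, 1_000_000, 20_000))
    enhancer_positions: tuple[int, ...] = (300_000, 340_000, 380_000,
                                           560_000, 600_000, 640_000)

    def __post_init__(self) -> None:
        if self.region_length < 50_000:
            raise ValueError("region_length must be >= 50 kb")
        if self.site_density < 0:
            raise ValueError("site_density must be >= 0")
        if self.decay_exponent <= 0 or self.decay_offset <= 0:
            raise ValueError("decay parameters must be positive")
        if not 0 < self.cross_tad_multiplier < 1:
            raise ValueError("cross_tad_multiplier must be in (0, 1)")
        if not self.cross_tad_multiplier < self.cross_subtad_multiplier <= 1:
            raise ValueError("cross_subtad_multiplier must be in (cross_tad_multiplier, 1]")
        for bounds in (self.tad_boundaries, self.subtad_boundaries):
            if list(bounds) != sorted(set(bounds)):
                raise ValueError("boundaries must be strictly increasing")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")


@dataclass
class SimulatedRegion:
    params: ContactModelParams
    sequence: str
    site_positions: list[int]
    fragments: list[RestrictionFragment]
    promoters: list[GenomicInterval]
    promoter_names: list[str]
    enhancers: list[GenomicInterval]
    enhancer_names: list[str]


@dataclass(frozen=True)
class PlantedContamination:
    low_quality: int
    offset_shift: int
    site_ablated: int


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Region and fragment map

def plant_site_positions(params: ContactModelParams, seed) -> list[int]:
    """Seeded point process for restriction-site starts.

    The number of sites is Poisson with mean site_density * length(kb);
    positions are uniform, kept clear of the region ends and of each other
    (>= 3x site length) so planted sites never merge.
    """
    rng = _rng(seed)
    site_len = len(ECORI_SITE)
    if params.site_density == 0:
        return []
    mean = params.site_density * params.region_length / 1000.0
    n = int(rng.poisson(mean))
    if n == 0:
        return []
    lo, hi = 20, params.region_length - 20 - site_len
    raw = np.sort(rng.integers(lo, hi, size=n))
    positions: list[int] = []
    for p in raw:
        if not positions or p - positions[-1] >= 3 * site_len:
            positions.append(int(p))
    return positions


def fragment_map(params: ContactModelParams, seed) -> list[RestrictionFragment]:
    """Fragment map implied by the planted sites, without materializing sequence."""
    sites = plant_site_positions(params, seed)
    edges = [0, *[s for s in sites if s > 0], params.region_length]
    fragments = [
        RestrictionFragment(GenomicInterval(params.seq_name, lo, hi), i)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    ]
    fragments = filter_fragments(fragments)
    if all(f.exclusion_reason == "too_small" for f in fragments):
        raise ValueError("site density so high that every fragment is below the size floor")
    return fragments


def _random_sequence_without_site(rng: np.random.Generator, length: int,
                                  site: str = ECORI_SITE) -> np.ndarray:
    seq = rng.choice(_BASES, size=length)
    while True:
        text = seq.tobytes().decode()
        hit = text.find(site)
        if hit == -1:
            return seq
        # mutate the middle base of the occurrence to a different base
        mid = hit + len(site) // 2
        choices = _BASES[_BASES != seq[mid]]
        seq[mid] = rng.choice(choices)


def simulate_region(params: ContactModelParams, seed) -> SimulatedRegion:
    """Materialize a region: sequence, fragment map, gene/enhancer annotations.

    The digest of the returned sequence reproduces the planted fragment map
    exactly (sites occur nowhere else).  Promoters and enhancers are placed
    on the eligible fragments nearest their nominal positions.
    """
    ss = _seedseq(seed)
    seed_sites, seed_seq = ss.spawn(2)
    sites = plant_site_positions(params, seed_sites)
    rng = _rng(seed_seq)
    seq = _random_sequence_without_site(rng, params.region_length)
    site_bytes = np.frombuffer(ECORI_SITE.encode(), dtype=np.uint8)
    for p in sites:
        seq[p: p + len(site_bytes)] = site_bytes
    # planting can create chance occurrences spanning a planted site's edges;
    # scrub them without touching planted spans
    planted_spans = [(p, p + len(ECORI_SITE)) for p in sites]
    text = seq.tobytes().decode()
    planted = set(sites)
    while True:
        # scan every occurrence (including overlapping ones, unlike the
        # greedy digest scan) so no chance site survives
        all_occ = []
        start = text.find(ECORI_SITE)
        while start != -1:
            all_occ.append(start)
            start = text.find(ECORI_SITE, start + 1)
        extras = [q for q in all_occ if q not in planted]
        if not extras:
            break
        q = extras[0]
        for off in range(len(ECORI_SITE)):
            pos = q + off
            if not any(lo <= pos < hi for lo, hi in planted_spans):
                choices = _BASES[_BASES != seq[pos]]
                seq[pos] = rng.choice(choices)
                break
        else:  # pragma: no cover - overlapping occurrences share all bases
            raise RuntimeError("cannot scrub chance site occurrence")
        text = seq.tobytes().decode()

    sequence = text
    fragments = filter_fragments(digest(sequence, seq_name=params.seq_name))
    if all(f.exclusion_reason == "too_small" for f in fragments):
        raise ValueError("site density so high that every fragment is below the size floor")
    # annotations prefer eligible fragments but fall back to any fragment
    # (e.g. a zero-density region is one large ineligible fragment)
    elig = eligible_fragments(fragments) or list(fragments)

    def host(position: int, taken: set[int]) -> RestrictionFragment:
        free = [f for f in elig if f.index not in taken] or elig
        return min(free, key=lambda f: abs(f.midpoint - position))

    taken: set[int] = set()
    promoters, promoter_names = [], []
    for k, pos in enumerate(params.gene_promoter_positions):
        frag = host(pos, taken)
        taken.add(frag.index)
        mid = int(frag.midpoint)
        half = min(100, frag.length // 2 - 1)
        promoters.append(GenomicInterval(params.seq_name, mid - half, mid + half))
        promoter_names.append(f"g{k + 1}")
    enhancers, enhancer_names = [], []
    for k, pos in enumerate(params.enhancer_positions):
        frag = host(pos, taken)
        taken.add(frag.index)
        mid = int(frag.midpoint)
        half = min(500, frag.length // 2 - 1)
        enhancers.append(GenomicInterval(params.seq_name, mid - half, mid + half))
        enhancer_names.append(f"e{k + 1}")

    return SimulatedRegion(
        params=params,
        sequence=sequence,
        site_positions=sites,
        fragments=fragments,
        promoters=promoters,
        promoter_names=promoter_names,
        enhancers=enhancers,
        enhancer_names=enhancer_names,
    )


def plant_limb_contacts(region: SimulatedRegion, enrichment: float = 8.0,
                        tissue: str = "limb") -> tuple[SpecificContact, ...]:
    """Pair every planted enhancer with a 5' gene promoter in the same TAD.

    Promoters on the enhancer side of the first TAD boundary are the
    eligible targets; enhancers cycle through them.
    """
    params = region.params
    boundary = params.tad_boundaries[0] if params.tad_boundaries else params.region_length
    targets = [p for p in region.promoters if p.midpoint < boundary] or region.promoters
    contacts = []
    for k, enh in enumerate(region.enhancers):
        contacts.append(
            SpecificContact(a=enh, b=targets[k % len(targets)],
                            enrichment=enrichment, tissue=tissue)
        )
    return tuple(contacts)


# ---------------------------------------------------------------------------
# Expected contact matrix

def expected_matrix(params: ContactModelParams,
                    fragments: Sequence[RestrictionFragment],
                    tissue: str) -> ContactMatrix:
    """Expected interaction probabilities over eligible fragment pairs.

    E[i, j] is proportional to (d_ij + d0)^-alpha, damped by the block
    multipliers for every TAD/sub-TAD boundary between the fragment
    midpoints, and boosted by the enrichment of any matching
    tissue-specific contact.  The matrix is symmetric with zero diagonal
    and normalized so the off-diagonal cells sum to 1.
    """
    elig = eligible_fragments(fragments)
    mids = np.array([f.midpoint for f in elig])
    n = len(mids)
    d = np.abs(mids[:, None] - mids[None, :])
    w = (d + params.decay_offset) ** (-params.decay_exponent)
    if params.decay_exponent == 0:
        w = np.ones_like(d)
    for t in params.tad_boundaries:
        crossed = (mids[:, None] < t) != (mids[None, :] < t)
        w = np.where(crossed, w * params.cross_tad_multiplier, w)
    for s in params.subtad_boundaries:
        crossed = (mids[:, None] < s) != (mids[None, :] < s)
        w = np.where(crossed, w * params.cross_subtad_multiplier, w)
    for contact in params.specific_contacts:
        if contact.tissue != tissue:
            continue
        in_a = np.array([f.interval.overlaps(contact.a) for f in elig])
        in_b = np.array([f.interval.overlaps(contact.b) for f in elig])
        hit = np.outer(in_a, in_b) | np.outer(in_b, in_a)
        w = np.where(hit, w * contact.enrichment, w)
    np.fill_diagonal(w, 0.0)
    w = w / w.sum()
    ids = [f"frag{f.index}" for f in elig]
    return ContactMatrix(
        row_intervals=[f.interval for f in elig],
        col_intervals=[f.interval for f in elig],
        row_ids=ids,
        col_ids=list(ids),
        values=w,
        state="expected",
    )


def _design_pair_probabilities(expected: ContactMatrix, design: FivecDesign
                               ) -> tuple[list[tuple[str, str]], np.ndarray]:
    pos = {rid: i for i, rid in enumerate(expected.row_ids)}
    pairs, probs = [], []
    for f in design.forward_primers:
        fi = pos[f"frag{f.fragment_index}"]
        for r in design.reverse_primers:
            ri = pos[f"frag{r.fragment_index}"]
            pairs.append((f.primer_id, r.primer_id))
            probs.append(expected.values[fi, ri])
    p = np.asarray(probs, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("expected matrix carries no mass on the design pairs")
    return pairs, p / total


def simulate_counts(expected: ContactMatrix, design: FivecDesign, n_reads: int,
                    seed) -> tuple[list[InteractionRecord], dict[tuple[str, str], int]]:
    """Multinomial pair counts over the design, without read objects.

    The fast path for matrix-level studies; read-level simulation
    (:func:`simulate_reads`) adds sequences and contaminants on top of the
    same distribution.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    pairs, probs = _design_pair_probabilities(expected, design)
    counts = _rng(seed).multinomial(n_reads, probs)
    mapping = {pair: int(c) for pair, c in zip(pairs, counts)}
    records = [InteractionRecord(f, r, c) for (f, r), c in sorted(mapping.items()) if c > 0]
    return records, mapping


def _ablate_site(sequence: str, rng: np.random.Generator) -> str:
    """Substitute one base of the (unique) restriction site; verify none remains."""
    pos = sequence.find(ECORI_SITE)
    if pos == -1:
        raise ValueError("sequence has no restriction site to ablate")
    for _ in range(20):
        off = int(rng.integers(0, len(ECORI_SITE)))
        old = sequence[pos + off]
        choices = [b for b in "ACGT" if b != old]
        new = choices[int(rng.integers(0, 3))]
        mutated = sequence[: pos + off] + new + sequence[pos + off + 1:]
        if ECORI_SITE not in mutated:
            return mutated
    raise RuntimeError("could not ablate site")  # pragma: no cover


def simulate_reads(expected: ContactMatrix, design: FivecDesign,
                   references: Sequence[JunctionReference],
                   params: ContactModelParams, seed,
                   n_reads: int | None = None
                   ) -> tuple[list[JunctionRead], PlantedContamination]:
    """Junction reads drawn multinomially from the expected matrix.

    Clean reads are exact junction reference sequences with quality >= 30
    and zero start offset.  Contaminant classes are planted with exact
    counts (round(rate * n_reads) each, drawn from the same pair
    distribution): quality below 30, start shifted by 3-5 nt, or the
    restriction site ablated by substitution.  Classes do not overlap, so a
    filter's rejection tally must reproduce the planted counts exactly.
    """
    n = int(n_reads if n_reads is not None else params.n_reads)
    if n <= 0:
        raise ValueError("n_reads must be > 0")
    rates = params.contamination
    n_lowq = round(rates.low_quality * n)
    n_shift = round(rates.offset_shift * n)
    n_ablate = round(rates.site_ablated * n)
    n_clean = n - n_lowq - n_shift - n_ablate
    if n_clean < 0:
        raise ValueError("contamination rates exceed read budget")

    ref_by_pair = {ref.pair: ref for ref in references}
    pairs, probs = _design_pair_probabilities(expected, design)
    rng = _rng(seed)

    def draw_pairs(count: int) -> list[tuple[str, str]]:
        if count == 0:
            return []
        counts = rng.multinomial(count, probs)
        out: list[tuple[str, str]] = []
        for pair, c in zip(pairs, counts):
            out.extend([pair] * int(c))
        return out

    reads: list[JunctionRead] = []
    for pair in draw_pairs(n_clean):
        reads.append(JunctionRead(ref_by_pair[pair].sequence,
                                  int(rng.integers(30, 43))))
    for pair in draw_pairs(n_lowq):
        reads.append(JunctionRead(ref_by_pair[pair].sequence,
                                  int(rng.integers(0, 30))))
    for pair in draw_pairs(n_shift):
        shift = int(rng.integers(3, 6))
        reads.append(JunctionRead(ref_by_pair[pair].sequence[shift:],
                                  int(rng.integers(30, 43))))
    for pair in draw_pairs(n_ablate):
        reads.append(JunctionRead(_ablate_site(ref_by_pair[pair].sequence, rng),
                                  int(rng.integers(30, 43))))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, PlantedContamination(n_lowq, n_shift, n_ablate)


def simulate_binned_matrix(params: ContactModelParams, seed,
                           n_reads: int | None = None,
                           bin_size: int = 20_000) -> tuple[ContactMatrix, ContactMatrix]:
    """Count-level sampling straight to a binned matrix (no sequences).

    Eligible fragments alternate forward/reverse roles; pair counts are
    multinomial from the expected model; the raw matrix is per-1000
    normalized and binned.  Returns (binned, normalized) matrices.  Used
    for matrix-level studies such as boundary-recovery benchmarks where
    read sequences are irrelevant.
    """
    from .matrix import bin_matrix, normalize

    n = int(n_reads if n_reads is not None else params.n_reads)
    ss = _seedseq(seed)
    seed_frag, seed_counts = ss.spawn(2)
    fragments = fragment_map(params, seed_frag)
    expected = expected_matrix(params, fragments, tissue="limb")
    elig = eligible_fragments(fragments)
    fwd = [f for k, f in enumerate(elig) if k % 2 == 0]
    rev = [f for k, f in enumerate(elig) if k % 2 == 1]
    pos = {rid: i for i, rid in enumerate(expected.row_ids)}
    probs = np.array([
        expected.values[pos[f"frag{f.index}"], pos[f"frag{r.index}"]]
        for f in fwd for r in rev
    ])
    probs = probs / probs.sum()
    counts = _rng(seed_counts).multinomial(n, probs).reshape(len(fwd), len(rev))
    raw = ContactMatrix(
        row_intervals=[f.interval for f in fwd],
        col_intervals=[r.interval for r in rev],
        row_ids=[f"F{f.index}" for f in fwd],
        col_ids=[f"R{r.index}" for r in rev],
        values=counts.astype(float),
        state="raw",
    )
    norm = normalize(raw, n)
    return bin_matrix(norm, bin_size), norm


# ---------------------------------------------------------------------------
# ChIP peaks

DEFAULT_MARKS = ("RNAP2", "Med12", "p300", "H3K27Ac")
DEFAULT_DROPOUT = {"RNAP2": 0.1, "Med12": 0.2, "p300": 0.2, "H3K27Ac": 0.1}


def simulate_chip(region: SimulatedRegion,
                  marks: Sequence[str] = DEFAULT_MARKS,
                  dropout: Mapping[str, float] | None = None,
                  decoys_per_mark: int = 5,
                  seed=0) -> tuple[dict[str, PeakSet], dict[str, set[str]]]:
    """ChIP peak tracks over planted enhancers and promoters.

    Every enhancer emits a peak for each mark independently with
    probability 1 - dropout[mark]; promoters emit RNAP2 peaks (transcribed
    genes); decoy single-mark peaks are added at random positions away from
    true features.  Returns the per-mark peak sets and the truth table
    (enhancer name -> marks actually emitted).
    """
    dropout = dict(DEFAULT_DROPOUT if dropout is None else dropout)
    rng = _rng(seed)
    seq_name = region.params.seq_name
    peaks: dict[str, list[GenomicInterval]] = {m: [] for m in marks}
    truth: dict[str, set[str]] = {}
    for name, enh in zip(region.enhancer_names, region.enhancers):
        emitted: set[str] = set()
        for mark in marks:
            if rng.random() >= dropout.get(mark, 0.0):
                jl = int(rng.integers(0, 200))
                jr = int(rng.integers(0, 200))
                peaks[mark].append(
                    GenomicInterval(seq_name, max(0, enh.start - jl), enh.end + jr)
                )
                emitted.add(mark)
        truth[name] = emitted
    if "RNAP2" in peaks:
        for prom in region.promoters:
            peaks["RNAP2"].append(
                GenomicInterval(seq_name, max(0, prom.start - 100), prom.end + 100)
            )
    avoid = [iv.padded(2_000) for iv in region.enhancers + region.promoters]
    for mark in marks:
        placed = 0
        attempts = 0
        while placed < decoys_per_mark and attempts < 200:
            attempts += 1
            start = int(rng.integers(0, region.params.region_length - 500))
            cand = GenomicInterval(seq_name, start, start + 400)
            if any(cand.overlaps(a) for a in avoid):
                continue
            peaks[mark].append(cand)
            avoid.append(cand.padded(500))
            placed += 1
    return {m: PeakSet(mark=m, peaks=p) for m, p in peaks.items()}, truth


# ---------------------------------------------------------------------------
# 3C PCR triplicates

def simulate_3c(true_contacts: Mapping[tuple[str, str], float],
                biases: Mapping[tuple[str, str], float] | None = None,
                noise_cv: float = 0.1,
                seed=0) -> tuple[dict[tuple[str, str], dict[str, tuple[float, float, float]]],
                                dict[tuple[str, str], float]]:
    """Gel-quantified PCR triplicates with primer-pair efficiency bias.

    The control (BAC library) expectation for a pair is its efficiency bias
    alone; the template expectation is bias x true contact.  Triplicates
    are log-normal around the expectation with coefficient of variation
    ``noise_cv`` (mean-preserving).  Returns the per-pair triplicates and
    the biases used (drawn log-normally when not supplied).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    pairs = sorted(true_contacts)
    if biases is None:
        biases = {p: float(np.exp(rng.normal(0.0, 0.5))) for p in pairs}
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))

    def noisy(expectation: float) -> tuple[float, float, float]:
        if expectation == 0:
            return (0.0, 0.0, 0.0)
        if sigma == 0:
            return (expectation,) * 3
        draws = expectation * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=3))
        return tuple(float(x) for x in draws)

    out = {}
    for pair in pairs:
        b = biases[pair]
        out[pair] = {
            "template": noisy(b * true_contacts[pair]),
            "control": noisy(b),
        }
    return out, dict(biases)


# ---------------------------------------------------------------------------
# Demo scenario

def mini_hoxa_params(**overrides) -> ContactModelParams:
    """Default demo scenario: the architecture described in the module docstring."""
    return replace(ContactModelParams(), **overrides) if overrides else ContactModelParams()


@dataclass
class Scenario:
    region: SimulatedRegion
    design: FivecDesign
    references: list[JunctionReference]
    expected: dict[str, ContactMatrix]  # tissue -> expected matrix


def build_scenario(params: ContactModelParams | None = None, seed=0,
                   scheme: str = "alternating",
                   anchor_region: GenomicInterval | None = None,
                   contact_enrichment: float = 8.0) -> Scenario:
    """Region + design + tissue-wise expected matrices, ready to sample from.

    With no explicit specific contacts in ``params``, six limb-specific
    enhancer-promoter contacts are planted via :func:`plant_limb_contacts`.
    """
    params = params or mini_hoxa_params()
    region = simulate_region(params, seed)
    if not params.specific_contacts:
        contacts = plant_limb_contacts(region, enrichment=contact_enrichment)
        params = replace(params, specific_contacts=contacts)
        region.params = params
    if scheme == "anchored" and anchor_region is None:
        boundary = params.tad_boundaries[0] if params.tad_boundaries else params.region_length
        gene_ivs = [p for p in region.promoters if p.midpoint < boundary] or region.promoters
        anchor_region = GenomicInterval(
            params.seq_name,
            min(p.start for p in gene_ivs) - 1_000,
            max(p.end for p in gene_ivs) + 1_000,
        )
    design = design_primers(region.fragments, region.sequence, scheme,
                            anchor_region=anchor_region)
    references = junction_reference(design)
    expected = {
        tissue: expected_matrix(params, region.fragments, tissue)
        for tissue in ("limb", "head")
    }
    return Scenario(region=region, design=design, references=references,
                    expected=expected)


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, str]:
    """Materialize a scenario directory (FASTA, BEDs, design table, truth JSON)."""
    from . import design as design_mod
    from .regions import write_bed_intervals, write_fragments_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = scenario.region
    paths = {}
    fasta = outdir / "region.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{region.params.seq_name}\n")
        seq = region.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i: i + 80] + "\n")
    paths["fasta"] = str(fasta)
    frag_bed = outdir / "fragments.bed"
    write_fragments_bed(region.fragments, frag_bed)
    paths["fragments"] = str(frag_bed)
    prom_bed = outdir / "promoters.bed"
    write_bed_intervals(region.promoters, prom_bed, names=region.promoter_names)
    paths["promoters"] = str(prom_bed)
    enh_bed = outdir / "enhancers.bed"
    write_bed_intervals(region.enhancers, enh_bed, names=region.enhancer_names)
    paths["enhancers"] = str(enh_bed)
    design_tsv = outdir / "design.tsv"
    design_mod.write_design_table(scenario.design, design_tsv)
    paths["design"] = str(design_tsv)
    truth = {
        "site_positions": region.site_positions,
        "specific_contacts": [
            {
                "a": [c.a.seq_name, c.a.start, c.a.end],
                "b": [c.b.seq_name, c.b.start, c.b.end],
                "enrichment": c.enrichment,
                "tissue": c.tissue,
            }
            for c in region.params.specific_contacts
        ],
        "tad_boundaries": list(region.params.tad_boundaries),
        "subtad_boundaries": list(region.params.subtad_boundaries),
        "contamination": asdict(region.params.contamination),
    }
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    paths["truth"] = str(truth_json)
    return paths
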