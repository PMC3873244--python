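# fivec

Chromosome-conformation analysis for 5C and 3C experiments: the
computational pipeline used to ask how remote enhancers and their target
genes are organised into topological domains — for example, how limb
enhancers upstream of a *Hox* cluster group into sub-TADs that contact the
5′ genes in limb but not head tissue.

The package is aimed at researchers analysing chromosome-conformation
capture data at a single locus (hundreds of kilobases to a few megabases):
it covers 5C experimental design, junction-read processing,
interaction-frequency matrices, tissue differentials, sub-TAD
segmentation, multi-mark enhancer-candidate calling, and BAC-normalized 3C
quantification — plus a synthetic-data generator that plants known
structure so every stage is testable without any external download.

## The model and statistics at its core

**Interaction frequency (IF).** A 5C sequencing run yields junction reads,
each identifying one (forward, reverse) primer pair, i.e. one fragment
pair. After filtering (mapping quality ≥ 30, alignment offset ≤ 2 nt,
restriction site present in the read), the IF of a contact is

```
IF(f, r) = 10^3 · N(f, r) / N_total
```

reads per thousand run reads. Heatmaps are built from these values, binned
as per-20 kb-bin-pair means and smoothed with an 8 kb boxcar; the
limb-enriched map is the element-wise difference of two tissues'
normalized matrices.

**Sub-TAD segmentation.** Domain boundaries are local minima of the
insulation score

```
I(b) = mean of the w×w off-diagonal square spanning rows (b−w, b], cols (b, b+w]
```

with w = 3 bins (≈60 kb at 20 kb bins), called when their prominence
exceeds 2.5 standard deviations of the profile — a reproducible,
scale-invariant replacement for delineating domains by eye.

**Candidate enhancers.** A locus distinct from proximal promoters
(±1 kb) is nominated when bound by RNA polymerase II plus at least one
other assayed mark (e.g. Med12, p300, H3K27Ac), or by both p300 and
H3K27Ac.

**3C quantification.** Each contact is PCR-quantified in triplicate from
the tissue library (template t₁..t₃) and from an equimolar BAC control
library (c₁..c₃); the IF is the mean of the nine ratios tᵢ/cⱼ, which
cancels primer-pair efficiency. Replicates are averaged after
normalization, and libraries are put on a common scale via a
compaction-profile factor over a control region.

**The generator.** Expected contacts follow
`E[i,j] ∝ (d_ij + d0)^−α · β_T^(#TAD crossings) · β_S^(#sub-TAD crossings) · γ`
for planted tissue-specific contacts; junction reads are multinomial draws
with exactly-counted planted contaminant classes.

## Worked example

`examples/03_matrices_and_subtads.py` builds the demo scenario (1 Mb, one
TAD boundary splitting a 10-gene cluster, two enhancer sub-TADs, six
limb-specific enhancer–promoter contacts), samples 500,000 reads per
tissue, and segments the limb map:

```
limb: 126 x 125 fragment matrix, 500,000 reads
head: 126 x 125 fragment matrix, 500,000 reads
differential: strongest limb-enriched cell 0.21 per 1000 reads (positive = limb-enriched, negative = head-enriched)
binned to 50 x 20 kb bins; 4 domain boundaries called at [240000, 500000, 760000, 880000] bp
planted boundaries: [240000, 500000, 760000, 880000]
```

All four planted TAD/sub-TAD boundaries are recovered at exact bin edges,
and the strongest positive differential cells are the planted
limb-specific contacts. The other examples cover digestion/primer design,
read filtering (exact recovery of planted contaminant counts), enhancer
calling, and 3C quantification.

A thin CLI wraps the workflows:

```
fivec simulate --outdir demo --seed 1
fivec run-5c --outdir run --seed 1
fivec run-3c --outdir run3c --seed 1
```

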