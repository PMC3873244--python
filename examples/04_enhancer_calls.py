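"""Candidate-enhancer calling from simulated multi-mark ChIP tracks.

A locus qualifies when bound by RNAP2 plus at least one other mark, or by
both p300 and H3K27Ac, and it is not promoter-proximal.
"""
from fivec.enhancers import call_candidates
from fivec.simulate import build_scenario, mini_hoxa_params, simulate_chip

scenario = build_scenario(mini_hoxa_params(), seed=3)
region = scenario.region

peaksets, truth = simulate_chip(region, seed=4)  # default per-mark dropout
for mark, ps in sorted(peaksets.items()):
    print(f"{mark}: {len(ps.peaks)} peaks")

candidates = call_candidates(peaksets, promoters=region.promoters)
print(f"\n{len(candidates)} candidate enhancers:")
for c in candidates:
    print(f"  {c.interval}  branch={c.rule_branch}  "
          f"marks={'+'.join(sorted(c.supporting_marks))}")

recovered = sum(any(c.interval.overlaps(e) for c in candidates)
                for e in region.enhancers)
print(f"\nrecovered {recovered}/{len(region.enhancers)} planted enhancers "
      f"(missed ones lost too many marks to dropout)")
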