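"""Junction-read mapping and the three filters, on reads with planted artefacts.

Simulates a 10,000-read 5C sequencing run in which exactly 120 reads carry
low mapping quality, 80 align 3-5 nt away from the reference start, and 50
lost their restriction site; the filters must reject exactly those reads,
by those reasons.
"""
from fivec.reads import ReferenceIndex, filter_reads, map_reads, tally
from fivec.simulate import build_scenario, mini_hoxa_params, simulate_reads

scenario = build_scenario(mini_hoxa_params(), seed=1, scheme="anchored")
reads, planted = simulate_reads(scenario.expected["limb"], scenario.design,
                                scenario.references, scenario.region.params,
                                seed=2, n_reads=10_000)
print(f"simulated {len(reads):,} junction reads; planted contaminants: "
      f"{planted.low_quality} low-quality, {planted.offset_shift} shifted, "
      f"{planted.site_ablated} site-ablated")

map_reads(reads, ReferenceIndex(scenario.references))
kept, rejected = filter_reads(reads, min_quality=30, max_offset=2)
print(f"kept {len(kept):,}; rejected: {dict(rejected)}")

records, total = tally(kept)
print(f"interaction frequency list: {len(records)} primer pairs, {total:,} used reads")
# The rejection tally reproduces the planted counts exactly because the
# contaminant classes are planted with exact counts and do not overlap.
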