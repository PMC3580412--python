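"""Two-step somatic indel calling with the germline-window test.

Plants three somatic and one germline indel, filters the tumor library to
inserts strictly inside (500, 5000) bp, groups identical CIGAR events into
candidates, and flags a candidate somatic only when the germline sample
shows no indel within 5 bp of its span.
"""

import matewalker as mw

cfg = mw.SimulationConfig(
    genome=[("chr1", 150_000)],
    germline_snp_rate=5e-4,
    somatic_indels=[
        mw.IndelSpec("chr1", 30_000, 4, "del"),
        mw.IndelSpec("chr1", 70_000, 2, "ins"),
        mw.IndelSpec("chr1", 110_000, 8, "del"),
    ],
    germline_indels=[mw.IndelSpec("chr1", 50_000, 3, "del")],
    seed=13,
)
ref = mw.generate_reference(cfg)
sim = mw.plant_variants(ref, cfg)
tumor = mw.simulate_mate_pairs(sim, "tumor")
germline = mw.simulate_mate_pairs(sim, "germline")

candidates = mw.call_somatic_indels(tumor, germline)
print(f"{len(candidates)} candidates from the tumor library:")
for c in candidates:
    span = f"{c.contig}:{c.start}-{c.end}" if c.kind == "del" else f"{c.contig}:{c.start}"
    print(f"  {c.kind} {span} support={c.support}/{c.covering} -> {c.status}")
# The germline 3 bp deletion at 50,000 appears as a candidate (it is present
# in the tumor too) but carries germline-window evidence, so only the three
# tumor-only events are flagged somatic.
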