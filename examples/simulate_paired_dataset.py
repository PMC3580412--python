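"""Simulate a matched tumor/germline mate-pair dataset with known truth.

Builds a 200 kb genome, plants germline SNPs, somatic SNVs and a somatic
deletion, then draws 1.5 kb-insert 50+50 bp mate pairs at 37x/40x with the
tumor library diluted to 60% tumor-cell content.  Writes FASTA/SAM/TSV and
prints what was planted versus what was sequenced.
"""

import pathlib

import matewalker as mw
from matewalker.simulate import write_fasta

out = pathlib.Path("scratch/example_sim")
out.mkdir(parents=True, exist_ok=True)

cfg = mw.SimulationConfig(
    genome=[("chr1", 200_000)],
    germline_snp_rate=1e-3,
    somatic_snv_count=20,
    somatic_indels=[mw.IndelSpec("chr1", 120_000, 5, "del")],
    seed=42,
)
ref = mw.generate_reference(cfg)
sim = mw.plant_variants(ref, cfg)
tumor = mw.simulate_mate_pairs(sim, "tumor")
germline = mw.simulate_mate_pairs(sim, "germline")

write_fasta(ref, out / "reference.fasta")
lens = {c.name: c.length for c in cfg.genome}
mw.write_sam(tumor, out / "tumor.sam", lens)
mw.write_sam(germline, out / "germline.sam", lens)
sim.truth.to_tsv(out / "truth.tsv")

print(f"planted: {len(sim.truth.germline_snps)} germline SNPs, "
      f"{len(sim.truth.somatic_snvs)} somatic SNVs, "
      f"{len(sim.truth.somatic_indels)} somatic indels")
print(f"sequenced: {len(tumor)} tumor reads ({len(tumor) * 50 / 200_000:.1f}x), "
      f"{len(germline)} germline reads ({len(germline) * 50 / 200_000:.1f}x)")
print(f"outputs in {out}/ (reference.fasta, tumor.sam, germline.sam, truth.tsv)")
# The truth TSV records every planted event; a clonal het somatic SNV in a
# copy-neutral region carries expected tumor allele fraction purity/2 = 0.30.
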