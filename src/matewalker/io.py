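"""Flat-file writers and readers for caller outputs (VCF, BED, bedGraph)."""

from __future__ import annotations

import pandas as pd

VCF_HEADER = "##fileformat=VCFv4.2\n"


def _vcf_lines(fh, source: str, extra_meta: list[str]):
    fh.write(VCF_HEADER)
    fh.write(f"##source={source}\n")
    for line in extra_meta:
        fh.write(line + "\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def write_genotype_vcf(calls, path) -> None:
    """Germline genotype calls with per-strand KS distances in INFO."""
    meta = [
        '##INFO=<ID=GT,Number=1,Type=String,Description="Consensus genotype">',
        '##INFO=<ID=FWD,Number=3,Type=Float,Description="Forward-strand distances to hom_ref,het,hom_alt">',
        '##INFO=<ID=REV,Number=3,Type=Float,Description="Reverse-strand distances to hom_ref,het,hom_alt">',
    ]
    with open(path, "w") as fh:
        _vcf_lines(fh, "matewalker-genotype", meta)
        for c in calls:
            if c.alt is None and not c.is_variant:
                continue

            def triple(d):
                return ",".join(f"{d.get(g, float('nan')):.4f}" for g in ("hom_ref", "het", "hom_alt"))

            filt = "PASS" if c.consensus is not None else "no_call"
            info = f"GT={c.consensus or '.'};FWD={triple(c.forward_distances)};REV={triple(c.reverse_distances)}"
            fh.write(
                f"{c.contig}\t{c.site + 1}\t.\t{c.ref}\t{c.alt or '.'}\t.\t{filt}\t{info}\n"
            )


def write_somatic_vcf(calls, path) -> None:
    """Somatic SNV consensus calls; FILTER carries the caller's status ledger."""
    meta = [
        '##INFO=<ID=STAT,Number=1,Type=Float,Description="Min over strands of the two-proportion z">',
        '##INFO=<ID=PROV,Number=.,Type=String,Description="Consensus provenance">',
    ]
    with open(path, "w") as fh:
        _vcf_lines(fh, "matewalker-somatic-snv", meta)
        for c in calls:
            filt = "PASS" if c.status == "pass" else c.status
            prov = ",".join(c.provenance) if c.provenance else "."
            fh.write(
                f"{c.contig}\t{c.site + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t"
                f"STAT={c.stat:.3f};PROV={prov}\n"
            )


def write_indel_vcf(candidates, reference: dict[str, str], path) -> None:
    """Indel candidates in anchor-base VCF convention (1-based)."""
    with open(path, "w") as fh:
        _vcf_lines(fh, "matewalker-somatic-indel", [
            '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting tumor reads">',
            '##INFO=<ID=STATUS,Number=1,Type=String,Description="somatic|germline|undetermined">',
        ])
        for c in candidates:
            anchor_pos = c.start - 1 if c.start > 0 else c.start
            anchor = reference[c.contig][anchor_pos]
            if c.kind == "del":
                ref = anchor + reference[c.contig][c.start : c.end]
                alt = anchor
            else:
                ref = anchor
                alt = anchor + c.sequence
            filt = "PASS" if c.somatic else c.status
            fh.write(
                f"{c.contig}\t{anchor_pos + 1}\t.\t{ref}\t{alt}\t.\t{filt}\t"
                f"SUPPORT={c.support};STATUS={c.status}\n"
            )


def write_segments_bed(segments, path) -> None:
    """CNV segments as BED with state and mean log2 difference columns."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.state}\t{s.mean_diff:.4f}\n")


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: contig, start, end (+ optional name) as a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "contig", 1: "start", 2: "end", 3: "name"})
    return df
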