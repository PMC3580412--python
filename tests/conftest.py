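import pytest
from hypothesis import settings

import matewalker as mw

# deterministic, CI-friendly hypothesis profile
settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_read(
    contig="c1",
    start=0,
    strand="+",
    cigar="50M",
    seq=None,
    qual=30,
    name=None,
    mate_contig=None,
    mate_start=None,
    insert=1500,
    mate_strand=None,
    is_read1=True,
):
    """Terse AlignedRead factory for hand-built fixtures."""
    n = sum(int(x) for x, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar) if op in "MIS=X")
    seq = seq if seq is not None else "A" * n
    return mw.AlignedRead(
        name=name or f"r{contig}:{start}:{strand}",
        contig=contig,
        start=start,
        strand=strand,
        cigar=cigar,
        seq=seq,
        quals=bytes([qual] * len(seq)),
        mate_contig=mate_contig if mate_contig is not None else contig,
        mate_start=mate_start if mate_start is not None else start + insert - 50,
        insert=insert,
        mate_strand=mate_strand or strand,
        is_read1=is_read1,
    )


@pytest.fixture(scope="session")
def snv_sim():
    """Shared read-level simulation: germline SNPs, somatic SNVs and indels.

    One 300 kb contig at the default design point (purity 0.6, 37x/40x,
    1.5 kb inserts, Q30).  Used by the genotyper, SNV and indel suites.
    """
    cfg = mw.SimulationConfig(
        genome=[("chr1", 300_000)],
        germline_snp_rate=1e-3,
        somatic_snv_count=60,
        somatic_indels=[
            mw.IndelSpec("chr1", 40_000, 4, "del"),
            mw.IndelSpec("chr1", 90_000, 1, "del"),
            mw.IndelSpec("chr1", 140_000, 10, "del"),
            mw.IndelSpec("chr1", 190_000, 3, "ins"),
            mw.IndelSpec("chr1", 240_000, 8, "ins"),
            mw.IndelSpec("chr1", 280_000, 1, "ins"),
        ],
        germline_indels=[
            mw.IndelSpec("chr1", 65_000, 5, "del"),
            mw.IndelSpec("chr1", 215_000, 4, "ins"),
        ],
        seed=5,
    )
    ref = mw.generate_reference(cfg)
    sim = mw.plant_variants(ref, cfg)
    tumor = mw.simulate_mate_pairs(sim, "tumor")
    germline = mw.simulate_mate_pairs(sim, "germline")
    return {"cfg": cfg, "ref": ref, "sim": sim, "tumor": tumor, "germline": germline}


@pytest.fixture(scope="session")
def fusion_sim():
    """Shared multi-contig simulation with two somatic and one shared fusion."""
    contigs = [("chrA", 200_000), ("chrB", 200_000), ("chrC", 200_000), ("chrD", 200_000)]
    cfg = mw.SimulationConfig(
        genome=contigs,
        germline_snp_rate=0.0,
        fusions=[
            mw.FusionSpec("chrA", 60_000, "chrB", 150_000, somatic=True),
            mw.FusionSpec("chrC", 120_000, "chrD", 40_000, somatic=True),
            mw.FusionSpec("chrB", 30_000, "chrC", 170_000, somatic=False),
        ],
        chimera_rate=2e-4,
        seed=9,
    )
    ref = mw.generate_reference(cfg)
    sim = mw.plant_variants(ref, cfg)
    tumor = mw.simulate_mate_pairs(sim, "tumor")
    germline = mw.simulate_mate_pairs(sim, "germline")
    lens = {name: L for name, L in contigs}
    return {"cfg": cfg, "ref": ref, "sim": sim, "tumor": tumor, "germline": germline, "lens": lens}
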