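"""Simulator contracts: determinism, mixture arithmetic, truth bookkeeping."""

import math

import numpy as np
import pytest

import matewalker as mw
from matewalker.simulate import write_fasta


def small_cfg(**kw):
    base = dict(genome=[("c1", 20_000)], germline_snp_rate=1e-3, seed=7)
    base.update(kw)
    return mw.SimulationConfig(**base)


class TestReference:
    def test_deterministic_and_sized(self):
        cfg = small_cfg(genome=[("c1", 10_000), ("c2", 12_000)])
        r1 = mw.generate_reference(cfg)
        r2 = mw.generate_reference(cfg)
        assert r1 == r2
        assert len(r1["c1"]) == 10_000 and len(r1["c2"]) == 12_000
        assert set(r1["c1"]) <= set("ACGT")

    def test_roughly_uniform_composition(self):
        ref = mw.generate_reference(small_cfg(genome=[("c1", 100_000)]))
        counts = {b: ref["c1"].count(b) for b in "ACGT"}
        for c in counts.values():
            assert abs(c / 100_000 - 0.25) < 0.02

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            mw.generate_reference(small_cfg(genome=[("c1", 0)]))

    def test_fasta_round_trip(self, tmp_path):
        ref = mw.generate_reference(small_cfg())
        path = tmp_path / "ref.fasta"
        write_fasta(ref, path)
        from Bio import SeqIO

        back = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert back == ref


class TestConfigValidation:
    def test_purity_bounds(self):
        with pytest.raises(ValueError):
            small_cfg(purity=0.0).validate()
        with pytest.raises(ValueError):
            small_cfg(purity=1.2).validate()

    def test_insert_must_exceed_reads(self):
        with pytest.raises(ValueError):
            small_cfg(insert_mean=90).validate()

    def test_partially_overlapping_cnvs_rejected(self):
        cfg = small_cfg(cnvs=[mw.CnvSpec("c1", 0, 10_000, 1), mw.CnvSpec("c1", 5_000, 15_000, 0)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_nested_cnvs_accepted_and_partitioned(self):
        cfg = small_cfg(cnvs=[mw.CnvSpec("c1", 2_000, 18_000, 1), mw.CnvSpec("c1", 8_000, 12_000, 0)])
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        assert sim.copy_number_at("c1", 1_000) == 2
        assert sim.copy_number_at("c1", 5_000) == 1
        assert sim.copy_number_at("c1", 10_000) == 0

    def test_out_of_bounds_events_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(somatic_indels=[mw.IndelSpec("c1", 25_000, 3, "del")]).validate()
        with pytest.raises(ValueError):
            small_cfg(fusions=[mw.FusionSpec("c1", 30_000, "c1", 10)]).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cfg(cnvs=[mw.CnvSpec("c1", 2_000, 4_000, 1)], somatic_snv_count=5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = mw.SimulationConfig.from_yaml(path)
        assert back == cfg


class TestPlantVariants:
    def test_transition_only_boundary(self):
        cfg = small_cfg(genome=[("c1", 100_000)], titv_ratio=math.inf, germline_snp_rate=5e-3)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        from matewalker.report import TRANSITIONS

        assert sim.truth.germline_snps
        assert all((s.ref, s.alt) in TRANSITIONS for s in sim.truth.germline_snps)

    def test_titv_near_target(self):
        # moderate-n check; the full 200k-site calibration runs in the acceptance suite
        cfg = small_cfg(genome=[("c1", 1_000_000)], germline_snp_count=20_000)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        ratio = mw.titv([(s.ref, s.alt) for s in sim.truth.germline_snps])
        assert abs(ratio - 2.12) < 0.12

    def test_exact_count_and_no_collisions(self):
        cfg = small_cfg(genome=[("c1", 50_000)], germline_snp_count=300, somatic_snv_count=40)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        assert len(sim.truth.germline_snps) == 300
        assert len(sim.truth.somatic_snvs) == 40
        germ = {(s.contig, s.pos) for s in sim.truth.germline_snps}
        som = {(s.contig, s.pos) for s in sim.truth.somatic_snvs}
        assert not germ & som

    def test_clonal_het_expected_af_is_purity_over_two(self):
        cfg = small_cfg(somatic_snv_count=10, purity=0.6)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        for s in sim.truth.somatic_snvs:
            assert s.expected_af == pytest.approx(0.3)

    def test_haplotypes_carry_planted_alleles(self):
        cfg = small_cfg(somatic_snv_count=5)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        for s in sim.truth.somatic_snvs:
            germ = {h.seq[h.hap_of_ref[s.pos]] for h in sim.germline[s.contig]}
            tum = {h.seq[h.hap_of_ref[s.pos]] for h in sim.tumor[s.contig]}
            assert s.alt not in germ
            assert s.alt in tum

    def test_indel_collision_rejected(self):
        cfg = small_cfg(
            somatic_indels=[mw.IndelSpec("c1", 5_000, 4, "del"), mw.IndelSpec("c1", 5_002, 2, "del")]
        )
        ref = mw.generate_reference(cfg)
        with pytest.raises(ValueError):
            mw.plant_variants(ref, cfg)

    def test_truth_tsv_written(self, tmp_path):
        cfg = small_cfg(somatic_snv_count=3, cnvs=[mw.CnvSpec("c1", 2_000, 4_000, 1)])
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        path = tmp_path / "truth.tsv"
        sim.truth.to_tsv(path)
        lines = path.read_text().splitlines()
        n_events = (
            len(sim.truth.germline_snps) + len(sim.truth.somatic_snvs) + len(sim.truth.cnv_segments)
        )
        assert len(lines) == 1 + n_events


class TestMatePairs:
    def test_deterministic(self):
        cfg = small_cfg(mean_coverage_tumor=10, mean_coverage_germline=10)
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        a = mw.simulate_mate_pairs(sim, "tumor")
        b = mw.simulate_mate_pairs(sim, "tumor")
        assert [(r.name, r.start, r.seq) for r in a] == [(r.name, r.start, r.seq) for r in b]

    def test_read_count_matches_coverage(self, snv_sim):
        cfg = snv_sim["cfg"]
        L = cfg.genome[0].length
        n_expected = cfg.mean_coverage_germline * L / cfg.read_len
        assert len(snv_sim["germline"]) == pytest.approx(n_expected, rel=0.02)
        n_expected_t = cfg.mean_coverage_tumor * L / cfg.read_len
        assert len(snv_sim["tumor"]) == pytest.approx(n_expected_t, rel=0.02)

    def test_somatic_af_near_diluted_expectation(self, snv_sim):
        from matewalker.reads import build_pileups

        truth = snv_sim["sim"].truth.somatic_snvs
        sites = [(s.contig, s.pos) for s in truth]
        pil = build_pileups(snv_sim["tumor"], sites)
        devs = 0
        for s in truth:
            p = pil[(s.contig, s.pos)]
            n = p.depth
            k = p.alt_count(s.alt)
            sd = math.sqrt(n * s.expected_af * (1 - s.expected_af))
            if abs(k - n * s.expected_af) > 3 * sd + 1:
                devs += 1
        assert devs <= max(1, int(0.01 * len(truth)) + 2)

    def test_homozygous_deletion_yields_no_tumor_fragments(self):
        cfg = mw.SimulationConfig(
            genome=[("c1", 100_000)],
            purity=1.0,
            germline_snp_rate=0,
            cnvs=[mw.CnvSpec("c1", 40_000, 60_000, 0)],
            mean_coverage_tumor=20,
            mean_coverage_germline=20,
            seed=3,
        )
        ref = mw.generate_reference(cfg)
        sim = mw.plant_variants(ref, cfg)
        tumor = mw.simulate_mate_pairs(sim, "tumor")
        inside = [r for r in tumor if r.start >= 45_000 and r.end <= 55_000]
        assert inside == []
        germ = mw.simulate_mate_pairs(sim, "germline")
        assert any(r.start >= 45_000 and r.end <= 55_000 for r in germ)

    def test_fusion_mates_map_to_partner_contigs(self, fusion_sim):
        cross = [r for r in fusion_sim["tumor"] if "x" in r.name]
        assert len(cross) > 50
        assert all(r.mate_contig != r.contig for r in cross)

    def test_indel_reads_carry_gapped_cigars(self, snv_sim):
        gapped = [r for r in snv_sim["tumor"] if "D" in r.cigar or "I" in r.cigar]
        assert gapped
        # each planted somatic deletion is seen by multiple reads
        dels = [i for i in snv_sim["sim"].truth.somatic_indels if i.kind == "del"]
        for d in dels:
            support = [
                r for r in gapped if r.contig == d.contig and r.start < d.start < r.end
            ]
            assert len(support) >= 3

    def test_desk_scale_guard(self):
        from matewalker.simulate import SimulatedGenomes, TruthSet

        cfg = small_cfg(
            genome=[("c1", 50_000_000)], mean_coverage_tumor=200, mean_coverage_germline=200
        )
        stub = SimulatedGenomes(cfg, {}, {}, {}, TruthSet())
        with pytest.raises(ValueError, match="desk-scale"):
            mw.simulate_mate_pairs(stub, "tumor")


class TestBinDepths:
    def test_neutral_ratio(self):
        cfg = mw.SimulationConfig(
            genome=[("c1", 2_000_000)], mean_coverage_tumor=37, mean_coverage_germline=40, seed=1
        )
        g, t = mw.simulate_bin_depths(cfg)
        assert np.mean(t.depths["c1"]) / np.mean(g.depths["c1"]) == pytest.approx(37 / 40, rel=0.01)

    def test_copy_number_mixture_scaling(self):
        cfg = mw.SimulationConfig(
            genome=[("c1", 3_000_000)],
            purity=0.6,
            mean_coverage_tumor=40,
            mean_coverage_germline=40,
            cnvs=[mw.CnvSpec("c1", 1_000_000, 2_000_000, 0)],
            seed=2,
        )
        g, t = mw.simulate_bin_depths(cfg)
        region = t.depths["c1"][10_000:20_000]
        assert np.mean(region) == pytest.approx(40 * 0.4, rel=0.02)
        outside = t.depths["c1"][:10_000]
        assert np.mean(outside) == pytest.approx(40, rel=0.02)

    def test_single_copy_loss_log2(self):
        # CN=1 at purity 0.6: expected normalized log2 ratio = log2(0.7)
        cfg = mw.SimulationConfig(
            genome=[("c1", 4_000_000)],
            purity=0.6,
            mean_coverage_tumor=40,
            mean_coverage_germline=40,
            cnvs=[mw.CnvSpec("c1", 0, 4_000_000, 1)],
            seed=4,
        )
        g, t = mw.simulate_bin_depths(cfg)
        ratio = np.mean(t.depths["c1"]) / np.mean(g.depths["c1"])
        assert np.log2(ratio) == pytest.approx(np.log2(0.7), abs=0.01)

    def test_determinism_and_positive_rate_guard(self):
        cfg = mw.SimulationConfig(genome=[("c1", 100_000)], seed=8)
        g1, t1 = mw.simulate_bin_depths(cfg)
        g2, t2 = mw.simulate_bin_depths(cfg)
        assert np.array_equal(g1.depths["c1"], g2.depths["c1"])
        assert np.array_equal(t1.depths["c1"], t2.depths["c1"])
        bad = mw.SimulationConfig(genome=[("c1", 100_000)], mean_coverage_tumor=0)
        with pytest.raises(ValueError):
            mw.simulate_bin_depths(bad)
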