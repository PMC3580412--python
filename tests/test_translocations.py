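"""Discordant-pair walker: window stats, outlier rule, calls, GFF round trip."""

import numpy as np
import pytest

from matewalker.translocations import (
    DiscordantWindow,
    TranslocationCall,
    call_regions,
    call_translocations,
    candidate_windows,
    outlier_cutoff,
    read_paired_gff,
    scan_windows,
    somatic_subtract,
    write_paired_gff,
)

from conftest import make_read


def window(contig="c1", start=0, total=100, hit=0, partner=None, hit_reads=()):
    return DiscordantWindow(contig, start, 1500, total, hit, partner, hit,
                            hit_reads=list(hit_reads))


class TestScanWindows:
    def test_concordant_reads_not_discordant(self):
        reads = [make_read(start=i * 100, name=f"r{i}") for i in range(20)]
        wins = scan_windows(reads, {"c1": 3000}, step=1500)
        assert all(w.discordant == 0 and w.proportion == 0 for w in wins["c1"])
        assert sum(w.total for w in wins["c1"]) == 20

    def test_highest_hit_voting(self):
        reads = [make_read(start=i, name=f"n{i}") for i in range(92)]
        reads += [make_read(start=100 + i, mate_contig="c2", mate_start=500, name=f"a{i}") for i in range(6)]
        reads += [make_read(start=200 + i, mate_contig="c3", mate_start=500, name=f"b{i}") for i in range(2)]
        reads.sort(key=lambda r: r.start)
        w = scan_windows(reads, {"c1": 1500}, step=1500)["c1"][0]
        assert w.total == 100 and w.discordant == 8
        assert w.highest_hit == "c2" and w.hit_count == 6
        assert w.proportion == pytest.approx(0.06)

    def test_tie_breaks_by_contig_name(self):
        reads = [make_read(start=i, mate_contig=c, mate_start=0, name=f"{c}{i}")
                 for i, c in enumerate(["c3", "c2", "c2", "c3"])]
        w = scan_windows(reads, {"c1": 1500}, step=1500)["c1"][0]
        assert w.highest_hit == "c2"

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            scan_windows([], {"c1": 1000}, step=0)

    def test_intrachromosomal_anomaly_classes(self):
        ok = make_read(start=0, name="ok", insert=1500)
        orient = make_read(start=100, name="or", mate_strand="-", strand="+", insert=1500)
        far = make_read(start=200, name="far", insert=9000)
        wins = scan_windows([ok, orient, far], {"c1": 1500}, step=1500,
                            anomaly="intrachromosomal", insert_mean=1500)
        assert wins["c1"][0].discordant == 2


class TestOutlierCutoff:
    def test_formula(self):
        props = [0.01, 0.02, 0.005, 0.03, 0.0, 0.015] * 6
        wins = [window(start=i * 1500, total=1000, hit=int(p * 1000)) for i, p in enumerate(props)]
        got = outlier_cutoff(wins)
        arr = np.array([w.proportion for w in wins])
        assert got == pytest.approx(arr.mean() + 3 * arr.std())

    def test_flat_background_no_candidates(self):
        wins = [window(start=i * 1500, total=100, hit=1, partner="c2") for i in range(40)]
        assert candidate_windows({"c1": wins}) == []

    def test_spike_is_candidate(self):
        wins = [window(start=i * 1500, total=1000, hit=h, partner="c2")
                for i, h in enumerate([10, 12, 8, 11] * 10)]
        wins.append(window(start=40 * 1500, total=1000, hit=60, partner="c2"))
        cands = candidate_windows({"c1": wins})
        assert [w.start for w in cands] == [40 * 1500]

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            outlier_cutoff([window()] * 10)


def hit_read(start, mate_contig="c2", mate_start=1000, name=None):
    return make_read(start=start, mate_contig=mate_contig, mate_start=mate_start,
                     name=name or f"h{start}.{mate_start}")


class TestCallRegions:
    def test_regions_span_hits_and_mates(self):
        reads = [hit_read(100 + 10 * i, mate_start=5000 + 20 * i) for i in range(6)]
        calls = call_regions([window(hit=6, partner="c2", hit_reads=reads)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.contig_a, c.start_a, c.end_a) == ("c1", 100, 200)
        assert (c.contig_b, c.start_b, c.end_b) == ("c2", 5000, 5150)
        assert c.n_pairs == 6

    def test_min_pairs_guard(self):
        reads = [hit_read(100 + i) for i in range(3)]
        assert call_regions([window(hit=3, partner="c2", hit_reads=reads)], min_pairs=5) == []

    def test_two_partners_two_calls(self):
        w1 = window(start=0, hit=5, partner="c2", hit_reads=[hit_read(10 * i) for i in range(5)])
        w2 = window(start=1500, hit=5, partner="c3",
                    hit_reads=[hit_read(1500 + 10 * i, mate_contig="c3") for i in range(5)])
        calls = call_regions([w1, w2])
        assert [(c.contig_a, c.contig_b) for c in calls] == [("c1", "c2"), ("c1", "c3")]

    def test_adjacent_windows_same_partner_merge(self):
        w1 = window(start=0, hit=4, partner="c2", hit_reads=[hit_read(10 * i) for i in range(4)])
        w2 = window(start=1500, hit=4, partner="c2",
                    hit_reads=[hit_read(1500 + 10 * i) for i in range(4)])
        calls = call_regions([w1, w2], min_pairs=5)
        assert len(calls) == 1 and calls[0].n_pairs == 8

    def test_distant_mate_clusters_split(self):
        near = [hit_read(100 + i, mate_start=5000 + i) for i in range(6)]
        far = [hit_read(200 + i, mate_start=5_000_000 + i) for i in range(6)]
        calls = call_regions([window(hit=12, partner="c2", hit_reads=near + far)], max_span=1_000_000)
        assert len(calls) == 2


class TestSomaticSubtract:
    def _call(self, sa=100, sb=5000, ca="c1", cb="c2"):
        return TranslocationCall(ca, sa, sa + 200, cb, sb, sb + 200, 8)

    def test_self_subtraction_is_empty(self):
        calls = [self._call(), self._call(sa=9000, cb="c3")]
        assert somatic_subtract(calls, calls) == []

    def test_tumor_only_call_is_somatic(self):
        out = somatic_subtract([self._call()], [self._call(sa=50_000, sb=90_000)])
        assert len(out) == 1 and out[0].somatic

    def test_overlap_requires_both_regions(self):
        tumor = self._call()
        germ = self._call(sb=50_000)  # region A overlaps, region B does not
        assert len(somatic_subtract([tumor], [germ])) == 1

    def test_swapped_region_order_still_matches(self):
        tumor = self._call()
        germ = TranslocationCall("c2", 5050, 5250, "c1", 150, 350, 8)
        assert somatic_subtract([tumor], [germ]) == []


class TestPairedGff:
    def test_two_calls_four_lines_and_round_trip(self, tmp_path):
        calls = [
            TranslocationCall("c1", 100, 300, "c2", 5000, 5200, 8, somatic=True),
            TranslocationCall("c3", 10, 60, "c4", 900, 1000, 5),
        ]
        path = tmp_path / "tl.gff3"
        write_paired_gff(calls, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("##gff-version")
        assert len(lines) == 5
        assert read_paired_gff(path) == calls

    def test_empty_calls_header_only(self, tmp_path):
        path = tmp_path / "empty.gff3"
        write_paired_gff([], path)
        assert path.read_text().splitlines() == ["##gff-version 3"]
        assert read_paired_gff(path) == []


class TestPipelineOnSimulation:
    def test_somatic_fusions_recovered_and_shared_removed(self, fusion_sim):
        calls = call_translocations(
            fusion_sim["tumor"], fusion_sim["germline"], fusion_sim["lens"]
        )
        assert len(calls) == 2
        planted = {
            frozenset([("chrA", 60_000), ("chrB", 150_000)]),
            frozenset([("chrC", 120_000), ("chrD", 40_000)]),
        }
        insert = fusion_sim["cfg"].insert_mean
        matched = set()
        for c in calls:
            for p in planted:
                d = dict(p)
                if {c.contig_a, c.contig_b} == set(d):
                    ra = (c.start_a, c.end_a) if c.contig_a in d else None
                    # breakpoint regions within one insert length of truth
                    assert abs((c.start_a + c.end_a) / 2 - d[c.contig_a]) < insert
                    assert abs((c.start_b + c.end_b) / 2 - d[c.contig_b]) < insert
                    matched.add(p)
        assert matched == planted

    def test_shared_fusion_called_in_both_samples(self, fusion_sim):
        wins_t = scan_windows(fusion_sim["tumor"], fusion_sim["lens"])
        wins_g = scan_windows(fusion_sim["germline"], fusion_sim["lens"])
        calls_t = call_regions(candidate_windows(wins_t))
        calls_g = call_regions(candidate_windows(wins_g))
        pairs_g = {frozenset((c.contig_a, c.contig_b)) for c in calls_g}
        assert pairs_g == {frozenset(("chrB", "chrC"))}
        pairs_t = {frozenset((c.contig_a, c.contig_b)) for c in calls_t}
        assert frozenset(("chrB", "chrC")) in pairs_t
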