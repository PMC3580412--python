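"""Alignment records, PCR-duplicate marking, stranded pileups and coverage.

Alignments are held as lightweight :class:`AlignedRead` objects (one mapped
50 bp mate each); SAM files are read and written through pysam.  All
downstream callers consume the outputs of this module: duplicate-flagged
read lists, per-site per-strand pileups, and 100 bp binned coverage tracks.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pysam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignedRead:
    """One mapped mate of a pair.

    ``start`` is 0-based; ``insert`` is the signed outer fragment span
    (0 when the mates map to different contigs); ``quals`` are raw Phred
    values, one per base.
    """

    name: str
    contig: str
    start: int
    strand: str  # "+" | "-"
    cigar: str
    seq: str
    quals: bytes
    mate_contig: str | None = None
    mate_start: int | None = None
    insert: int = 0
    mate_strand: str | None = None
    is_read1: bool = True
    is_duplicate: bool = False

    def cigar_ops(self) -> list[tuple[str, int]]:
        return [(op, int(n)) for n, op in _CIGAR_RE.findall(self.cigar)]

    @property
    def end(self) -> int:
        """One past the last reference base consumed by the alignment."""
        return self.start + sum(n for op, n in self.cigar_ops() if op in "MDN=X")

    def base_at(self, site: int) -> tuple[str, int] | None:
        """(base, quality) aligned over reference position ``site``, or None.

        Deleted and skipped reference positions yield None; insertions do
        not consume reference and so never match a site.
        """
        ref = self.start
        qi = 0
        for op, n in self.cigar_ops():
            if op in "M=X":
                if ref <= site < ref + n:
                    off = qi + (site - ref)
                    return self.seq[off], self.quals[off]
                ref += n
                qi += n
            elif op in "DN":
                if ref <= site < ref + n:
                    return None
                ref += n
            elif op in "IS":
                qi += n
        return None

    def total_quality(self) -> int:
        return sum(self.quals)

    def aligned_ref_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals consumed by M/=/X operations."""
        out = []
        ref = self.start
        for op, n in self.cigar_ops():
            if op in "M=X":
                out.append((ref, ref + n))
                ref += n
            elif op in "DN":
                ref += n
        return out


@dataclass
class StrandedPileup:
    """Per-site base/quality observations, kept separately per strand."""

    contig: str
    site: int
    forward: list[tuple[str, int]] = field(default_factory=list)
    reverse: list[tuple[str, int]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.forward) + len(self.reverse)

    def combined(self) -> list[tuple[str, int]]:
        return self.forward + self.reverse

    def alt_count(self, alt: str) -> int:
        return sum(1 for b, _ in self.forward if b == alt) + sum(
            1 for b, _ in self.reverse if b == alt
        )


@dataclass
class CoverageTrack:
    """Binned coverage per contig.

    ``kind`` is "base" (mean per-base sequence depth within the bin) or
    "fragment" (count of mate-pair outer spans overlapping the bin — the
    clonal-coverage convention for long-insert libraries).
    """

    bin_size: int
    kind: str
    depths: dict[str, np.ndarray]

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.depths):
                d = self.depths[contig]
                for i, v in enumerate(d):
                    fh.write(f"{contig}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:g}\n")


# ---------------------------------------------------------------------------
# SAM I/O


def _sam_header(contig_lengths: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(ln)} for name, ln in contig_lengths.items()],
    }


def write_sam(reads: list[AlignedRead], path, contig_lengths: dict[str, int]) -> None:
    """Write coordinate-sorted records as SAM (or BAM if the path ends .bam)."""
    mode = "wb" if str(path).endswith(".bam") else "w"
    header = _sam_header(contig_lengths)
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        refids = {name: i for i, name in enumerate(contig_lengths)}
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = refids[r.contig]
            a.reference_start = r.start
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.cigarstring = r.cigar
            a.mapping_quality = 60
            flag = 0x1  # paired
            if r.strand == "-":
                flag |= 0x10
            if r.mate_strand == "-":
                flag |= 0x20
            flag |= 0x40 if r.is_read1 else 0x80
            if r.is_duplicate:
                flag |= 0x400
            if r.mate_contig is None:
                flag |= 0x8
            a.flag = flag
            if r.mate_contig is not None:
                a.next_reference_id = refids[r.mate_contig]
                a.next_reference_start = r.mate_start
            a.template_length = r.insert
            out.write(a)


def read_sam(path) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    name=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    cigar=a.cigarstring,
                    seq=a.query_sequence,
                    quals=bytes(a.query_qualities),
                    mate_contig=None if a.mate_is_unmapped else a.next_reference_name,
                    mate_start=None if a.mate_is_unmapped else a.next_reference_start,
                    insert=a.template_length,
                    mate_strand=None
                    if a.mate_is_unmapped
                    else ("-" if a.mate_is_reverse else "+"),
                    is_read1=a.is_read1,
                    is_duplicate=a.is_duplicate,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# duplicate marking


def _check_sorted(reads: list[AlignedRead]) -> None:
    cur: str | None = None
    last_start = -1
    seen: set[str] = set()
    for r in reads:
        if r.contig != cur:
            if r.contig in seen:
                raise ValueError(
                    f"input not coordinate-sorted at record {r.name}: contig {r.contig} re-appears"
                )
            seen.add(r.contig)
            cur = r.contig
            last_start = -1
        if r.start < last_start:
            raise ValueError(
                f"input not coordinate-sorted at record {r.name} ({r.contig}:{r.start})"
            )
        last_start = r.start


def mark_duplicates(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Flag PCR-duplicate equivalents at the fragment level.

    Reads sharing (contig, start, strand, mate contig, mate start) are one
    amplification family: all but the member with the highest total base
    quality are flagged (ties keep the first in input order).  Requires
    coordinate-sorted input; returns the same list with flags set.
    """
    _check_sorted(reads)
    best: dict[tuple, AlignedRead] = {}
    for r in reads:
        r.is_duplicate = False
        key = (r.contig, r.start, r.strand, r.mate_contig, r.mate_start)
        cur = best.get(key)
        if cur is None:
            best[key] = r
        elif r.total_quality() > cur.total_quality():
            cur.is_duplicate = True
            best[key] = r
        else:
            r.is_duplicate = True
    return reads


# ---------------------------------------------------------------------------
# pileups


def build_pileups(
    reads: list[AlignedRead], sites: list[tuple[str, int]]
) -> dict[tuple[str, int], StrandedPileup]:
    """Stranded pileups at the requested (contig, site) positions.

    Duplicate-flagged reads are excluded.  Each covering read contributes
    exactly one (base, quality) observation to the list for its strand;
    reads whose CIGAR deletes the site contribute nothing.
    """
    by_contig: dict[str, list[int]] = {}
    for contig, site in sites:
        by_contig.setdefault(contig, []).append(site)
    for v in by_contig.values():
        v.sort()
    out = {key: StrandedPileup(key[0], key[1]) for key in sites}
    for r in reads:
        if r.is_duplicate:
            continue
        csites = by_contig.get(r.contig)
        if not csites:
            continue
        lo = bisect_left(csites, r.start)
        hi = bisect_right(csites, r.end - 1)
        for site in csites[lo:hi]:
            obs = r.base_at(site)
            if obs is None:
                continue
            p = out[(r.contig, site)]
            (p.forward if r.strand == "+" else p.reverse).append(obs)
    return out


# ---------------------------------------------------------------------------
# binned coverage


def binned_coverage(
    reads: list[AlignedRead],
    contig_lengths: dict[str, int],
    kind: str = "fragment",
    bin_size: int = 100,
) -> CoverageTrack:
    """100 bp-binned coverage of one sample.

    ``kind="base"`` reports mean per-base aligned-sequence depth per bin;
    ``kind="fragment"`` counts mate-pair outer spans (leftmost mate start to
    rightmost mate end) overlapping each bin, counted once per pair.  Pairs
    whose mates sit on different contigs, and reads with unmapped mates,
    contribute to base coverage only.  Duplicate-flagged reads are ignored.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if kind not in ("base", "fragment"):
        raise ValueError(f"unknown coverage kind {kind!r}")
    depths: dict[str, np.ndarray] = {}
    nbins = {c: (L + bin_size - 1) // bin_size for c, L in contig_lengths.items()}
    if kind == "base":
        for contig, L in contig_lengths.items():
            delta = np.zeros(L + 1, dtype=np.int64)
            for r in reads:
                if r.is_duplicate or r.contig != contig:
                    continue
                for s, e in r.aligned_ref_blocks():
                    delta[s] += 1
                    delta[min(e, L)] -= 1
            per_base = np.cumsum(delta[:-1])
            n = nbins[contig]
            padded = np.zeros(n * bin_size, dtype=np.int64)
            padded[:L] = per_base
            depths[contig] = padded.reshape(n, bin_size).sum(axis=1) / bin_size
        return CoverageTrack(bin_size=bin_size, kind="base", depths=depths)

    # fragment kind: outer span per same-contig pair, counted once
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    seen: dict[str, AlignedRead] = {}
    for r in reads:
        if r.is_duplicate:
            continue
        if r.mate_contig is None or r.mate_contig != r.contig:
            continue
        mate = seen.pop(r.name, None)
        if mate is None:
            seen[r.name] = r
            continue
        s = min(r.start, mate.start)
        e = max(r.end, mate.end)
        spans[r.contig].append((s, e))
    for contig, L in contig_lengths.items():
        n = nbins[contig]
        delta = np.zeros(n + 1, dtype=np.int64)
        for s, e in spans[contig]:
            b0 = s // bin_size
            b1 = min((e - 1) // bin_size, n - 1)
            delta[b0] += 1
            delta[b1 + 1] -= 1
        depths[contig] = np.cumsum(delta[:-1]).astype(float)
    return CoverageTrack(bin_size=bin_size, kind="fragment", depths=depths)
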