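"""Strand-minimum two-proportion somatic SNV caller and dual-threshold consensus.

For each candidate site the tumor and germline alternate-allele counts are
compared per strand with a pooled two-proportion z statistic; the reported
site statistic is the minimum of the forward and reverse statistics, so a
passing call needs somatic evidence on both strands.  Sites with alternate
evidence in the germline are filtered to suppress under-sampled germline
polymorphisms.  Final calls are the consensus with the KS genotyper: sites
called by both algorithms under a strict parameter set, plus sites called
by both under a lenient set that also survive deterministic post-filters
(strand allele-fraction balance, distance from indel candidates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .reads import AlignedRead, StrandedPileup, build_pileups
from .genotype import solsnp_somatic_sites
import numpy as np


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for one tier of the proportion-test caller."""

    min_stat: float
    germline_max_alt: int
    germline_max_frac: float
    min_alt_per_strand: int
    min_depth_per_strand: int
    label: str = "custom"


# Default tiers.  The statistic thresholds are the one-sided normal
# quantiles for p = 0.001 (strict) and p = 0.05 (lenient); they apply to the
# *minimum* over the two strand statistics, so a lenient pass is already a
# joint requirement on both strands.  See the methods note for the power
# analysis behind these choices at the 37x/40x, 60%-purity design point.
STRICT_DEFAULTS = CallerParams(
    min_stat=3.09, germline_max_alt=1, germline_max_frac=0.02,
    min_alt_per_strand=3, min_depth_per_strand=8, label="strict",
)
LENIENT_DEFAULTS = CallerParams(
    min_stat=1.645, germline_max_alt=2, germline_max_frac=0.05,
    min_alt_per_strand=2, min_depth_per_strand=4, label="lenient",
)


@dataclass
class SomaticSnvCall:
    contig: str
    site: int
    ref: str
    alt: str
    forward_stat: float
    reverse_stat: float
    stat: float  # min of the two strand statistics
    tumor_alt: tuple[int, int]  # (forward, reverse)
    tumor_depth: tuple[int, int]
    germline_alt: tuple[int, int]
    germline_depth: tuple[int, int]
    status: str  # pass | germline_evidence | low_stat | post_filter_fail
    params: str = "custom"
    provenance: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def strand_stat(k_t: int, n_t: int, k_g: int, n_g: int) -> float:
    """Pooled two-proportion z statistic for tumor vs germline alt fractions.

    z = (k_t/n_t - k_g/n_g) / sqrt(p(1-p)(1/n_t + 1/n_g)) with the pooled
    p = (k_t+k_g)/(n_t+n_g); defined as 0 when the pooled proportion is
    degenerate (0 or 1).
    """
    if n_t < 1 or n_g < 1:
        raise ValueError("both samples need at least one observation")
    if not (0 <= k_t <= n_t) or not (0 <= k_g <= n_g):
        raise ValueError("alt counts exceed depths")
    p = (k_t + k_g) / (n_t + n_g)
    if p <= 0.0 or p >= 1.0:
        return 0.0
    se = math.sqrt(p * (1 - p) * (1 / n_t + 1 / n_g))
    return (k_t / n_t - k_g / n_g) / se


def _strand_counts(p: StrandedPileup, alt: str) -> tuple[int, int, int, int]:
    kf = sum(1 for b, _ in p.forward if b == alt)
    kr = sum(1 for b, _ in p.reverse if b == alt)
    return kf, len(p.forward), kr, len(p.reverse)


def call_somatic(
    tumor: StrandedPileup,
    germline: StrandedPileup,
    ref: str,
    alt: str,
    params: CallerParams,
) -> SomaticSnvCall:
    """Score one site from matched tumor/germline stranded pileups.

    The germline-evidence filter fires when germline alternate reads exceed
    ``germline_max_alt`` or the germline alternate fraction exceeds
    ``germline_max_frac``; a pass additionally needs the minimum strand
    statistic at or above threshold, and per-strand tumor alternate reads
    and depths at their minima.
    """
    tkf, tnf, tkr, tnr = _strand_counts(tumor, alt)
    gkf, gnf, gkr, gnr = _strand_counts(germline, alt)

    def safe_stat(kt, nt, kg, ng):
        if nt < 1 or ng < 1:
            return None
        return strand_stat(kt, nt, kg, ng)

    fs = safe_stat(tkf, tnf, gkf, gnf)
    rs = safe_stat(tkr, tnr, gkr, gnr)
    if fs is None or rs is None:
        stat = 0.0
        fs = fs if fs is not None else 0.0
        rs = rs if rs is not None else 0.0
        status = "low_stat"
    else:
        stat = min(fs, rs)
        g_alt = gkf + gkr
        g_depth = gnf + gnr
        g_frac = g_alt / g_depth if g_depth else 0.0
        if g_alt > params.germline_max_alt or g_frac > params.germline_max_frac:
            status = "germline_evidence"
        elif (
            stat >= params.min_stat
            and tkf >= params.min_alt_per_strand
            and tkr >= params.min_alt_per_strand
            and tnf >= params.min_depth_per_strand
            and tnr >= params.min_depth_per_strand
        ):
            status = "pass"
        else:
            status = "low_stat"
    return SomaticSnvCall(
        tumor.contig, tumor.site, ref, alt, fs, rs, stat,
        (tkf, tkr), (tnf, tnr), (gkf, gkr), (gnf, gnr),
        status, params.label,
    )


# ---------------------------------------------------------------------------
# consensus with the genotyper and deterministic post-filters


def _near_indel(contig: str, site: int, indel_positions: Sequence[tuple[str, int, int]],
                margin: int = 5) -> bool:
    for c, s, e in indel_positions:
        if c == contig and s - margin <= site <= e + margin:
            return True
    return False


def _strand_balance_ok(call: SomaticSnvCall, max_fold: float = 2.0) -> bool:
    tf, tr = call.tumor_alt
    nf, nr = call.tumor_depth
    if nf == 0 or nr == 0:
        return False
    af, ar = tf / nf, tr / nr
    lo, hi = min(af, ar), max(af, ar)
    if lo == 0.0:
        return False
    return hi <= max_fold * lo


def consensus_calls(
    solsnp_sites: dict[tuple[str, int], tuple[str, str]],
    strict_calls: Iterable[SomaticSnvCall],
    lenient_calls: Iterable[SomaticSnvCall],
    indel_positions: Sequence[tuple[str, int, int]] = (),
    max_strand_fold: float = 2.0,
) -> list[SomaticSnvCall]:
    """Final somatic SNV list from the two-algorithm, two-tier design.

    The strict set is the intersection of genotyper-somatic sites with
    strict-tier proportion-test passes; the lenient set likewise under the
    lenient tier.  The final list is the strict set plus lenient-only calls
    surviving the automated post-filters (tumor strand allele fractions
    within ``max_strand_fold`` of each other; site farther than 5 bp from
    any indel candidate).  Every call carries its provenance.
    """
    strict_by_site = {(c.contig, c.site): c for c in strict_calls}
    lenient_by_site = {(c.contig, c.site): c for c in lenient_calls}
    for key in set(strict_by_site) & set(lenient_by_site):
        a, b = strict_by_site[key], lenient_by_site[key]
        if (a.ref, a.alt) != (b.ref, b.alt):
            raise ValueError(f"inconsistent alleles between callers at {key}")
    for key, (ref, alt) in solsnp_sites.items():
        for d in (strict_by_site, lenient_by_site):
            c = d.get(key)
            if c is not None and (c.ref, c.alt) != (ref, alt):
                raise ValueError(f"inconsistent alleles between callers at {key}")

    final: list[SomaticSnvCall] = []
    strict_set = {
        k for k, c in strict_by_site.items() if c.passed and k in solsnp_sites
    }
    for key in sorted(strict_set):
        c = strict_by_site[key]
        c.provenance = ["strict_common"]
        final.append(c)
    for key in sorted(set(lenient_by_site) - strict_set):
        c = lenient_by_site[key]
        if not (c.passed and key in solsnp_sites):
            continue
        c.provenance = ["lenient_common"]
        if not _strand_balance_ok(c, max_strand_fold):
            c.status = "post_filter_fail"
            c.provenance.append("strand_balance_fail")
            continue
        if _near_indel(c.contig, c.site, indel_positions):
            c.status = "post_filter_fail"
            c.provenance.append("near_indel_fail")
            continue
        c.provenance.append("post_filters_pass")
        final.append(c)
    final.sort(key=lambda c: (c.contig, c.site))
    return final


# ---------------------------------------------------------------------------
# end-to-end convenience pipeline


def candidate_sites(
    tumor_reads: list[AlignedRead],
    reference: dict[str, str],
    min_alt: int = 3,
) -> list[tuple[str, int]]:
    """Sites with at least ``min_alt`` non-reference tumor reads.

    A vectorized mismatch scan over simple (all-M) alignments plus a
    per-read walk for gapped ones; used to restrict full pileup construction
    to plausible SNV candidates.
    """
    counts: dict[str, np.ndarray] = {}
    refarr: dict[str, np.ndarray] = {
        c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in reference.items()
    }
    simple: dict[str, tuple[list[int], list[str]]] = {c: ([], []) for c in reference}
    rl = None
    for r in tumor_reads:
        if r.is_duplicate:
            continue
        ops = r.cigar_ops()
        if len(ops) == 1 and ops[0][0] == "M":
            if rl is None:
                rl = ops[0][1]
            if ops[0][1] == rl:
                starts, seqs = simple[r.contig]
                starts.append(r.start)
                seqs.append(r.seq)
                continue
        # gapped or unusual length: walk explicitly
        arr = counts.setdefault(r.contig, np.zeros(len(reference[r.contig]), dtype=np.int32))
        qi = 0
        ref = r.start
        for op, n in ops:
            if op in "M=X":
                sub = np.frombuffer(r.seq[qi : qi + n].encode(), dtype=np.uint8)
                mism = np.nonzero(sub != refarr[r.contig][ref : ref + n])[0]
                arr[ref + mism] += 1
                ref += n
                qi += n
            elif op in "DN":
                ref += n
            elif op in "IS":
                qi += n
    for contig, (starts, seqs) in simple.items():
        if not starts:
            continue
        arr = counts.setdefault(contig, np.zeros(len(reference[contig]), dtype=np.int32))
        sarr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(starts), rl)
        st = np.asarray(starts, dtype=np.int64)
        gathered = refarr[contig][st[:, None] + np.arange(rl)[None, :]]
        ri, rj = np.nonzero(sarr != gathered)
        np.add.at(arr, st[ri] + rj, 1)
    out = []
    for contig in sorted(counts):
        for pos in np.nonzero(counts[contig] >= min_alt)[0]:
            out.append((contig, int(pos)))
    return out


def call_somatic_snvs(
    tumor_reads: list[AlignedRead],
    germline_reads: list[AlignedRead],
    reference: dict[str, str],
    strict: CallerParams = STRICT_DEFAULTS,
    lenient: CallerParams = LENIENT_DEFAULTS,
    indel_positions: Sequence[tuple[str, int, int]] = (),
    min_candidate_alt: int = 3,
    sites: list[tuple[str, int]] | None = None,
    purity: float | None = None,
) -> list[SomaticSnvCall]:
    """Full somatic SNV pipeline on in-memory reads.

    Candidate sites (unless given) are tumor positions with enough
    non-reference support; both callers are evaluated at every candidate and
    the strict/lenient consensus is returned.  When the specimen's tumor
    cellularity is known, passing ``purity`` adjusts the genotyper's
    tumor-side heterozygous expectation to the diluted fraction purity/2.
    """
    if sites is None:
        sites = candidate_sites(tumor_reads, reference, min_candidate_alt)
    if not sites:
        return []
    tp = build_pileups(tumor_reads, sites)
    gp = build_pileups(germline_reads, sites)
    het_af = 0.5 if purity is None else purity / 2.0
    sol = solsnp_somatic_sites(tp, gp, reference, tumor_het_alt_fraction=het_af)

    def walker(params: CallerParams) -> list[SomaticSnvCall]:
        calls = []
        for key in sites:
            contig, site = key
            ref = reference[contig][site]
            if key in sol:
                alt = sol[key][1]
            else:
                from .genotype import pick_alt

                alt = pick_alt(tp[key], ref)
            if alt is None:
                continue
            calls.append(call_somatic(tp[key], gp[key], ref, alt, params))
        return calls

    return consensus_calls(sol, walker(strict), walker(lenient), indel_positions)
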