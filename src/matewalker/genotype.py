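"""Stranded Kolmogorov-Smirnov-style genotyper.

At each site, the sampled pileup on each strand is compared to expected
pileups for every genotype compatible with the ploidy (all-reference,
half-and-half, all-alternative for a diploid).  Each expected pileup keeps
the observed number of positions and the observed quality values, only the
bases change.  A KS-like distance — the maximum absolute difference between
quality-weighted cumulative base-category masses — scores each expected
pileup, the argmin is the strand's genotype, and in consensus mode a call is
made only when both strands agree.  A site is a variant when a non-reference
genotype is detected on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .reads import StrandedPileup

Observation = tuple[str, int]  # (base, Phred quality)

GENOTYPES_DIPLOID = ("hom_ref", "het", "hom_alt")
GENOTYPES_HAPLOID = ("hom_ref", "hom_alt")


def quality_weight(q: int) -> float:
    """Probability the base call is correct: 1 - 10^(-q/10)."""
    return 1.0 - 10.0 ** (-q / 10.0)


@dataclass
class GenotypeCall:
    contig: str
    site: int
    ref: str
    alt: str | None
    forward_genotype: str | None
    reverse_genotype: str | None
    forward_distances: dict[str, float]
    reverse_distances: dict[str, float]
    consensus: str | None
    is_variant: bool
    no_call_reason: str | None = None


def expected_pileups(
    observed: Sequence[Observation],
    ref: str,
    alt: str,
    ploidy: int = 2,
    het_alt_fraction: float = 0.5,
) -> dict[str, list[Observation]]:
    """Expected pileups for each genotype, matching the observed qualities.

    The heterozygous pileup (diploid only) assigns the reference base to the
    first ceil(n/2) positions and the alternative to the rest; with a single
    observation this degenerates to an all-reference pileup (documented,
    the caller treats such strands as too shallow anyway).

    ``het_alt_fraction`` generalizes the heterozygous expectation for impure
    specimens: a clonal het diluted by tumor cellularity c has expected
    alternate fraction c/2, so a tumor-side caller can pass
    ``het_alt_fraction=c/2`` instead of the pure-diploid 0.5.  The expected
    pileup then assigns the alternative base to the last
    ``floor(n * het_alt_fraction)`` positions.
    """
    if ref == alt:
        raise ValueError("reference and alternative base must differ")
    if not observed:
        raise ValueError("need at least one observation")
    if not 0.0 < het_alt_fraction <= 0.5:
        raise ValueError("het_alt_fraction must lie in (0, 0.5]")
    quals = [q for _, q in observed]
    n = len(quals)
    out = {
        "hom_ref": [(ref, q) for q in quals],
        "hom_alt": [(alt, q) for q in quals],
    }
    if ploidy == 2:
        n_ref = n - int(n * het_alt_fraction)  # == ceil(n/2) at fraction 0.5
        out["het"] = [(ref if i < n_ref else alt, q) for i, q in enumerate(quals)]
    elif ploidy != 1:
        raise ValueError("only ploidy 1 or 2 supported")
    return out


def _category_masses(
    pileup: Sequence[Observation],
    ref: str,
    alt: str,
    weight_fn: Callable[[int], float],
) -> tuple[float, float, float]:
    """Normalized quality-weighted mass over the ordered alphabet ref < alt < other."""
    m = [0.0, 0.0, 0.0]
    for base, q in pileup:
        w = weight_fn(q)
        if base == ref:
            m[0] += w
        elif base == alt:
            m[1] += w
        else:
            m[2] += w
    tot = m[0] + m[1] + m[2]
    if tot <= 0.0:
        raise ValueError("uninformative pileup: all quality weights are zero")
    return m[0] / tot, m[1] / tot, m[2] / tot


def ks_distance(
    observed: Sequence[Observation],
    expected: Sequence[Observation],
    ref: str,
    alt: str,
    weight_fn: Callable[[int], float] = quality_weight,
) -> float:
    """Max absolute difference of cumulative quality-weighted base masses.

    Both pileups are reduced to normalized masses over the fixed category
    order (ref, alt, other); the distance is the largest absolute difference
    between the two cumulative mass functions.  Symmetric, in [0, 1], and 0
    iff the weighted masses agree exactly.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected pileups must have equal position counts")
    o = _category_masses(observed, ref, alt, weight_fn)
    e = _category_masses(expected, ref, alt, weight_fn)
    c1 = abs(o[0] - e[0])
    c2 = abs((o[0] + o[1]) - (e[0] + e[1]))
    return max(c1, c2)


def pick_alt(pileup: StrandedPileup, ref: str,
             weight_fn: Callable[[int], float] = quality_weight) -> str | None:
    """Non-reference base with the greatest total quality weight (both strands).

    Ties break lexicographically (the alphabetically first base wins).
    Returns None when no non-reference base was observed.
    """
    weights: dict[str, float] = {}
    for base, q in pileup.combined():
        if base != ref:
            weights[base] = weights.get(base, 0.0) + weight_fn(q)
    if not weights:
        return None
    return min(weights, key=lambda b: (-weights[b], b))


def _strand_genotype(
    obs: Sequence[Observation],
    ref: str,
    alt: str,
    ploidy: int,
    weight_fn: Callable[[int], float],
    het_alt_fraction: float = 0.5,
) -> tuple[str, dict[str, float]]:
    exp = expected_pileups(obs, ref, alt, ploidy, het_alt_fraction)
    order = GENOTYPES_DIPLOID if ploidy == 2 else GENOTYPES_HAPLOID
    dists = {g: ks_distance(obs, exp[g], ref, alt, weight_fn) for g in order}
    best = min(order, key=lambda g: dists[g])  # ties resolve to hom_ref first
    return best, dists


def call_site(
    pileup: StrandedPileup,
    ref: str,
    alt: str | None = None,
    strand_mode: str = "consensus",
    ploidy: int = 2,
    min_strand_depth: int = 4,
    weight_fn: Callable[[int], float] = quality_weight,
    het_alt_fraction: float = 0.5,
) -> GenotypeCall:
    """Genotype one site from its stranded pileup.

    ``strand_mode="consensus"`` requires identical genotypes on both strands
    (otherwise no-call); ``"any"`` drops the identity requirement but a
    variant still needs a non-reference genotype on *both* strands.
    """
    if strand_mode not in ("consensus", "any"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    if alt is None:
        alt = pick_alt(pileup, ref, weight_fn)
    if alt is None:
        # no non-reference observation anywhere: trivially hom_ref
        dists = {g: (0.0 if g == "hom_ref" else 1.0)
                 for g in (GENOTYPES_DIPLOID if ploidy == 2 else GENOTYPES_HAPLOID)}
        return GenotypeCall(pileup.contig, pileup.site, ref, None, "hom_ref", "hom_ref",
                            dists, dict(dists), "hom_ref", False)
    if len(pileup.forward) < min_strand_depth or len(pileup.reverse) < min_strand_depth:
        return GenotypeCall(pileup.contig, pileup.site, ref, alt, None, None, {}, {},
                            None, False, no_call_reason="strand depth below minimum")
    fg, fd = _strand_genotype(pileup.forward, ref, alt, ploidy, weight_fn, het_alt_fraction)
    rg, rd = _strand_genotype(pileup.reverse, ref, alt, ploidy, weight_fn, het_alt_fraction)
    if strand_mode == "consensus":
        consensus = fg if fg == rg else None
        variant = consensus is not None and consensus != "hom_ref"
        reason = None if consensus else "strand genotypes disagree"
    else:
        consensus = fg if fg == rg else None
        variant = fg != "hom_ref" and rg != "hom_ref"
        reason = None
    return GenotypeCall(pileup.contig, pileup.site, ref, alt, fg, rg, fd, rd,
                        consensus, variant, no_call_reason=reason)


def solsnp_somatic_sites(
    tumor_pileups: dict[tuple[str, int], StrandedPileup],
    germline_pileups: dict[tuple[str, int], StrandedPileup],
    reference: dict[str, str],
    tumor_het_alt_fraction: float = 0.5,
    **kwargs,
) -> dict[tuple[str, int], tuple[str, str]]:
    """Sites the genotyper deems somatic: variant in tumor, hom_ref in germline.

    The tumor-side heterozygous expectation can be purity-adjusted through
    ``tumor_het_alt_fraction`` (cellularity/2 for a clonal het); the germline
    is always genotyped against the pure-diploid expectation.  Returns a map
    of (contig, site) to (ref, alt) for consumption by the consensus step of
    the somatic SNV pipeline.
    """
    out: dict[tuple[str, int], tuple[str, str]] = {}
    for key, tp in tumor_pileups.items():
        contig, site = key
        ref = reference[contig][site]
        alt = pick_alt(tp, ref)
        if alt is None:
            continue
        tcall = call_site(tp, ref, alt, het_alt_fraction=tumor_het_alt_fraction, **kwargs)
        if not tcall.is_variant:
            continue
        gp = germline_pileups.get(key)
        if gp is None:
            continue
        gcall = call_site(gp, ref, alt, **kwargs)
        if gcall.consensus == "hom_ref":
            out[key] = (ref, alt)
    return out
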