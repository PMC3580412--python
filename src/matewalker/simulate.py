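"""Paired tumor/germline mate-pair simulator with planted truth.

The simulator emulates the study design the callers in this package target:
a diploid germline genome and a matched tumor specimen of ~60% tumor-cell
content, sequenced as 1.5 kb-insert mate-pair libraries with 50 bp x 50 bp
reads to ~37x (tumor) and ~40x (germline) base coverage.

Two fidelity modes are provided:

* **read-level** (:func:`simulate_mate_pairs`) — emits per-read alignment
  records with correct CIGARs for planted indels, purity-diluted somatic
  alleles, copy-number-weighted sampling, and fusion-spanning pairs whose
  mates map to two different contigs.  Intended for genomes up to a few Mb.
* **depth-level** (:func:`simulate_bin_depths`) — emits Poisson fragment
  depths per 100 bp bin for tumor and germline, with the tumor rate scaled
  by the local mixture copy number ``purity*CN/2 + (1-purity)``.  Intended
  for tens-of-Mb copy-number experiments where read-level simulation is
  unnecessary.

Every planted event is recorded in a :class:`TruthSet`, the acceptance
surface for the callers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .reads import AlignedRead, CoverageTrack

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

# stage tags mixed into the seed stream so each simulation phase has an
# independent but reproducible RNG
_STAGE_REFERENCE = 1
_STAGE_VARIANTS = 2
_STAGE_READS_GERMLINE = 3
_STAGE_READS_TUMOR = 4
_STAGE_DEPTHS = 5

MAX_READS = 100_000_000  # desk-scale guard for read-level mode


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int


@dataclass(frozen=True)
class IndelSpec:
    """A planted insertion or deletion.

    ``start`` is 0-based on the reference; deletions remove
    ``[start, start+length)``; insertions insert ``length`` bases (or the
    explicit ``sequence``) immediately before ``start``.
    """

    contig: str
    start: int
    length: int
    kind: str  # "ins" | "del"
    sequence: str | None = None

    @property
    def end(self) -> int:
        return self.start + (self.length if self.kind == "del" else 0)


@dataclass(frozen=True)
class CnvSpec:
    contig: str
    start: int
    end: int
    copy_number: int  # tumor copy number in {0,1,2,3,4}


@dataclass(frozen=True)
class FusionSpec:
    contig_a: str
    pos_a: int
    contig_b: str
    pos_b: int
    somatic: bool = True


@dataclass
class SimulationConfig:
    """All knobs of one paired simulation.

    Defaults encode the study conditions: 60% tumor cellularity, 37x/40x
    tumor/germline coverage, 1.5 kb mate-pair inserts with 50 bp reads, and a
    germline transition:transversion ratio of 2.12.
    """

    genome: list[ContigSpec] = field(default_factory=list)
    purity: float = 0.6
    mean_coverage_tumor: float = 37.0
    mean_coverage_germline: float = 40.0
    insert_mean: float = 1500.0
    insert_sd: float = 150.0
    read_len: int = 50
    titv_ratio: float = 2.12
    germline_snp_rate: float = 1e-3
    germline_snp_count: int | None = None
    het_fraction: float = 2.0 / 3.0
    somatic_snv_count: int = 0
    somatic_indels: list[IndelSpec] = field(default_factory=list)
    germline_indels: list[IndelSpec] = field(default_factory=list)
    cnvs: list[CnvSpec] = field(default_factory=list)
    fusions: list[FusionSpec] = field(default_factory=list)
    base_quality: int = 30
    error_rate: float | None = None  # default: 10**(-base_quality/10)
    duplicate_rate: float = 0.0
    chimera_rate: float = 0.0  # fraction of pairs given a random-mate chimeric placement
    seed: int = 0

    def __post_init__(self) -> None:
        self.genome = [
            c if isinstance(c, ContigSpec) else ContigSpec(*c) for c in self.genome
        ]
        self.somatic_indels = [
            i if isinstance(i, IndelSpec) else IndelSpec(**i) for i in self.somatic_indels
        ]
        self.germline_indels = [
            i if isinstance(i, IndelSpec) else IndelSpec(**i) for i in self.germline_indels
        ]
        self.cnvs = [c if isinstance(c, CnvSpec) else CnvSpec(**c) for c in self.cnvs]
        self.fusions = [
            f if isinstance(f, FusionSpec) else FusionSpec(**f) for f in self.fusions
        ]

    # -- validation ---------------------------------------------------------

    def contig_length(self, name: str) -> int:
        for c in self.genome:
            if c.name == name:
                return c.length
        raise ValueError(f"unknown contig {name!r}")

    def validate(self) -> None:
        if not self.genome:
            raise ValueError("genome spec is empty")
        for c in self.genome:
            if c.length <= 0:
                raise ValueError(f"contig {c.name!r} has non-positive length {c.length}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed twice the read length")
        if self.titv_ratio < 0:
            raise ValueError("titv_ratio must be non-negative")
        for ind in self.somatic_indels + self.germline_indels:
            L = self.contig_length(ind.contig)
            if not (0 <= ind.start and ind.end <= L):
                raise ValueError(f"indel {ind} outside contig bounds")
            if ind.kind not in ("ins", "del"):
                raise ValueError(f"indel kind must be 'ins' or 'del', got {ind.kind!r}")
        for cnv in self.cnvs:
            L = self.contig_length(cnv.contig)
            if not (0 <= cnv.start < cnv.end <= L):
                raise ValueError(f"CNV {cnv} outside contig bounds")
            if cnv.copy_number not in (0, 1, 2, 3, 4):
                raise ValueError(f"tumor copy number must be 0..4, got {cnv.copy_number}")
        # same-contig CNV intervals must be nested or disjoint
        for i, a in enumerate(self.cnvs):
            for b in self.cnvs[i + 1 :]:
                if a.contig != b.contig:
                    continue
                lo, hi = sorted((a, b), key=lambda c: (c.start, -c.end))
                overlap = min(a.end, b.end) - max(a.start, b.start)
                nested = lo.start <= hi.start and hi.end <= lo.end
                if overlap > 0 and not nested:
                    raise ValueError(f"CNV intervals {a} and {b} partially overlap")
        for fus in self.fusions:
            for contig, pos in ((fus.contig_a, fus.pos_a), (fus.contig_b, fus.pos_b)):
                if not 0 <= pos < self.contig_length(contig):
                    raise ValueError(f"fusion breakpoint {contig}:{pos} out of bounds")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genome"] = [ContigSpec(**c) for c in raw.get("genome", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# truth set


@dataclass(frozen=True)
class GermlineSnp:
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"


@dataclass(frozen=True)
class SomaticSnv:
    contig: str
    pos: int
    ref: str
    alt: str
    expected_af: float  # expected alternate-allele fraction in the tumor specimen


@dataclass(frozen=True)
class TruthIndel:
    contig: str
    start: int
    end: int
    kind: str
    sequence: str
    somatic: bool


@dataclass
class TruthSet:
    """Record of every planted event — the acceptance surface for the callers."""

    germline_snps: list[GermlineSnp] = field(default_factory=list)
    somatic_snvs: list[SomaticSnv] = field(default_factory=list)
    somatic_indels: list[TruthIndel] = field(default_factory=list)
    germline_indels: list[TruthIndel] = field(default_factory=list)
    cnv_segments: list[CnvSpec] = field(default_factory=list)
    fusions: list[FusionSpec] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tcontig\tstart\tend\tref\talt\tinfo\n")
            for s in self.germline_snps:
                fh.write(
                    f"germline_snp\t{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{s.genotype}\n"
                )
            for s in self.somatic_snvs:
                fh.write(
                    f"somatic_snv\t{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.ref}\t{s.alt}\taf={s.expected_af:.4f}\n"
                )
            for i in self.somatic_indels + self.germline_indels:
                k = ("somatic_" if i.somatic else "germline_") + i.kind
                fh.write(f"{k}\t{i.contig}\t{i.start}\t{i.end}\t.\t{i.sequence}\t.\n")
            for c in self.cnv_segments:
                fh.write(f"cnv\t{c.contig}\t{c.start}\t{c.end}\t.\t.\tcn={c.copy_number}\n")
            for f in self.fusions:
                tag = "somatic" if f.somatic else "germline"
                fh.write(
                    f"fusion\t{f.contig_a}\t{f.pos_a}\t{f.pos_a + 1}\t.\t.\t{tag}:{f.contig_b}:{f.pos_b}\n"
                )


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class Haplotype:
    """One phased copy of a contig, with coordinate maps to the reference.

    ``refpos[i]`` is the 0-based reference position of haplotype base ``i``
    (-1 for inserted bases); ``hap_of_ref[p]`` is the haplotype index of
    reference base ``p`` (-1 for bases deleted on this haplotype).
    """

    contig: str
    seq: str
    refpos: np.ndarray
    hap_of_ref: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)

    def hap_coord(self, ref_pos: int) -> int:
        """Haplotype index of the first retained reference base at/after ref_pos."""
        h = self.hap_of_ref
        p = ref_pos
        while p < len(h) and h[p] < 0:
            p += 1
        if p >= len(h):
            return len(self.seq)
        return int(h[p])


def _apply_variants(
    contig: str, ref: str, snvs: dict[int, str], indels: list[IndelSpec]
) -> Haplotype:
    arr = bytearray(ref.encode())
    for pos, alt in snvs.items():
        arr[pos] = ord(alt)
    parts: list[bytes] = []
    rparts: list[np.ndarray] = []
    cur = 0
    for ind in sorted(indels, key=lambda i: i.start):
        if ind.start < cur:
            raise ValueError(f"overlapping indels on {contig} at {ind.start}")
        parts.append(bytes(arr[cur : ind.start]))
        rparts.append(np.arange(cur, ind.start, dtype=np.int64))
        if ind.kind == "del":
            cur = ind.start + ind.length
        else:
            parts.append(ind.sequence.encode())
            rparts.append(np.full(ind.length, -1, dtype=np.int64))
            cur = ind.start
    parts.append(bytes(arr[cur:]))
    rparts.append(np.arange(cur, len(arr), dtype=np.int64))
    seq = b"".join(parts).decode()
    refpos = np.concatenate(rparts) if rparts else np.empty(0, dtype=np.int64)
    hap_of_ref = np.full(len(ref), -1, dtype=np.int64)
    mapped = refpos >= 0
    hap_of_ref[refpos[mapped]] = np.nonzero(mapped)[0]
    return Haplotype(contig, seq, refpos, hap_of_ref)


@dataclass
class SimulatedGenomes:
    """Reference, phased germline and tumor haplotypes, and the planted truth."""

    config: SimulationConfig
    reference: dict[str, str]
    germline: dict[str, list[Haplotype]]
    tumor: dict[str, list[Haplotype]]
    truth: TruthSet

    def cn_intervals(self, contig: str) -> list[tuple[int, int, int]]:
        """Elementary (start, end, tumor CN) partition of a contig.

        Nested CNV intervals resolve innermost-wins; uncovered stretches are
        copy-neutral (CN 2).
        """
        L = self.config.contig_length(contig)
        specs = [c for c in self.config.cnvs if c.contig == contig]
        bounds = sorted({0, L} | {c.start for c in specs} | {c.end for c in specs})
        out = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            covering = [c for c in specs if c.start <= s and e <= c.end]
            if covering:
                innermost = min(covering, key=lambda c: c.end - c.start)
                cn = innermost.copy_number
            else:
                cn = 2
            if out and out[-1][2] == cn:
                out[-1] = (out[-1][0], e, cn)
            else:
                out.append((s, e, cn))
        return out

    def copy_number_at(self, contig: str, pos: int) -> int:
        for s, e, cn in self.cn_intervals(contig):
            if s <= pos < e:
                return cn
        return 2


# ---------------------------------------------------------------------------
# stage 1: reference


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Draw a roughly uniform-composition reference sequence per contig.

    Deterministic for a fixed ``config.seed``.  Contigs of at least 10 kb are
    the supported regime for downstream read-level simulation.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_REFERENCE)
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out = {}
    for c in config.genome:
        idx = rng.integers(0, 4, size=c.length)
        out[c.name] = base_arr[idx].tobytes().decode()
    return out


def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# stage 2: variant planting


def _draw_alt(ref: str, p_transition: float, rng: np.random.Generator) -> str:
    if rng.random() < p_transition:
        return _TRANSITION[ref]
    tv = _TRANSVERSIONS[ref]
    return tv[int(rng.integers(0, 2))]


def plant_variants(reference: dict[str, str], config: SimulationConfig) -> SimulatedGenomes:
    """Plant germline and somatic variants; return phased genomes plus truth.

    Germline SNPs substitute a transition with probability
    ``titv_ratio / (titv_ratio + 1)`` and are heterozygous with probability
    ``het_fraction``.  Somatic events touch only the tumor haplotypes; the
    truth set records for every somatic SNV its expected tumor allele
    fraction under the purity/copy-number mixture
    ``purity*c / (purity*CN + (1-purity)*2)`` with ``c`` carrier-haplotype
    copies (``purity/2`` for a clonal het in a copy-neutral region).
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_VARIANTS)
    # transition probability; an infinite ratio means transitions only
    p_ti = (
        1.0
        if math.isinf(config.titv_ratio)
        else config.titv_ratio / (config.titv_ratio + 1.0)
    )
    truth = TruthSet(cnv_segments=list(config.cnvs), fusions=list(config.fusions))

    # materialize insertion sequences once so truth and haplotypes agree
    def _resolve(ind: IndelSpec) -> IndelSpec:
        if ind.kind == "ins" and ind.sequence is None:
            seq = "".join(BASES[i] for i in rng.integers(0, 4, size=ind.length))
            return dataclasses.replace(ind, sequence=seq)
        return ind

    germline_indels = [_resolve(i) for i in config.germline_indels]
    somatic_indels = [_resolve(i) for i in config.somatic_indels]

    # positions to keep clear of random SNVs: indel footprints +/- 10 bp
    blocked: dict[str, set[int]] = {c.name: set() for c in config.genome}
    for ind in germline_indels + somatic_indels:
        blocked[ind.contig].update(range(max(0, ind.start - 10), ind.end + 11))

    contigs = [c.name for c in config.genome]
    lengths = np.array([c.length for c in config.genome], dtype=np.int64)
    total = int(lengths.sum())

    # germline SNP sites: either an exact genome-wide count or a per-base rate
    if config.germline_snp_count is not None:
        offsets = rng.choice(total, size=config.germline_snp_count, replace=False)
        offsets.sort()
        cum = np.concatenate([[0], np.cumsum(lengths)])
        per_contig_sites = {
            name: (offsets[(offsets >= cum[i]) & (offsets < cum[i + 1])] - cum[i])
            for i, name in enumerate(contigs)
        }
    else:
        per_contig_sites = {
            name: np.nonzero(rng.random(int(L)) < config.germline_snp_rate)[0]
            for name, L in zip(contigs, lengths)
        }

    germ_snvs: dict[str, tuple[dict[int, str], dict[int, str]]] = {}
    germline_sites: dict[str, set[int]] = {}
    for name in contigs:
        ref = reference[name]
        h0: dict[int, str] = {}
        h1: dict[int, str] = {}
        used: set[int] = set()
        for pos in per_contig_sites[name]:
            pos = int(pos)
            if pos in blocked[name]:
                continue
            rb = ref[pos]
            alt = _draw_alt(rb, p_ti, rng)
            if rng.random() < config.het_fraction:
                gt = "het"
                if rng.random() < 0.5:
                    h0[pos] = alt
                else:
                    h1[pos] = alt
            else:
                gt = "hom"
                h0[pos] = alt
                h1[pos] = alt
            truth.germline_snps.append(GermlineSnp(name, pos, rb, alt, gt))
            used.add(pos)
        germ_snvs[name] = (h0, h1)
        germline_sites[name] = used

    # somatic SNVs: uniform over the genome, avoiding germline events and indels
    som_snvs: dict[str, tuple[dict[int, str], dict[int, str]]] = {
        name: ({}, {}) for name in contigs
    }
    probs = lengths / total
    sim_stub = SimulatedGenomes(config, reference, {}, {}, truth)
    n_placed = 0
    attempts = 0
    while n_placed < config.somatic_snv_count:
        attempts += 1
        if attempts > 100 * max(1, config.somatic_snv_count):
            raise RuntimeError("could not place requested somatic SNVs (genome too constrained)")
        ci = int(rng.choice(len(contigs), p=probs))
        name = contigs[ci]
        pos = int(rng.integers(0, lengths[ci]))
        if pos in germline_sites[name] or pos in blocked[name]:
            continue
        if pos in som_snvs[name][0] or pos in som_snvs[name][1]:
            continue
        rb = reference[name][pos]
        alt = _draw_alt(rb, p_ti, rng)
        hap = int(rng.integers(0, 2))
        som_snvs[name][hap][pos] = alt
        cn = sim_stub.copy_number_at(name, pos)
        mult = (cn + 1) // 2 if hap == 0 else cn // 2  # carrier copies under CN split
        denom = config.purity * cn + (1 - config.purity) * 2
        af = (config.purity * mult / denom) if denom > 0 else 0.0
        truth.somatic_snvs.append(SomaticSnv(name, pos, rb, alt, af))
        n_placed += 1

    for ind in somatic_indels:
        for h in (som_snvs[ind.contig][0], germ_snvs[ind.contig][0]):
            for pos in list(h):
                if ind.start <= pos < ind.end:
                    raise ValueError(
                        f"somatic indel at {ind.contig}:{ind.start} overlaps a planted SNV"
                    )
        seq = ind.sequence if ind.kind == "ins" else reference[ind.contig][ind.start : ind.end]
        truth.somatic_indels.append(
            TruthIndel(ind.contig, ind.start, ind.end, ind.kind, seq, True)
        )
    for ind in germline_indels:
        seq = ind.sequence if ind.kind == "ins" else reference[ind.contig][ind.start : ind.end]
        truth.germline_indels.append(
            TruthIndel(ind.contig, ind.start, ind.end, ind.kind, seq, False)
        )

    germline: dict[str, list[Haplotype]] = {}
    tumor: dict[str, list[Haplotype]] = {}
    for name in contigs:
        ref = reference[name]
        g_ind = [i for i in germline_indels if i.contig == name]
        s_ind = [i for i in somatic_indels if i.contig == name]
        g0, g1 = germ_snvs[name]
        s0, s1 = som_snvs[name]
        germline[name] = [
            _apply_variants(name, ref, g0, g_ind),  # germline indels carried on hap 0
            _apply_variants(name, ref, g1, []),
        ]
        tumor[name] = [
            _apply_variants(name, ref, {**g0, **s0}, g_ind + s_ind),
            _apply_variants(name, ref, {**g1, **s1}, []),
        ]
    return SimulatedGenomes(config, reference, germline, tumor, truth)


# ---------------------------------------------------------------------------
# stage 3: read-level mate pairs


def _read_from_hap(hap: Haplotype, a: int, read_len: int):
    """Alignment of haplotype bases [a, a+read_len) back to the reference.

    Returns (ref_start, cigar_ops, seq) where cigar_ops is a list of
    (op, length) with op in "MID".  The window is nudged left so it neither
    starts nor ends inside an insertion.
    """
    rp = hap.refpos
    n = len(rp)
    if a + read_len > n:
        a = n - read_len
    while a > 0 and (rp[a] < 0 or rp[a + read_len - 1] < 0):
        a -= 1
    seg = rp[a : a + read_len]
    seq = hap.seq[a : a + read_len]
    ops: list[tuple[str, int]] = []
    ref_start = int(seg[0])
    i = 0
    prev = None
    while i < read_len:
        if seg[i] < 0:
            j = i
            while j < read_len and seg[j] < 0:
                j += 1
            ops.append(("I", j - i))
            i = j
            continue
        if prev is not None and seg[i] - prev > 1:
            ops.append(("D", int(seg[i] - prev - 1)))
        j = i
        while j + 1 < read_len and seg[j + 1] == seg[j] + 1:
            j += 1
        if ops and ops[-1][0] == "M":
            ops[-1] = ("M", ops[-1][1] + (j - i + 1))
        else:
            ops.append(("M", j - i + 1))
        prev = seg[j]
        i = j + 1
    return ref_start, ops, seq


def _cigar_str(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def _ref_len(ops: list[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in "MD")


def simulate_mate_pairs(
    sim: SimulatedGenomes, sample: str, config: SimulationConfig | None = None
) -> list[AlignedRead]:
    """Read-level simulation of one sample ("tumor" or "germline").

    Fragments are drawn per haplotype at a rate proportional to the local
    haplotype multiplicity; for the tumor sample the library is a
    purity-weighted mixture of tumor cells and residual normal cells.
    Fragment lengths are Normal(insert_mean, insert_sd) truncated below at
    twice the read length; both mates of a pair are emitted on the same
    strand (the concordant state for this library chemistry).  Fusion
    breakpoints yield pairs whose mates map to the two partner contigs.
    Records are returned coordinate-sorted.
    """
    config = config or sim.config
    if sample not in ("tumor", "germline"):
        raise ValueError("sample must be 'tumor' or 'germline'")
    stage = _STAGE_READS_TUMOR if sample == "tumor" else _STAGE_READS_GERMLINE
    rng = _rng(config.seed, stage)
    rl = config.read_len
    cov = config.mean_coverage_tumor if sample == "tumor" else config.mean_coverage_germline
    rate = cov / (2.0 * rl)  # pairs per bp at diploid weight 1
    p = config.purity
    err = config.error_rate if config.error_rate is not None else 10 ** (-config.base_quality / 10)
    quals = bytes([config.base_quality]) * rl

    total_bp = sum(c.length for c in config.genome)
    if 2 * rate * total_bp * 2 > MAX_READS:
        raise ValueError("requested depth implies more than 10^8 reads; refuse (desk-scale guard)")

    reads: list[AlignedRead] = []
    counter = 0
    base_bytes = BASES.encode()

    def emit_pair(hap_or_ref, contig, a1, a2, strand, tag):
        nonlocal counter
        if isinstance(hap_or_ref, Haplotype):
            s1, ops1, seq1 = _read_from_hap(hap_or_ref, a1, rl)
            s2, ops2, seq2 = _read_from_hap(hap_or_ref, a2, rl)
        else:  # plain reference string (fusion fragments)
            s1, ops1, seq1 = a1, [("M", rl)], hap_or_ref[0][a1 : a1 + rl]
            s2, ops2, seq2 = a2, [("M", rl)], hap_or_ref[1][a2 : a2 + rl]
            contig, contig2 = contig
        name = f"{sample[0]}{tag}{counter}"
        counter += 2
        if isinstance(hap_or_ref, Haplotype):
            span = (s2 + _ref_len(ops2)) - s1
            r1 = AlignedRead(name, contig, s1, strand, _cigar_str(ops1), seq1, quals,
                             contig, s2, span, strand, True)
            r2 = AlignedRead(name, contig, s2, strand, _cigar_str(ops2), seq2, quals,
                             contig, s1, -span, strand, False)
        else:
            ca, cb = contig, contig2
            r1 = AlignedRead(name, ca, s1, strand, _cigar_str(ops1), seq1, quals,
                             cb, s2, 0, strand, True)
            r2 = AlignedRead(name, cb, s2, strand, _cigar_str(ops2), seq2, quals,
                             ca, s1, 0, strand, False)
        reads.append(r1)
        reads.append(r2)
        return r1, r2

    for contig in (c.name for c in config.genome):
        # sampling components: (haplotype, ref interval, weight per diploid copy)
        comps: list[tuple[Haplotype, int, int, float]] = []
        L = config.contig_length(contig)
        if sample == "germline":
            for h in sim.germline[contig]:
                comps.append((h, 0, L, 0.5))
        else:
            for h in sim.germline[contig]:
                comps.append((h, 0, L, (1 - p) / 2))
            for hi, h in enumerate(sim.tumor[contig]):
                for s, e, cn in sim.cn_intervals(contig):
                    mult = (cn + 1) // 2 if hi == 0 else cn // 2
                    if mult > 0:
                        comps.append((h, s, e, p * mult / 2))
        for hap, s, e, w in comps:
            n = rng.poisson(rate * w * (e - s))
            if n == 0:
                continue
            hs = hap.hap_coord(s)
            he = hap.hap_coord(e) if e < L else len(hap)
            ins = np.maximum(2 * rl, np.rint(rng.normal(config.insert_mean, config.insert_sd, n))).astype(np.int64)
            lim = he - ins
            starts = hs + (rng.random(n) * np.maximum(0, lim - hs)).astype(np.int64)
            keep = (lim > hs) & (starts + ins <= len(hap))
            starts, ins = starts[keep], ins[keep]
            strands = rng.random(len(starts)) < 0.5
            # sequencing errors: flat base indices over this batch
            nb = 2 * len(starts) * rl
            n_err = rng.binomial(nb, err) if err > 0 else 0
            err_map: dict[int, list[int]] = {}
            if n_err:
                for flat in rng.integers(0, nb, size=n_err):
                    err_map.setdefault(int(flat) // rl, []).append(int(flat) % rl)
            for i in range(len(starts)):
                a1 = int(starts[i])
                a2 = a1 + int(ins[i]) - rl
                strand = "+" if strands[i] else "-"
                r1, r2 = emit_pair(hap, contig, a1, a2, strand, "f")
                for ridx, r in ((2 * i, r1), (2 * i + 1, r2)):
                    if ridx in err_map:
                        ba = bytearray(r.seq.encode())
                        for off in err_map[ridx]:
                            cur = ba[off]
                            repl = cur
                            while repl == cur:
                                repl = base_bytes[int(rng.integers(0, 4))]
                            ba[off] = repl
                        r.seq = ba.decode()

    # fusion-spanning fragments
    for fus in config.fusions:
        if fus.somatic and sample == "germline":
            continue
        cell_frac = p if (fus.somatic and sample == "tumor") else 1.0
        w = cell_frac * 0.5  # one junction copy per carrying cell
        span = max(0.0, config.insert_mean - 2 * rl)
        n = rng.poisson(rate * w * span)
        ref_a = sim.reference[fus.contig_a]
        ref_b = sim.reference[fus.contig_b]
        for _ in range(n):
            ins = max(2 * rl + 2, int(round(rng.normal(config.insert_mean, config.insert_sd))))
            u = int(rng.integers(rl + 1, ins - rl))  # junction offset inside the fragment
            a1 = fus.pos_a - u
            a2 = fus.pos_b + (ins - u) - rl
            if a1 < 0 or a2 + rl > len(ref_b) or a1 + rl > len(ref_a) or fus.pos_b > a2:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            emit_pair((ref_a, ref_b), (fus.contig_a, fus.contig_b), a1, a2, strand, "x")

    # chimeric library artifacts: pairs whose mates land at random loci
    if config.chimera_rate > 0:
        contigs = [c.name for c in config.genome]
        lens = np.array([c.length for c in config.genome], dtype=float)
        n = rng.poisson(config.chimera_rate * rate * total_bp)
        for _ in range(n):
            ia, ib = rng.choice(len(contigs), size=2, p=lens / lens.sum())
            pa = int(rng.integers(0, lens[ia] - rl))
            pb = int(rng.integers(0, lens[ib] - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            emit_pair(
                (sim.reference[contigs[ia]], sim.reference[contigs[ib]]),
                (contigs[ia], contigs[ib]),
                pa, pb, strand, "c",
            )

    # PCR-duplicate artifacts: re-emit a sampled subset at identical placements
    if config.duplicate_rate > 0:
        n_dup = rng.binomial(len(reads) // 2, config.duplicate_rate)
        pairs = {r.name for r in reads}
        chosen = rng.choice(sorted(pairs), size=min(n_dup, len(pairs)), replace=False)
        chosen = set(chosen)
        clones = []
        for r in reads:
            if r.name in chosen:
                clone = dataclasses.replace(r, name=r.name + "_dup")
                clones.append(clone)
        reads.extend(clones)

    reads.sort(key=lambda r: (r.contig, r.start, r.name))
    return reads


# ---------------------------------------------------------------------------
# depth-level mode


def simulate_bin_depths(
    config: SimulationConfig, bin_size: int = 100
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson per-bin fragment depths for germline and tumor.

    Germline bins are Poisson(lambda_g); tumor bins are
    Poisson(lambda_t * (purity*CN/2 + (1-purity))) with CN the planted tumor
    copy number covering the bin start.  Returns (germline, tumor) tracks.
    """
    config.validate()
    lam_g = config.mean_coverage_germline
    lam_t = config.mean_coverage_tumor
    if lam_g <= 0 or lam_t <= 0:
        raise ValueError("coverage rates must be positive")
    rng = _rng(config.seed, _STAGE_DEPTHS)
    sim_stub = SimulatedGenomes(config, {}, {}, {}, TruthSet())
    g_depths: dict[str, np.ndarray] = {}
    t_depths: dict[str, np.ndarray] = {}
    for c in config.genome:
        nbins = (c.length + bin_size - 1) // bin_size
        g_depths[c.name] = rng.poisson(lam_g, size=nbins).astype(float)
        cn = np.full(nbins, 2.0)
        for s, e, v in sim_stub.cn_intervals(c.name):
            b0 = s // bin_size
            b1 = (e + bin_size - 1) // bin_size
            cn[b0:b1] = v
        mix = config.purity * cn / 2.0 + (1.0 - config.purity)
        t_depths[c.name] = rng.poisson(lam_t * mix).astype(float)
    g = CoverageTrack(bin_size=bin_size, kind="fragment", depths=g_depths)
    t = CoverageTrack(bin_size=bin_size, kind="fragment", depths=t_depths)
    return g, t
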