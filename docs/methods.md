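# Methods

This note documents the models and procedures implemented in `matewalker`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Study design emulated

The package targets a specific sequencing design: a matched tumor/germline
pair from one patient, sequenced as long-insert mate-pair libraries
(~1.5 kb fragments, 50 bp + 50 bp reads) to ~37× (tumor) and ~40×
(germline) base coverage, with the tumor specimen containing ~60%
tumor cells. Two consequences of this design drive everything downstream:

* **Allele dilution.** A clonal heterozygous somatic SNV in a copy-neutral
  region has expected tumor allele fraction `purity/2 = 0.30`, not 0.50.
  A homozygous deletion does not reach zero coverage — the residual
  normal-cell DNA keeps it at `1 − purity = 0.40` relative depth
  (log2 = −1.32); a single-copy loss sits at `purity/2 + (1−purity) = 0.70`
  (log2 = −0.515).
* **Clonal coverage.** Counting each 1.5 kb fragment span rather than its
  100 sequenced bases multiplies effective structural-variant coverage by
  insert/(2×read length) = 15, which is why discordant-pair evidence is
  abundant even at 37×.

## Synthetic data generator

`simulate` produces paired tumor/germline data with a fully known truth set
at two fidelity levels.

**Read level** (`simulate_mate_pairs`, for genomes up to a few Mb): diploid
germline haplotypes carry SNPs sampled at a configurable rate or exact
count, transitions with probability `titv/(titv+1)` (default 2.12/3.12),
heterozygous with probability 2/3; indels are planted explicitly. Tumor
haplotypes inherit the germline variants and add somatic SNVs/indels.
Fragments are drawn per haplotype at a rate proportional to the local
haplotype multiplicity, so a tumor library is a purity-weighted mixture of
tumor and residual normal cells and planted copy-number states scale read
depth as `purity·CN/2 + (1−purity)`. Inserts are Normal(1500, 150)
truncated below at twice the read length; both mates of a pair share a
strand (the concordant orientation for this library chemistry). Reads
overlapping planted indels receive correct gapped CIGARs derived from the
haplotype-to-reference coordinate map. Base qualities are a point mass at
Q30 with per-base substitution errors at the implied rate 10^(−Q/10); both
are configurable. Fusion breakpoints emit junction-spanning fragments whose
mates map to the two partner contigs; an optional `chimera_rate` adds
random-mate library artifacts (default 0; 2×10⁻⁴ in the structural-variant
suites) so discordant-read backgrounds are non-trivial. An optional
`duplicate_rate` re-emits fragments at identical placements to exercise
duplicate marking. Everything is deterministic given the config seed, with
independent substreams per stage.

**Depth level** (`simulate_bin_depths`, for tens-of-Mb copy-number
experiments): germline bins are Poisson(λ_g), tumor bins
Poisson(λ_t · (purity·CN/2 + 1−purity)) per 100 bp bin.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: alignment and mapping error (reads are placed
where they were drawn), ligation-sequencing color space, GC and mappability
bias, quality-score heterogeneity, subclonal tumor populations, and
germline structural variation beyond small indels and planted fusions. The
null false-positive suites in particular measure the callers' behaviour
under sequencing error and sampling noise only, not under mismapping, which
dominates false positives in real genomes.

## Duplicate marking and pileups

Reads sharing all of (contig, start, strand, mate contig, mate start) are
treated as one PCR amplification family; the member with the highest total
base quality survives (ties keep input order) and the rest are excluded
from every downstream count. Fragment-level keying (both mate placements)
is used because long-insert libraries make single-end coordinate collisions
common at high depth. Stranded pileups record one (base, quality) per
covering non-duplicate read per strand; reads whose CIGAR deletes a site
contribute nothing there. Binned coverage is computed in two kinds:
"base" (mean aligned-base depth per 100 bp bin) and "fragment" (count of
mate-pair outer spans overlapping the bin, once per pair — the clonal
convention; pairs split across contigs and reads with unmapped mates count
toward base coverage only).

## Stranded KS genotyper

At a site with reference allele R and alternative A (the non-reference base
with the greatest quality-weighted support, ties alphabetical), each strand's
pileup is compared to expected pileups that keep the observed positions and
qualities but fix the bases: all-R, all-A, and for diploids a heterozygous
pileup with the reference base at the first ⌈n/2⌉ positions. Each pileup is
reduced to a normalized mass over the ordered categories (R, A, other),
weighting every observation by its probability of being correct,
`w = 1 − 10^(−q/10)`; the distance between observed and expected is the
maximum absolute difference of the cumulative masses — a two-sample
KS statistic on the category marginal, degrading to the classical one under
equal weights. The strand's genotype is the argmin (ties resolve toward
hom_ref); in consensus mode a genotype is emitted only when both strands
agree, and a site is a variant only when a non-reference genotype is seen
on both strands. Strands below `min_strand_depth` (default 4) no-call.
The weighting function is injectable; quality-probability weighting is the
default because it uses both the base identity and the confidence while
keeping the statistic in [0, 1].

With the half/half heterozygous expectation the argmin boundary between
hom_ref and het lies at per-strand alt fraction 0.25. For impure tumor
specimens the heterozygous expectation can be diluted
(`het_alt_fraction = purity/2`), moving the boundary to purity/4; the
somatic pipeline applies this on the tumor side when purity is supplied and
always genotypes the germline against the pure-diploid expectation.

## Proportion-test somatic caller and consensus

For each candidate site the caller computes, per strand, the pooled
two-proportion z statistic between tumor and germline alt counts, and
reports the minimum of the forward and reverse statistics, so evidence must
exist independently on both strands. Sites with germline alternate
evidence above a count or fraction ceiling are filtered as probable
under-sampled germline polymorphisms. Two parameter tiers are evaluated:

| tier | min z (per-strand min) | tumor alt/strand ≥ | depth/strand ≥ | germline alt ≤ | germline frac ≤ |
|---|---|---|---|---|---|
| strict | 3.09 (p ≈ 0.001) | 3 | 8 | 1 | 0.02 |
| lenient | 1.645 (p ≈ 0.05) | 2 | 4 | 2 | 0.05 |

The final call list is the intersection of genotyper-somatic sites
(variant in tumor, hom_ref in germline) with strict-tier passes, plus
lenient-tier intersections that survive two deterministic post-filters:
tumor strand allele fractions within 2-fold of each other, and distance
> 5 bp from any indel candidate. The post-filters replace the original
workflow's manual review of the lenient set with reproducible rules.

**Power at the design point.** The z thresholds were set from a power
analysis at the study design (before any end-to-end runs): with ~18× per
tumor strand, ~20× per germline strand and allele fraction 0.30, the
per-strand z has mean ≈ 2.6, so demanding min-strand z ≥ 3 would reject
most true clonal somatic SNVs (P ≈ 0.05) and z ≥ 5 essentially all; the
standard 0.001/0.05 one-sided quantiles give the strict tier high purity
and the lenient tier high power. Detection is nonetheless capped well below
1 by the both-strand requirements themselves: Monte Carlo at depth
Poisson(37) gives P(both strand alt fractions > 0.25) ≈ 0.41 for the
pure-diploid genotyper boundary, ≈ 0.84 for the purity-aware boundary, and
≈ 0.95 for the ≥2-alt-reads-per-strand floor alone. The dual-algorithm
intersection therefore recalls roughly 70% of clonal het somatic SNVs at
37×/purity 0.6 with precision ≈ 1; recovering the remainder requires
deeper sequencing, not different thresholds. The acceptance suite states an
aspirational 0.95 recall bound at this operating point and reports the
measured value honestly rather than relaxing the conditions.

## Somatic indels

Step one removes tumor reads whose absolute insert size lies outside the
open interval (500, 5000) bp — mate-pair fragments far from the 1.5 kb
target are circularization artifacts — then groups identical CIGAR
insertion/deletion events by (contig, start, type, sequence). A candidate
needs ≥ 3 supporting reads and support/covering ≥ 0.1. Step two inspects
the germline over a window from 5 bases upstream of the candidate start to
5 bases downstream of its end: the candidate is somatic only if no germline
read carries any indel event overlapping that window; windows with fewer
than 8 overlapping germline reads are "undetermined", never somatic.

## Copy number

Coverage is normalized per 100 bp bin as
`log2((depth + 0.5) / modal depth)` (the 0.5 pseudocount keeps homozygous
deletions finite); bins whose germline depth is outside 0.1–10× the
germline mode are masked as repeat-like. The germline mode is the
half-sample mode of its depth histogram. The tumor's copy-neutral level is
*not* taken from its own histogram: when a large genome fraction is
aberrant the tumor histogram is multi-modal and any single-sample mode can
anchor on an aberrant peak. Instead `paired_modal` locates the mode of the
windowed tumor:germline log2 ratio — copy-neutral windows are the largest
single ratio population even when aberrant states jointly outweigh them —
and scales the germline mode by it.

The tumor−germline normalized difference is averaged over a 2 kb window
sliding by one bin (window length configurable; 2 kb and 4 kb are both
reasonable readings of the original description), emitted as missing when
fewer than half the window's bins are usable. Windows with |value| > 0.75
are flagged; same-sign runs (tolerating 2 missing windows) merge into
segments, overlapping spans are reconciled (same-direction merge,
opposite-direction split at the midpoint) so output segments are disjoint
and sorted, and each segment is classified by its mean over usable member
bins with thresholds derived from the 60%-purity mixture expectations:
≤ −1.0 homozygous loss, (−1.0, −0.4] hemizygous loss, ≥ 0.32 gain,
≥ 1.0 amplified. Note the deliberate asymmetry between flagging and
classification: at 60% purity a single-copy loss (expected −0.515) does not
exceed the 0.75 departure, so broad hemizygous events are recovered by
lowering the flag threshold (e.g. `departure=0.4`) while the
classification thresholds stay fixed; whole-chromosome events are reported
separately as per-chromosome median differences (`chromosome_summary`),
which a windowed departure rule cannot flag at this purity.
`exon_moderate_deletions` applies the same normalization and departure rule
to base-kind ("sequence") coverage restricted to coding exons, catching
deletions shorter than the genome-wide window resolves.

## Translocations

The genome is walked in non-overlapping windows with step equal to the
insert size (1.5 kb default). Per window the caller counts aligned reads
and anomalous reads — mates on a different contig — and votes the
"highest hit" partner contig (ties by name order). The per-window
proportion of highest-hit reads over total aligned reads is treated as
approximately normal across each chromosome; windows strictly above
mean + 3 SD are candidates. Candidate windows need ≥ 5 supporting pairs;
adjacent candidates with the same partner merge; region A is the span of
the hit reads and region B the span of their mates (mate clusters spanning
> 1 Mb split at their largest gaps). Every event is seen from both partner
chromosomes, so reciprocal detections are folded into one canonical call.
Tumor and germline are called separately with identical parameters and a
tumor call is somatic only if no germline call with the same contig pair
overlaps both of its regions by ≥ 1 bp; `somatic_subtract(X, X)` is empty
by construction. Output is a GFF3 file of paired lines sharing an event
identifier, round-trippable by the package's own reader. Intrachromosomal
rearrangements reuse the walker with "anomalous" redefined as
orientation-violating (mates on opposite strands, the concordant state
being same-direction) or |insert| > 3× the library mean, and are emitted
as a separate call class.

## Reporting and validation arithmetic

Variant-class accounting distinguishes missense, nonsense (consequence
ending in a stop, e.g. R177X) and frameshift indels (deletion-interval
positions); coding point mutations are missense + nonsense, and the
damaging fraction is SIFT-"Damaging" calls over all missense records,
rounded to the nearest whole percent. Ti/Tv is transitions (A↔G, C↔T)
over transversions, undefined without a transversion. Coverage summaries
report fold coverage (bases/genome length) and read-pair coverage
(pairs × insert / genome length). qPCR fold changes follow the ddCt method
with assumed amplification efficiency 2: per sample
ΔCt = mean Ct(gene) − mean Ct(reference), fold = 2^(−ΔΔCt); in a 60%-pure
specimen the expected fold is 0.4 for a homozygous and 0.7 for a
hemizygous deletion. `circos_summary` flattens all caller outputs into one
tidy table (rendering is out of scope).

## Problem sizes in the test and acceptance suites

All suites run on synthetic data sized for a desk machine: the shared SNV
suite uses one 300 kb contig at 37×/40×; the somatic-SNV operating point
600 kb with 500 planted sites; the fusion suite four 200 kb contigs with
two somatic and one shared fusion; the null (variant-free) suite twenty
seeds of four 50 kb contigs feeding both the SNV and SV callers; the
copy-number acceptance run a 40 Mb contig at depth level with a 20 Mb
single-copy loss nesting a 2 Mb homozygous interval. The Ti/Tv calibration
draws 200,000 germline SNPs on a 2 Mb contig. Sampling-noise tolerances in
tests follow binomial/Poisson standard deviations at these sizes.

## Known limitations

* Recall of clonal somatic SNVs at 37× and 60% purity is bounded near 0.7
  by the both-strand dual-algorithm design (power analysis above); the
  pipeline favors precision.
* Copy-number states above 4 are not modeled by the simulator, and the
  caller performs no GC/mappability correction or purity/ploidy inference.
* The translocation caller reports breakpoint *regions* at insert-length
  resolution; base-pair breakpoints would need split-read or assembly
  evidence that 50 bp mate-pair data cannot provide.
* Multi-allelic somatic sites are folded into the strongest alternative
  allele; indels longer than ~10 bp are untested territory for the CIGAR
  grouping detector.
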