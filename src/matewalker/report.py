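"""Summary statistics, validation arithmetic and tabular reporting.

Covers the accounting done on top of the callers: variant-class counts and
damaging fractions over an annotated coding-variant table, the
transition:transversion ratio, genome and read-pair ("clonal") coverage
calculators for long-insert libraries, qPCR ddCt relative-quantification
fold changes, and a flat tabular summary of all caller outputs suitable for
a Circos-style overview plot.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_POINT_RE = re.compile(r"^Chr([\w]+):(\d+)([ACGT])/([ACGT])$")
_DEL_RE = re.compile(r"^Chr([\w]+):(\d+)-(\d+)del$")


@dataclass(frozen=True)
class AnnotatedVariantRecord:
    contig: str
    start: int  # 1-based as annotated
    end: int
    ref: str | None
    alt: str | None
    gene: str
    codon_change: str
    consequence: str
    variant_class: str  # missense | nonsense | frameshift_indel
    sift: str  # Damaging | Tolerated | Not scored | none


def _classify_row(position: str, consequence: str, row_id) -> tuple:
    m = _POINT_RE.match(position)
    if m:
        contig, pos, ref, alt = m.groups()
        cls = "nonsense" if consequence.endswith("X") else "missense"
        return contig, int(pos), int(pos), ref, alt, cls
    m = _DEL_RE.match(position)
    if m:
        contig, s, e = m.groups()
        return contig, int(s), int(e), None, None, "frameshift_indel"
    raise ValueError(f"unparsable variant position in row {row_id}: {position!r}")


def load_variant_table(path_or_buffer) -> list[AnnotatedVariantRecord]:
    """Parse an annotated coding-variant TSV (position, gene, codon change,
    consequence, SIFT prediction) into typed records."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str).fillna("-")
    records = []
    for i, row in df.iterrows():
        contig, s, e, ref, alt, cls = _classify_row(row["position"], row["consequence"], i)
        sift = row["sift"]
        if sift not in ("Damaging", "Tolerated", "Not scored", "-"):
            raise ValueError(f"unknown SIFT label {sift!r} in row {i}")
        records.append(
            AnnotatedVariantRecord(
                contig, s, e, ref, alt, row["gene"], row["codon_change"],
                row["consequence"], cls, "none" if sift == "-" else sift,
            )
        )
    return records


def packaged_coding_table() -> list[AnnotatedVariantRecord]:
    """The packaged somatic coding point-mutation and small-indel table."""
    ref = importlib.resources.files("matewalker.data") / "coding_somatic_variants.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_variant_table(path)


def class_counts(records: list[AnnotatedVariantRecord]) -> dict:
    """Variant-class accounting plus the SIFT-damaging fraction.

    Coding point mutations are missense plus nonsense; the damaging fraction
    is Damaging calls over all missense mutations, rounded to a whole
    percent (None when there are no missense records).
    """
    counts = {"missense": 0, "nonsense": 0, "frameshift_indel": 0}
    damaging = 0
    for r in records:
        if r.variant_class not in counts:
            raise ValueError(f"unknown variant class {r.variant_class!r} for {r.gene}")
        counts[r.variant_class] += 1
        if r.variant_class == "missense" and r.sift == "Damaging":
            damaging += 1
    counts["coding_point_mutations"] = counts["missense"] + counts["nonsense"]
    counts["damaging"] = damaging
    counts["damaging_percent"] = (
        round(100.0 * damaging / counts["missense"]) if counts["missense"] else None
    )
    return counts


def titv(variants) -> float:
    """Transition:transversion ratio over (ref, alt) substitution pairs.

    Accepts any iterable of objects with ``ref``/``alt`` attributes or
    (ref, alt) tuples.  Undefined without at least one transversion
    (raises ValueError, callers report "undefined").
    """
    ti = tv = 0
    for v in variants:
        pair = (v.ref, v.alt) if hasattr(v, "ref") else (v[0], v[1])
        if pair[0] == pair[1] or any(b not in "ACGT" for b in pair):
            continue
        if pair in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError("Ti/Tv undefined: no transversions observed")
    return ti / tv


def coverage_summary(
    n_unique_bases: float, n_tag_pairs: float, insert: float, genome_length: float
) -> dict:
    """Fold coverage and read-pair ("clonal") coverage of one library.

    Fold coverage is uniquely mapping bases over genome length; read-pair
    coverage multiplies the pair count by the insert length over the genome
    length, crediting each pair with its whole fragment span.  Both are
    returned unrounded and floored.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    fold = n_unique_bases / genome_length
    rp = n_tag_pairs * insert / genome_length
    return {
        "fold_coverage": fold,
        "fold_coverage_floor": int(np.floor(fold)),
        "read_pair_coverage": rp,
        "read_pair_coverage_floor": int(np.floor(rp)),
    }


# ---------------------------------------------------------------------------
# qPCR ddCt


def read_qpcr_plate(path_or_buffer) -> pd.DataFrame:
    """Read a Ct plate CSV with columns gene, sample, ct (one row per replicate)."""
    df = pd.read_csv(path_or_buffer)
    required = {"gene", "sample", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR plate needs columns {sorted(required)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def ddct_fold_change(plate: pd.DataFrame, gene: str, reference_gene: str) -> float:
    """Tumor-versus-normal fold change by the ddCt method.

    Per sample, dCt = mean Ct(gene) - mean Ct(reference); ddCt is
    dCt(tumor) - dCt(normal); the fold change is 2^(-ddCt), assuming ideal
    amplification efficiency.  For a homozygous deletion in a 60%-pure
    specimen the expected fold is 0.4 (the residual normal-cell DNA).
    """
    dct = {}
    for sample in ("tumor", "normal"):
        sub = plate[plate["sample"] == sample]
        g = sub[sub["gene"] == gene]["ct"]
        r = sub[sub["gene"] == reference_gene]["ct"]
        if g.empty or r.empty:
            raise ValueError(f"missing {gene if g.empty else reference_gene} Ct values for sample {sample}")
        dct[sample] = g.mean() - r.mean()
    ddct = dct["tumor"] - dct["normal"]
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# flat summary of all caller outputs


def circos_summary(
    coding_variants: list[AnnotatedVariantRecord] | None = None,
    cnv_segments=None,
    translocations=None,
) -> pd.DataFrame:
    """One tidy table of all somatic events for plotting or review.

    Tracks: coding point mutations, coding indels, CNV segments with state,
    translocation region pairs.  Row counts conserve the caller outputs.
    """
    rows = []
    for r in coding_variants or []:
        track = "coding_indel" if r.variant_class == "frameshift_indel" else "coding_point"
        rows.append((track, r.contig, r.start, r.end, r.gene, r.variant_class))
    for s in cnv_segments or []:
        rows.append(("cnv", s.contig, s.start, s.end, f"{s.mean_diff:.3f}", s.state))
    for t in translocations or []:
        (ca, sa, ea), (cb, sb, eb) = t.regions()
        label = f"{cb}:{sb}-{eb}"
        rows.append(("translocation", ca, sa, ea, label, "somatic" if t.somatic else "unfiltered"))
    return pd.DataFrame(rows, columns=["track", "contig", "start", "end", "label", "detail"])
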