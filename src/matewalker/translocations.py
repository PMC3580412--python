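"""Discordant mate-pair translocation detection with germline subtraction.

The genome is walked in non-overlapping windows with step equal to the
library insert size.  In every window the anomalous reads — those whose
mate aligns to a different chromosome — are counted, and the "highest hit"
is the partner chromosome receiving most of the discordant mates.  The
per-window proportion of highest-hit discordant reads over total aligned
reads is assumed approximately normal across each chromosome; windows above
mean + 3 SD are translocation candidates.  The breakpoint regions are the
spans of the hit reads and of their mates; tumor and germline are called
separately and overlapping calls are subtracted to leave somatic events,
reported as a paired-line GFF3 file.

Intrachromosomal rearrangements reuse the same walker with "anomalous"
redefined as orientation-violating pairs (mates on opposite strands, this
chemistry's concordant state being same-direction) or pairs whose absolute
insert exceeds three times the library mean; they are emitted as a separate
call class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .reads import AlignedRead


@dataclass
class DiscordantWindow:
    contig: str
    start: int
    length: int
    total: int
    discordant: int
    highest_hit: str | None
    hit_count: int
    hit_reads: list[AlignedRead] = field(default_factory=list)

    @property
    def proportion(self) -> float:
        return self.hit_count / self.total if self.total else 0.0


@dataclass
class TranslocationCall:
    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    n_pairs: int
    somatic: bool = False
    call_class: str = "interchromosomal"

    def regions(self):
        return (self.contig_a, self.start_a, self.end_a), (
            self.contig_b, self.start_b, self.end_b,
        )


def _is_interchrom_anomalous(r: AlignedRead) -> bool:
    return r.mate_contig is not None and r.mate_contig != r.contig


def _intrachrom_anomalous(insert_mean: float):
    def pred(r: AlignedRead) -> bool:
        if r.mate_contig is None or r.mate_contig != r.contig:
            return False
        if r.mate_strand is not None and r.mate_strand != r.strand:
            return True  # orientation violation: concordant pairs are same-direction
        return abs(r.insert) > 3 * insert_mean

    return pred


def scan_windows(
    reads: list[AlignedRead],
    contig_lengths: dict[str, int],
    step: int = 1500,
    anomaly: str = "interchromosomal",
    insert_mean: float | None = None,
) -> dict[str, list[DiscordantWindow]]:
    """Count anomalous reads in non-overlapping windows tiling each contig.

    ``step`` is both the walker step and the window length (set it to the
    library insert size).  Highest-hit ties break by contig name order.
    Duplicate-flagged reads are ignored.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if anomaly == "interchromosomal":
        pred = _is_interchrom_anomalous
    elif anomaly == "intrachromosomal":
        pred = _intrachrom_anomalous(insert_mean if insert_mean is not None else float(step))
    else:
        raise ValueError(f"unknown anomaly class {anomaly!r}")
    windows: dict[str, list[DiscordantWindow]] = {}
    for contig, L in contig_lengths.items():
        n = (L + step - 1) // step
        windows[contig] = [
            DiscordantWindow(contig, i * step, step, 0, 0, None, 0) for i in range(n)
        ]
    anomalous: dict[tuple[str, int], list[AlignedRead]] = {}
    for r in reads:
        if r.is_duplicate or r.contig not in windows:
            continue
        wi = r.start // step
        w = windows[r.contig][wi]
        w.total += 1
        if pred(r):
            w.discordant += 1
            anomalous.setdefault((r.contig, wi), []).append(r)
    for (contig, wi), rs in anomalous.items():
        w = windows[contig][wi]
        if anomaly == "interchromosomal":
            hits = Counter(r.mate_contig for r in rs)
            # most common; ties by contig name order
            best = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            w.highest_hit = best
            w.hit_reads = [r for r in rs if r.mate_contig == best]
        else:
            w.highest_hit = contig
            w.hit_reads = rs
        w.hit_count = len(w.hit_reads)
    return windows


def outlier_cutoff(windows: list[DiscordantWindow], min_windows: int = 30) -> float:
    """mean + 3 SD of hit proportions across one chromosome's windows.

    With zero variance the cutoff is the mean, so only windows strictly
    above the (flat) background can be candidates.
    """
    if len(windows) < min_windows:
        raise ValueError(f"need at least {min_windows} windows, got {len(windows)}")
    props = np.array([w.proportion for w in windows])
    return float(props.mean() + 3.0 * props.std())


def candidate_windows(
    windows: dict[str, list[DiscordantWindow]], min_windows: int = 30
) -> list[DiscordantWindow]:
    out = []
    for contig in sorted(windows):
        ws = windows[contig]
        if len(ws) < min_windows:
            continue
        cut = outlier_cutoff(ws, min_windows)
        out.extend(w for w in ws if w.proportion > cut)
    return out


def _split_by_span(reads: list[AlignedRead], max_span: int):
    """Split mate clusters whose partner span exceeds max_span at the largest gaps."""
    reads = sorted(reads, key=lambda r: r.mate_start)
    clusters = [reads]
    done = []
    while clusters:
        c = clusters.pop()
        span = c[-1].mate_start - c[0].mate_start
        if span <= max_span or len(c) == 1:
            done.append(c)
            continue
        gaps = [c[i + 1].mate_start - c[i].mate_start for i in range(len(c) - 1)]
        k = int(np.argmax(gaps))
        clusters.append(c[: k + 1])
        clusters.append(c[k + 1 :])
    return done


def call_regions(
    candidates: list[DiscordantWindow],
    min_pairs: int = 5,
    max_span: int = 1_000_000,
    read_len: int = 50,
    call_class: str = "interchromosomal",
) -> list[TranslocationCall]:
    """Turn candidate windows into breakpoint-region calls.

    Adjacent candidate windows on the same contig with the same partner
    contig are merged; region A is the span of the hit reads, region B the
    span of their mates.  Mate clusters spanning more than ``max_span`` are
    split into separate calls; each call needs ``min_pairs`` supporting
    reads.
    """
    merged: list[list[DiscordantWindow]] = []
    for w in sorted(candidates, key=lambda w: (w.contig, w.start)):
        if (
            merged
            and merged[-1][-1].contig == w.contig
            and merged[-1][-1].highest_hit == w.highest_hit
            and w.start - (merged[-1][-1].start + merged[-1][-1].length) <= 0
        ):
            merged[-1].append(w)
        else:
            merged.append([w])
    calls: list[TranslocationCall] = []
    for group in merged:
        reads = [r for w in group for r in w.hit_reads]
        if not reads:
            continue
        partner = group[0].highest_hit
        for cluster in _split_by_span(reads, max_span):
            if len(cluster) < min_pairs:
                continue
            sa = min(r.start for r in cluster)
            ea = max(r.end for r in cluster)
            sb = min(r.mate_start for r in cluster)
            eb = max(r.mate_start for r in cluster) + read_len
            call = TranslocationCall(
                group[0].contig, sa, ea, partner, sb, eb, len(cluster),
                call_class=call_class,
            )
            if call.contig_b < call.contig_a:  # canonical orientation
                call = TranslocationCall(
                    call.contig_b, call.start_b, call.end_b,
                    call.contig_a, call.start_a, call.end_a,
                    call.n_pairs, call_class=call_class,
                )
            calls.append(call)
    calls.sort(key=lambda c: (c.contig_a, c.start_a, c.contig_b, c.start_b))
    # the walker sees every event from both partner chromosomes; fold the
    # reciprocal detections into one call per event
    deduped: list[TranslocationCall] = []
    for c in calls:
        for k in deduped:
            if (
                (k.contig_a, k.contig_b) == (c.contig_a, c.contig_b)
                and _regions_overlap(k, c)
            ):
                k.start_a = min(k.start_a, c.start_a)
                k.end_a = max(k.end_a, c.end_a)
                k.start_b = min(k.start_b, c.start_b)
                k.end_b = max(k.end_b, c.end_b)
                k.n_pairs = max(k.n_pairs, c.n_pairs)
                break
        else:
            deduped.append(c)
    return deduped


def _regions_overlap(a: TranslocationCall, b: TranslocationCall) -> bool:
    if {a.contig_a, a.contig_b} != {b.contig_a, b.contig_b}:
        return False
    # orient b to match a's contig assignment
    if a.contig_a == b.contig_a:
        pairs = [((a.start_a, a.end_a), (b.start_a, b.end_a)),
                 ((a.start_b, a.end_b), (b.start_b, b.end_b))]
    else:
        pairs = [((a.start_a, a.end_a), (b.start_b, b.end_b)),
                 ((a.start_b, a.end_b), (b.start_a, b.end_a))]
    return all(x0 < y1 and y0 < x1 for (x0, x1), (y0, y1) in pairs)


def somatic_subtract(
    tumor_calls: list[TranslocationCall], germline_calls: list[TranslocationCall]
) -> list[TranslocationCall]:
    """Tumor calls with no reciprocally overlapping germline counterpart.

    A tumor call is eliminated when a germline call with the same contig
    pair overlaps both of its regions by at least one base; survivors are
    returned flagged somatic.
    """
    out = []
    for t in tumor_calls:
        if any(_regions_overlap(t, g) for g in germline_calls):
            continue
        t.somatic = True
        out.append(t)
    return out


def call_translocations(
    tumor_reads: list[AlignedRead],
    germline_reads: list[AlignedRead],
    contig_lengths: dict[str, int],
    step: int = 1500,
    min_pairs: int = 5,
    max_span: int = 1_000_000,
    read_len: int = 50,
    min_windows: int = 30,
) -> list[TranslocationCall]:
    """End-to-end somatic interchromosomal calling on matched samples."""
    calls = {}
    for label, reads in (("tumor", tumor_reads), ("germline", germline_reads)):
        wins = scan_windows(reads, contig_lengths, step)
        cands = candidate_windows(wins, min_windows)
        calls[label] = call_regions(cands, min_pairs, max_span, read_len)
    return somatic_subtract(calls["tumor"], calls["germline"])


# ---------------------------------------------------------------------------
# paired-line GFF output


def write_paired_gff(calls: list[TranslocationCall], path) -> None:
    """Two GFF3 lines per call sharing an event id in source and attributes.

    Coordinates are 1-based inclusive per GFF; the source column carries the
    event identifier that pairs the two lines.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls):
            ev = f"TL{i:04d}"
            status = "somatic" if c.somatic else "unfiltered"
            for regid, (contig, s, e), mate in (
                ("A", (c.contig_a, c.start_a, c.end_a), c.contig_b),
                ("B", (c.contig_b, c.start_b, c.end_b), c.contig_a),
            ):
                attrs = (
                    f"ID={ev}.{regid};event={ev};partner={mate};pairs={c.n_pairs};"
                    f"status={status};class={c.call_class}"
                )
                fh.write(
                    f"{contig}\t{ev}\ttranslocation_region\t{s + 1}\t{e}\t"
                    f"{c.n_pairs}\t.\t.\t{attrs}\n"
                )


def read_paired_gff(path) -> list[TranslocationCall]:
    """Reconstruct calls from a file written by :func:`write_paired_gff`."""
    events: dict[str, dict[str, tuple]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, ev, _type, s, e, score, _strand, _frame, attrs = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in attrs.split(";") if item)
            regid = kv["ID"].rsplit(".", 1)[1]
            events.setdefault(ev, {})[regid] = (contig, int(s) - 1, int(e))
            meta[ev] = {
                "pairs": int(kv["pairs"]),
                "somatic": kv["status"] == "somatic",
                "class": kv.get("class", "interchromosomal"),
            }
    calls = []
    for ev in sorted(events):
        a = events[ev]["A"]
        b = events[ev]["B"]
        m = meta[ev]
        calls.append(
            TranslocationCall(a[0], a[1], a[2], b[0], b[1], b[2], m["pairs"],
                              somatic=m["somatic"], call_class=m["class"])
        )
    return calls
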