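"""Two-step somatic indel calling.

Step one restricts the tumor library to well-formed pairs — reads whose
absolute insert size lies strictly inside (500, 5000) bp — and groups
identical CIGAR insertion/deletion events into candidates.  Step two checks
each candidate against the germline sample over a window extending five
bases upstream of the start and five bases downstream of the end: the
candidate is somatic only when no germline read carries any indel event
overlapping that window.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .reads import AlignedRead

log = logging.getLogger(__name__)


@dataclass
class IndelCandidate:
    """A grouped small insertion or deletion observed in tumor reads.

    Coordinates are 0-based half-open; an insertion has start == end and a
    nonempty inserted sequence.
    """

    contig: str
    start: int
    end: int
    kind: str  # "ins" | "del"
    sequence: str
    support: int
    covering: int
    somatic: bool = False
    status: str = "untested"  # untested | somatic | germline | undetermined
    germline_events: int = 0

    def __post_init__(self) -> None:
        if self.kind == "del" and self.end <= self.start:
            raise ValueError("deletion needs end > start")
        if self.kind == "ins" and not self.sequence:
            raise ValueError("insertion needs a nonempty sequence")
        if self.support > self.covering:
            raise ValueError("supporting reads exceed covering reads")


def filter_by_insert(
    reads: list[AlignedRead], low: int = 500, high: int = 5000
) -> list[AlignedRead]:
    """Keep reads with low < |insert| < high (open interval on both ends).

    Reads with an unset insert (mates on different contigs store 0) are
    removed along with out-of-range ones; the removed count is logged.
    Idempotent.
    """
    if low >= high:
        raise ValueError("insert filter needs low < high")
    kept = [r for r in reads if low < abs(r.insert) < high]
    log.info("insert-size filter removed %d of %d reads", len(reads) - len(kept), len(reads))
    return kept


def _read_indel_events(r: AlignedRead) -> list[tuple[int, int, str, str]]:
    """(start, end, kind, sequence) for each I/D CIGAR op of one read."""
    events = []
    ref = r.start
    qi = 0
    for op, n in r.cigar_ops():
        if op in "M=X":
            ref += n
            qi += n
        elif op == "I":
            events.append((ref, ref, "ins", r.seq[qi : qi + n]))
            qi += n
        elif op in "DN":
            events.append((ref, ref + n, "del", ""))
            ref += n
        elif op == "S":
            qi += n
    return events


def detect_candidates(
    tumor_reads: list[AlignedRead],
    min_support: int = 3,
    min_fraction: float = 0.1,
) -> list[IndelCandidate]:
    """Group identical indel CIGAR events into candidates.

    Events sharing (contig, start, type, sequence/length) are one candidate;
    a candidate is emitted when its supporting-read count reaches
    ``min_support`` and support divided by reads covering the event span is
    at least ``min_fraction``.  Malformed CIGARs are skipped with a log line.
    """
    groups: dict[tuple, int] = {}
    spans: dict[str, tuple[list[int], list[int]]] = {}
    for r in tumor_reads:
        if r.is_duplicate:
            continue
        try:
            events = _read_indel_events(r)
        except Exception:  # malformed CIGAR: record-level skip
            log.warning("skipping read %s with unparsable CIGAR %r", r.name, r.cigar)
            continue
        ss, ee = spans.setdefault(r.contig, ([], []))
        ss.append(r.start)
        ee.append(r.end)
        for ev in events:
            key = (r.contig,) + ev
            groups[key] = groups.get(key, 0) + 1
    out: list[IndelCandidate] = []
    # covering reads: alignments whose reference span contains the event
    sorted_spans = {
        c: (sorted(ss), sorted(ee)) for c, (ss, ee) in spans.items()
    }
    for (contig, start, end, kind, seq), support in sorted(groups.items()):
        if support < min_support:
            continue
        starts, ends = sorted_spans[contig]
        n_started = bisect_right(starts, start)
        n_ended = bisect_left(ends, max(end, start + 1))
        covering = max(support, n_started - n_ended)
        if support / covering < min_fraction:
            continue
        out.append(IndelCandidate(contig, start, end, kind, seq, support, covering))
    out.sort(key=lambda c: (c.contig, c.start, c.end, c.kind))
    return out


def somatic_check(
    candidate: IndelCandidate,
    germline_reads: list[AlignedRead],
    min_coverage: int = 8,
    window: int = 5,
) -> IndelCandidate:
    """Germline-window somatic test (mutates and returns the candidate).

    The window spans [start - 5, end + 5]; the candidate is somatic only
    when zero germline reads carry an insertion/deletion CIGAR event
    overlapping it.  If fewer than ``min_coverage`` germline reads overlap
    the window the status is "undetermined" and the candidate is not called
    somatic.
    """
    ws = candidate.start - window
    we = candidate.end + window
    n_cover = 0
    n_events = 0
    for r in germline_reads:
        if r.is_duplicate or r.contig != candidate.contig:
            continue
        if r.end <= ws or r.start > we:
            continue
        n_cover += 1
        for s, e, kind, _ in _read_indel_events(r):
            # insertions are points (s == e); treat boundary touch as overlap
            if s <= we and e >= ws:
                n_events += 1
    candidate.germline_events = n_events
    if n_cover < min_coverage:
        candidate.status = "undetermined"
        candidate.somatic = False
    elif n_events == 0:
        candidate.status = "somatic"
        candidate.somatic = True
    else:
        candidate.status = "germline"
        candidate.somatic = False
    return candidate


def call_somatic_indels(
    tumor_reads: list[AlignedRead],
    germline_reads: list[AlignedRead],
    insert_low: int = 500,
    insert_high: int = 5000,
    min_support: int = 3,
    min_fraction: float = 0.1,
    min_germline_coverage: int = 8,
) -> list[IndelCandidate]:
    """Full two-step pipeline: insert filter, candidate grouping, germline check."""
    filtered = filter_by_insert(tumor_reads, insert_low, insert_high)
    candidates = detect_candidates(filtered, min_support, min_fraction)
    by_contig: dict[str, list[AlignedRead]] = {}
    for r in germline_reads:
        by_contig.setdefault(r.contig, []).append(r)
    for cand in candidates:
        somatic_check(cand, by_contig.get(cand.contig, []), min_germline_coverage)
    return candidates
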