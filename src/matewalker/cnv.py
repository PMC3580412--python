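"""Binned log2-ratio copy-number analysis for matched tumor/germline tracks.

Coverage is summarized in 100 bp bins; each bin is normalized as
log2((depth + pseudocount) / modal depth), where the germline modal depth
comes from its own histogram and the tumor's copy-neutral level is anchored
to the germline through the modal tumor:germline ratio (robust when large
genome fractions are aberrant; see :func:`paired_modal`).  Bins whose
germline depth falls outside 0.1-10x the germline mode are masked as
repeat-like/unsequencable.  The tumor-minus-germline
normalized difference is averaged over a sliding window (2 kb default,
sliding by one bin), windows departing from baseline by more than 0.75 are
flagged, same-sign runs are merged into segments, and segments are
classified by their mean difference into homozygous loss, hemizygous loss,
gain or amplification using thresholds derived from a 60%-purity mixture
(log2 of 0.4, 0.7, 1.3 and 2x relative depth respectively).

An exon-restricted scan (:func:`exon_moderate_deletions`) applies the same
normalization and departure rule to base-level ("sequence") coverage over
coding exons, catching moderate deletions shorter than the genome-wide
window can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reads import CoverageTrack

DEPARTURE = 0.75
STATE_THRESHOLDS = {
    "homozygous_loss": -1.0,  # mean <= -1.0
    "hemizygous_loss": -0.4,  # -1.0 < mean <= -0.4
    "gain": 0.32,             # mean >= 0.32
    "amplified": 1.0,         # mean >= 1.0
}


@dataclass
class CnvSegment:
    contig: str
    start: int
    end: int
    mean_diff: float
    state: str
    n_bins: int
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def modal_depth(
    track: CoverageTrack,
    contigs: list[str] | None = None,
    method: str = "half_sample",
) -> int:
    """Modal bin depth of the track (must be > 0).

    A tumor depth histogram is bimodal whenever a sizable genome fraction is
    copy-number aberrant, and the raw histogram argmax can lock onto the
    aberrant peak (lower-depth Poisson peaks are narrower, hence taller per
    unit mass).  The default "half_sample" method is the half-sample mode:
    the search interval is repeatedly halved onto the sub-interval carrying
    the most histogram mass, which converges to the heaviest — copy-neutral
    — peak; "argmax" returns the raw histogram argmax.
    """
    depths = np.concatenate(
        [track.depths[c] for c in (contigs or sorted(track.depths))]
    )
    if depths.size == 0 or not np.any(depths > 0):
        raise ValueError("coverage track is empty or all-zero")
    rounded = np.rint(depths).astype(np.int64)
    rounded = rounded[rounded > 0]
    counts = np.bincount(rounded)
    if method == "argmax":
        return int(counts.argmax())
    if method != "half_sample":
        raise ValueError(f"unknown mode estimation method {method!r}")
    csum = np.concatenate([[0], np.cumsum(counts)])
    lo, hi = 0, len(counts)  # half-open depth interval under consideration
    while hi - lo > 4:
        w = (hi - lo + 1) // 2
        starts = range(lo, hi - w + 1)
        lo = max(starts, key=lambda s: csum[s + w] - csum[s])
        hi = lo + w
    return int(lo + counts[lo:hi].argmax())


def paired_modal(
    germline: CoverageTrack,
    tumor: CoverageTrack,
    pseudocount: float = 0.5,
    window_bins: int = 20,
) -> tuple[float, float]:
    """Germline modal depth, and the tumor's copy-neutral level anchored to it.

    The germline histogram is effectively unimodal, so its mode is taken
    directly.  The tumor histogram is not: whenever a large genome fraction
    is copy-number aberrant it grows rival peaks and a single-sample mode can
    land on an aberrant state (or the valley between states).  The bins are
    matched loci, though, so the neutral level is identified instead as the
    modal windowed tumor:germline log2 ratio — copy-neutral windows are the
    single largest ratio population even when aberrant states jointly
    outweigh them — and the tumor modal depth is the germline mode scaled by
    2^(that ratio).  Falls back to the tumor's own half-sample mode when
    there are too few usable windows to build the ratio histogram.
    """
    g_modal = modal_depth(germline)
    vals = []
    for contig in sorted(germline.depths):
        g = germline.depths[contig]
        t = tumor.depths[contig]
        mask = usable_mask(g, g_modal)
        r = np.log2(t + pseudocount) - np.log2(g + pseudocount)
        n = len(r) // window_bins
        if n == 0:
            continue
        rw = r[: n * window_bins].reshape(n, window_bins)
        mw = mask[: n * window_bins].reshape(n, window_bins)
        cnt = mw.sum(axis=1)
        ok = cnt >= (window_bins + 1) // 2
        vals.append((rw * mw).sum(axis=1)[ok] / cnt[ok])
    ratios = np.concatenate(vals) if vals else np.empty(0)
    if ratios.size < 30:
        return float(g_modal), float(modal_depth(tumor))
    width = 0.02
    idx = np.round(ratios / width).astype(np.int64)
    offset = idx.min()
    counts = np.bincount(idx - offset)
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    shift = (int(smooth.argmax()) + offset) * width
    return float(g_modal), float(g_modal * 2.0**shift)


def normalized_log2(
    depths: np.ndarray, modal: float, pseudocount: float = 0.5
) -> np.ndarray:
    """Per-bin log2((depth + pseudocount) / modal); modal must be positive."""
    if modal <= 0:
        raise ValueError("modal depth must be positive")
    return np.log2((np.asarray(depths, dtype=float) + pseudocount) / modal)


def usable_mask(
    germline_depths: np.ndarray, germline_modal: float,
    low: float = 0.1, high: float = 10.0,
) -> np.ndarray:
    """Bins whose germline depth lies within [low, high] x the germline mode."""
    d = np.asarray(germline_depths, dtype=float)
    return (d >= low * germline_modal) & (d <= high * germline_modal)


def windowed_difference(
    germline_values: np.ndarray,
    tumor_values: np.ndarray,
    usable: np.ndarray,
    window_bins: int = 20,
) -> np.ndarray:
    """Sliding-window mean of (tumor - germline) normalized coverage.

    Windows are ``window_bins`` consecutive bins sliding by one bin; the
    window value is the mean over its usable bins, NaN when fewer than half
    the bins are usable.  Output length is nbins - window_bins + 1.
    """
    if window_bins < 1:
        raise ValueError("window must span at least one bin")
    diff = np.where(usable, tumor_values - germline_values, 0.0)
    cnt = usable.astype(np.int64)
    csum = np.concatenate([[0.0], np.cumsum(diff)])
    ccnt = np.concatenate([[0], np.cumsum(cnt)])
    n = len(diff) - window_bins + 1
    if n <= 0:
        return np.empty(0)
    wsum = csum[window_bins:] - csum[:-window_bins]
    wcnt = ccnt[window_bins:] - ccnt[:-window_bins]
    out = np.full(n, np.nan)
    ok = wcnt >= (window_bins + 1) // 2
    out[ok] = wsum[ok] / wcnt[ok]
    return out


def _classify(mean: float) -> str:
    if mean <= STATE_THRESHOLDS["homozygous_loss"]:
        return "homozygous_loss"
    if mean <= STATE_THRESHOLDS["hemizygous_loss"]:
        return "hemizygous_loss"
    if mean >= STATE_THRESHOLDS["amplified"]:
        return "amplified"
    if mean >= STATE_THRESHOLDS["gain"]:
        return "gain"
    return "neutral"


def flag_and_segment(
    window_values: np.ndarray,
    contig: str,
    bin_size: int = 100,
    window_bins: int = 20,
    departure: float = DEPARTURE,
    gap_tolerance: int = 2,
    per_bin_diff: np.ndarray | None = None,
    usable: np.ndarray | None = None,
) -> list[CnvSegment]:
    """Merge same-sign runs of flagged windows into classified segments.

    A window is flagged when |value| > departure.  Runs of consecutive
    flagged windows of the same sign, tolerating up to ``gap_tolerance``
    interleaved missing (NaN) windows, become one segment spanning from the
    first window's first bin to the last window's last bin.  The segment
    mean is recomputed over its usable member bins when per-bin values are
    supplied, otherwise over its window values; states follow the
    classification thresholds.  Unflagged windows always break a run, so
    adjacent loss and gain events stay separate.
    """
    vals = np.asarray(window_values, dtype=float)
    segments: list[CnvSegment] = []
    run: list[int] = []
    run_sign = 0
    gap = 0

    def close_run():
        nonlocal run, run_sign, gap
        if run:
            first, last = run[0], run[-1]
            start = first * bin_size
            end = (last + window_bins) * bin_size
            b0, b1 = first, last + window_bins
            if per_bin_diff is not None:
                m = usable[b0:b1] if usable is not None else np.ones(b1 - b0, bool)
                member = per_bin_diff[b0:b1][m]
                mean = float(member.mean()) if member.size else float(np.nanmean(vals[run]))
            else:
                mean = float(np.nanmean(vals[run]))
            segments.append(
                CnvSegment(contig, start, end, mean, _classify(mean), b1 - b0, len(run))
            )
        run, run_sign, gap = [], 0, 0

    for i, v in enumerate(vals):
        if np.isnan(v):
            if run:
                gap += 1
                if gap > gap_tolerance:
                    close_run()
            continue
        sign = 1 if v > departure else (-1 if v < -departure else 0)
        if sign == 0:
            close_run()
        elif sign == run_sign:
            run.append(i)
            gap = 0
        else:
            close_run()
            run = [i]
            run_sign = sign
    close_run()

    # window spans extend window_bins past the last flagged window, so runs
    # separated by a short break can produce overlapping spans; reconcile so
    # the output is disjoint: same-direction overlaps merge, opposite-direction
    # overlaps split at the midpoint
    def remean(seg: CnvSegment) -> CnvSegment:
        if per_bin_diff is None:
            return seg
        b0, b1 = seg.start // bin_size, seg.end // bin_size
        m = usable[b0:b1] if usable is not None else np.ones(b1 - b0, bool)
        member = per_bin_diff[b0:b1][m]
        if member.size:
            seg.mean_diff = float(member.mean())
            seg.state = _classify(seg.mean_diff)
        seg.n_bins = b1 - b0
        return seg

    disjoint: list[CnvSegment] = []
    for s in segments:
        if disjoint and s.start < disjoint[-1].end:
            prev = disjoint[-1]
            if (prev.mean_diff < 0) == (s.mean_diff < 0):
                prev.end = max(prev.end, s.end)
                prev.n_windows += s.n_windows
                remean(prev)
                continue
            mid = ((prev.end + s.start) // (2 * bin_size)) * bin_size
            prev.end = mid
            s.start = mid
            remean(prev)
            remean(s)
        disjoint.append(s)
    return disjoint


def call_cnvs(
    germline: CoverageTrack,
    tumor: CoverageTrack,
    window: int = 2000,
    departure: float = DEPARTURE,
    gap_tolerance: int = 2,
    pseudocount: float = 0.5,
) -> list[CnvSegment]:
    """Whole-genome segment calling from matched binned coverage tracks."""
    if germline.bin_size != tumor.bin_size:
        raise ValueError("tracks must share a bin size")
    bin_size = germline.bin_size
    window_bins = max(1, window // bin_size)
    g_modal, t_modal = paired_modal(germline, tumor, pseudocount, window_bins)
    segments: list[CnvSegment] = []
    for contig in sorted(germline.depths):
        gd = germline.depths[contig]
        td = tumor.depths[contig]
        gv = normalized_log2(gd, g_modal, pseudocount)
        tv = normalized_log2(td, t_modal, pseudocount)
        mask = usable_mask(gd, g_modal)
        wv = windowed_difference(gv, tv, mask, window_bins)
        diff = tv - gv
        segments.extend(
            flag_and_segment(
                wv, contig, bin_size, window_bins, departure, gap_tolerance,
                per_bin_diff=diff, usable=mask,
            )
        )
    return segments


def chromosome_summary(
    germline: CoverageTrack, tumor: CoverageTrack, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-chromosome median normalized log2 difference.

    Whole-chromosome gains or losses shift this median without necessarily
    tripping the 0.75 windowed departure rule (a single-copy change at 60%
    purity sits near +/-0.4-0.5), so chromosome-arm-scale events are
    reported through this summary rather than through segments.
    """
    g_modal, t_modal = paired_modal(germline, tumor, pseudocount)
    rows = []
    for contig in sorted(germline.depths):
        gd = germline.depths[contig]
        td = tumor.depths[contig]
        mask = usable_mask(gd, g_modal)
        diff = normalized_log2(td, t_modal, pseudocount) - normalized_log2(
            gd, g_modal, pseudocount
        )
        med = float(np.median(diff[mask])) if mask.any() else float("nan")
        rows.append({"contig": contig, "median_log2_diff": med, "n_usable_bins": int(mask.sum())})
    return pd.DataFrame(rows)


def exon_moderate_deletions(
    germline: CoverageTrack,
    tumor: CoverageTrack,
    exons: pd.DataFrame,
    departure: float = DEPARTURE,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-exon log2 coverage difference with the genome-wide departure rule.

    ``exons`` needs columns contig/start/end (0-based half-open, e.g. from a
    BED file via :func:`matewalker.io.read_bed`).  Both tracks should be
    base ("sequence") coverage.  Returns one row per exon with the mean
    difference over usable bins, a flag per the departure rule, and a
    no-data marker for exons without usable germline coverage.
    """
    bin_size = germline.bin_size
    g_modal, t_modal = paired_modal(germline, tumor, pseudocount)
    rows = []
    for row in exons.itertuples(index=False):
        contig, start, end = row.contig, int(row.start), int(row.end)
        gd = germline.depths.get(contig)
        td = tumor.depths.get(contig)
        if gd is None:
            rows.append((contig, start, end, np.nan, False, "no_data"))
            continue
        b0, b1 = start // bin_size, (end + bin_size - 1) // bin_size
        g = gd[b0:b1]
        t = td[b0:b1]
        mask = usable_mask(g, g_modal)
        if not mask.any() or not np.any(g > 0):
            rows.append((contig, start, end, np.nan, False, "no_data"))
            continue
        diff = normalized_log2(t, t_modal, pseudocount) - normalized_log2(g, g_modal, pseudocount)
        mean = float(diff[mask].mean())
        flagged = abs(mean) > departure
        rows.append((contig, start, end, mean, flagged, "ok"))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "log2_diff", "flagged", "status"]
    )
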