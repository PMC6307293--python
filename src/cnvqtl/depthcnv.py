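"""Read-depth CNV calling: GC normalisation, sliding-window scan, merging.

Per-base depth is first divided by the track median and then by the median
of its GC bin, so systematic capture bias with GC content cancels and the
copy-neutral ratio sits at 1. A 20-bp window sliding by 1 bp is a variant
window when at least 18 of its bases have a ratio >= 1.4 (gain) or <= 0.6
(loss). Overlapping same-type variant windows are unioned, unions closer
than a merge gap are merged, and each merged region becomes one call with
its mean ratio and an integer copy estimate round(2 * mean_ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DepthTrack, Interval

__all__ = ["CallerParams", "CNVCall", "normalize", "call_windows",
           "merge_and_call", "call_cnvs", "junction_support"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    window_len: int = 20
    min_variant_bases: int = 18
    gain_ratio: float = 1.4
    loss_ratio: float = 0.6
    merge_gap: int = 200
    gc_bin_width: float = 0.02

    def __post_init__(self) -> None:
        if self.min_variant_bases > self.window_len:
            raise ValueError("min_variant_bases cannot exceed window_len")
        if not (self.loss_ratio < 1.0 < self.gain_ratio):
            raise ValueError("need loss_ratio < 1 < gain_ratio")
        if self.window_len < 1 or self.merge_gap < 0:
            raise ValueError("invalid window/merge parameters")


@dataclass
class CNVCall:
    interval: Interval
    type: str  # "gain" | "loss"
    mean_ratio: float
    estimated_copies: int
    n_supporting_junction_reads: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("gain", "loss"):
            raise ValueError(f"unknown call type {self.type!r}")


def normalize(track: DepthTrack, gc_bin_width: float = 0.02) -> np.ndarray:
    """Median- and GC-corrected copy ratio per base (copy-neutral ~ 1)."""
    depth = track.depth
    med = np.median(depth)
    if med <= 0:
        raise ValueError("track median depth is zero; cannot normalise")
    ratio = depth / med
    bins = np.floor(track.gc / gc_bin_width).astype(int)
    out = np.empty_like(ratio)
    for b in np.unique(bins):
        sel = bins == b
        bin_med = np.median(ratio[sel])
        if bin_med <= 0:
            log.warning("GC bin %d has zero median; using global median", b)
            bin_med = 1.0
        out[sel] = ratio[sel] / bin_med
    return out


def call_windows(ratio: np.ndarray, params: CallerParams = CallerParams()
                 ) -> list[tuple[int, str]]:
    """(start index, type) of every variant window, sliding by 1 base."""
    ratio = np.asarray(ratio, dtype=float)
    L = params.window_len
    if len(ratio) < L:
        return []
    kernel = np.ones(L)
    gain_counts = np.convolve((ratio >= params.gain_ratio).astype(float),
                              kernel, mode="valid")
    loss_counts = np.convolve((ratio <= params.loss_ratio).astype(float),
                              kernel, mode="valid")
    windows = []
    thr = params.min_variant_bases - 0.5  # integer counts; avoids FP equality
    for i in np.flatnonzero(gain_counts > thr):
        windows.append((int(i), "gain"))
    for i in np.flatnonzero(loss_counts > thr):
        windows.append((int(i), "loss"))
    windows.sort()
    return windows


def merge_and_call(windows: list[tuple[int, str]], ratio: np.ndarray,
                   params: CallerParams = CallerParams(), chrom: str = "chr",
                   track_start: int = 1) -> list[CNVCall]:
    """Union variant windows per type, merge near regions, emit calls.

    Gains and losses are merged independently; an overlap between the two
    types yields two separate calls. Coordinates of the emitted intervals
    are 1-based inclusive in genome space (track_start maps base index 0).
    """
    calls = []
    L = params.window_len
    for cnv_type in ("gain", "loss"):
        starts = sorted(i for i, t in windows if t == cnv_type)
        if not starts:
            continue
        # union of [i, i+L-1] spans, then merge unions separated <= merge_gap
        regions: list[list[int]] = []
        for i in starts:
            a, b = i, i + L - 1
            if regions and a <= regions[-1][1] + 1 + params.merge_gap:
                regions[-1][1] = max(regions[-1][1], b)
            else:
                regions.append([a, b])
        for a, b in regions:
            mean_ratio = float(np.mean(ratio[a : b + 1]))
            calls.append(
                CNVCall(
                    interval=Interval(chrom, track_start + a, track_start + b),
                    type=cnv_type,
                    mean_ratio=mean_ratio,
                    estimated_copies=int(np.floor(2.0 * mean_ratio + 0.5)),
                )
            )
    calls.sort(key=lambda c: (c.interval.start, c.type))
    return calls


def call_cnvs(track: DepthTrack, params: CallerParams = CallerParams()
              ) -> list[CNVCall]:
    """Normalise a depth track and emit merged CNV calls."""
    ratio = normalize(track, params.gc_bin_width)
    windows = call_windows(ratio, params)
    calls = merge_and_call(windows, ratio, params, chrom=track.chrom,
                           track_start=track.start)
    log.info("CNV caller: %d variant windows -> %d calls", len(windows),
             len(calls))
    return calls


def junction_support(clipped_read_positions: list[tuple[int, str]],
                     call: CNVCall, tolerance_bp: int = 50) -> int:
    """Count clipped-read records within +-tolerance of either call boundary."""
    a, b = call.interval.start, call.interval.end
    n = 0
    for pos, _side in clipped_read_positions:
        if abs(pos - a) <= tolerance_bp or abs(pos - b) <= tolerance_bp:
            n += 1
    return n
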