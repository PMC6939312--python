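"""Identification of intrinsically disordered regions (IDRs) from a
per-residue disorder track.

A disorder track (e.g. IUPRED output) is turned into retained IDR segments in
four steps, applied in order:

1. smooth the track with a centered rolling mean (window 7 residues,
   shrinking at the sequence ends);
2. take maximal runs where the smoothed propensity is strictly above a
   cutoff (0.45);
3. merge runs separated by a short ordered gap (gap of at most 7 residues);
   a merged segment spans the gap residues, which then count as disordered
   in all downstream analysis;
4. drop segments shorter than a minimum length (30 residues).

Coordinates are 0-based half-open throughout this module; user-facing output
converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

__all__ = [
    "Segment",
    "SegmentationParams",
    "smooth_track",
    "threshold_runs",
    "merge_segments",
    "filter_segments",
    "segment_idrs",
]


@dataclass(frozen=True, order=True)
class Segment:
    """A residue interval, 0-based half-open: [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the IDR segmentation step.

    Defaults are the published operating point: a 7-residue smoothing
    window, a 0.45 disorder cutoff (strict), merging of runs within 7
    residues of each other, and a 30-residue minimum IDR length.
    """

    smooth_window: int = 7
    cutoff: float = 0.45
    merge_gap: int = 7
    min_length: int = 30

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd positive integer")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


def smooth_track(scores: Seq[float], window: int) -> np.ndarray:
    """Centered rolling mean with a window that shrinks at the edges.

    The value at position i is the arithmetic mean of the input over
    [i - h, i + h] intersected with the track, h = (window - 1) / 2.
    Output has the same length as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    arr = np.asarray(scores, dtype=float)
    n = arr.size
    if n == 0:
        return arr
    h = (window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(arr)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def threshold_runs(smoothed: Seq[float], cutoff: float) -> list[Segment]:
    """Maximal runs of positions with value strictly greater than `cutoff`."""
    arr = np.asarray(smoothed, dtype=float)
    above = np.concatenate([[False], arr > cutoff, [False]])
    steps = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(steps == 1)
    ends = np.flatnonzero(steps == -1)
    return [Segment(int(s), int(e)) for s, e in zip(starts, ends)]


def merge_segments(segments: Seq[Segment], max_gap: int) -> list[Segment]:
    """Union consecutive segments whose gap is at most `max_gap` residues.

    The merged segment spans from the first start to the last end and so
    includes the gap residues. A gap of max_gap + 1 or more interrupts.
    Input must be sorted and disjoint.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    segs = list(segments)
    for prev, nxt in zip(segs, segs[1:]):
        if nxt.start < prev.end:
            raise ValueError("segments must be sorted and disjoint")
    if not segs:
        return []
    merged: list[Segment] = [segs[0]]
    for seg in segs[1:]:
        if seg.start - merged[-1].end <= max_gap:
            merged[-1] = Segment(merged[-1].start, seg.end)
        else:
            merged.append(seg)
    return merged


def filter_segments(segments: Seq[Segment], min_length: int) -> list[Segment]:
    """Keep segments of length >= min_length (a length-30 segment is kept
    under the default: only strictly shorter ones are excluded)."""
    if min_length < 1:
        raise ValueError("min_length must be positive")
    return [s for s in segments if len(s) >= min_length]


def segment_idrs(scores: Seq[float], params: SegmentationParams | None = None) -> list[Segment]:
    """Full segmentation: smooth, threshold, merge, length-filter, in order."""
    p = params or SegmentationParams()
    smoothed = smooth_track(scores, p.smooth_window)
    runs = threshold_runs(smoothed, p.cutoff)
    merged = merge_segments(runs, p.merge_gap)
    return filter_segments(merged, p.min_length)
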