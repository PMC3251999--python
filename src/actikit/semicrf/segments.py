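"""Segment encoding for null-activity-aware semi-Markov sequence models.

A per-time label sequence is turned into an ordered list of segments
``(y, b, e)`` (label, begin, end; 1-based inclusive).  Labels declared
*null* (activities present in the data but not targeted for recognition)
are eliminated: their runs become gaps, so consecutive segments satisfy
the relaxed constraint ``b[i+1] > e[i]`` rather than ``b[i+1] == e[i]+1``.
Gaps are later charged with the inactivity (IA) observation weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, NamedTuple, Sequence

import numpy as np

from ..errors import ContractError


class SemiSegment(NamedTuple):
    """One labelled segment; ``b`` and ``e`` are 1-based and inclusive."""

    y: Hashable
    b: int
    e: int

    @property
    def duration(self) -> int:
        return self.e - self.b + 1


def encode_segments(labels: Sequence, null_labels: Iterable = ()) -> list[SemiSegment]:
    """Encode a per-time label sequence into semi-Markov segments.

    Maximal runs of each non-null label become segments; runs of null
    labels become gaps.  An all-null sequence encodes to an empty list.

    >>> encode_segments([1, 1, 2, 2, 2, 3, 4, 4])
    [SemiSegment(y=1, b=1, e=2), SemiSegment(y=2, b=3, e=5), SemiSegment(y=3, b=6, e=6), SemiSegment(y=4, b=7, e=8)]
    """
    nulls = set(null_labels)
    segments: list[SemiSegment] = []
    start = None
    current = None
    for t, lab in enumerate(labels, start=1):
        if lab in nulls:
            if current is not None:
                segments.append(SemiSegment(current, start, t - 1))
                current = None
            continue
        if lab != current:
            if current is not None:
                segments.append(SemiSegment(current, start, t - 1))
            current = lab
            start = t
    if current is not None:
        segments.append(SemiSegment(current, start, len(labels)))
    return segments


def decode_segments(segments: Sequence[SemiSegment], T: int, ia_label: Hashable = "IA") -> list:
    """Inverse of :func:`encode_segments`: gaps are filled with ``ia_label``.

    ``encode_segments(decode_segments(S, T), {ia_label}) == S`` for any
    valid segmentation ``S``.
    """
    out = [ia_label] * T
    prev_end = 0
    for seg in segments:
        if not (1 <= seg.b <= seg.e <= T):
            raise ContractError(f"segment {seg} outside sequence of length {T}")
        if seg.b <= prev_end:
            raise ContractError(f"segment {seg} overlaps or touches its predecessor")
        for t in range(seg.b, seg.e + 1):
            out[t - 1] = seg.y
        prev_end = seg.e
    return out


@dataclass(frozen=True)
class DurationStats:
    """Per-label mean and variance of segment durations.

    Variances use the population convention and are floored at
    ``variance_floor`` so the Gaussian duration potential never divides
    by (near) zero.
    """

    m: dict
    s2: dict
    variance_floor: float = 0.25

    def mean(self, y) -> float:
        return self.m.get(y, 1.0)

    def var(self, y) -> float:
        return self.s2.get(y, self.variance_floor)


def duration_stats(
    corpus: Iterable[Sequence[SemiSegment]],
    labels: Iterable | None = None,
    variance_floor: float = 0.25,
) -> DurationStats:
    """Per-label sample mean/variance of durations ``d = e - b + 1``.

    ``labels`` optionally declares the full label set; labels unseen in
    the corpus fall back to ``(m=1, s2=floor)``.
    """
    durations: dict = {}
    for segmentation in corpus:
        for seg in segmentation:
            durations.setdefault(seg.y, []).append(seg.duration)
    m, s2 = {}, {}
    for y, ds in durations.items():
        arr = np.asarray(ds, dtype=float)
        m[y] = float(arr.mean())
        s2[y] = float(max(arr.var(), variance_floor))
    if labels is not None:
        for y in labels:
            if y not in m:
                m[y] = 1.0
                s2[y] = variance_floor
    return DurationStats(m=m, s2=s2, variance_floor=variance_floor)
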