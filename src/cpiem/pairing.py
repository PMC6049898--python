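"""Doubly bound regions: overlapping (target, partner) peak pairs.

A genomic region is doubly bound when a peak of the target TF and a peak of
the partner TF overlap by at least one base pair (half-open intervals).  Each
such pair carries the two peak intensities (x, y) that are the input to the
mixture model, plus the distance between the two peak summits used by the
peak-distance baseline.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from .peaks import PeakRecord


@dataclass
class PeakPair:
    """An overlapping (target, partner) peak pair."""

    target: PeakRecord
    partner: PeakRecord
    x: float
    y: float
    overlap_length: int
    summit_distance: int


def summit_distance(a: PeakRecord, b: PeakRecord) -> int:
    """Absolute distance (bp) between two peak summits on the same chromosome."""
    if a.chrom != b.chrom:
        raise ValueError(
            f"peaks on different chromosomes: {a.chrom} vs {b.chrom}"
        )
    return abs(a.summit - b.summit)


def make_pair(target: PeakRecord, partner: PeakRecord) -> PeakPair:
    ov = min(target.end, partner.end) - max(target.start, partner.start)
    if ov < 1:
        raise ValueError("peaks do not overlap")
    return PeakPair(
        target=target,
        partner=partner,
        x=target.signal,
        y=partner.signal,
        overlap_length=ov,
        summit_distance=summit_distance(target, partner),
    )


def find_overlapping_pairs(
    target_peaks: Sequence[PeakRecord],
    partner_peaks: Sequence[PeakRecord],
    unique: bool = False,
) -> list[PeakPair]:
    """All (target, partner) pairs whose intervals intersect by >= 1 bp.

    Output order is deterministic: target file order, then partner file
    order.  With ``unique=True`` only the best partner per target peak is
    kept (largest overlap, ties broken by smaller summit distance, then
    partner order).
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(partner_peaks):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[0], t[1], t[2]))
    starts = {c: [t[0] for t in lst] for c, lst in by_chrom.items()}

    pairs: list[PeakPair] = []
    for t in target_peaks:
        lst = by_chrom.get(t.chrom)
        if not lst:
            continue
        hi = bisect_left(starts[t.chrom], t.end)  # partner.start < t.end
        hits = [i for (ps, pe, i) in lst[:hi] if pe > t.start]
        hits.sort()
        cand = [make_pair(t, partner_peaks[i]) for i in hits]
        if unique and cand:
            best = min(
                range(len(cand)),
                key=lambda k: (-cand[k].overlap_length, cand[k].summit_distance, k),
            )
            cand = [cand[best]]
        pairs.extend(cand)
    return pairs


def intensities(pairs: Iterable[PeakPair]):
    """(x, y) intensity arrays of a pair collection."""
    import numpy as np

    pairs = list(pairs)
    return (
        np.array([p.x for p in pairs], dtype=float),
        np.array([p.y for p in pairs], dtype=float),
    )
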