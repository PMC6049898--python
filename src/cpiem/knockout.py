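"""Ground-truth cooperative/non-cooperative labels from partner-knockout ChIP-seq.

A doubly bound location is *cooperative* when the target TF's peak disappears
after the partner TF is knocked out, or when its peak rank (rank 1 = highest
intensity) becomes significantly weaker.  A peak whose rank strengthens is
*competitive*; an unchanged peak is *independent*.  Competitive and
independent together form the non-cooperative class.

Two labeling modes are provided.  ``loss_only`` uses peak losses alone (the
fallback when per-replicate peak calls are unavailable); ``rank_change``
additionally tests surviving peaks for significant rank shifts against an
empirical null built from wild-type replicate-vs-replicate rank differences.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .pairing import PeakPair
from .peaks import PeakRecord

COOPERATIVE = "cooperative"
COMPETITIVE = "competitive"
INDEPENDENT = "independent"

NON_COOPERATIVE_LABELS = frozenset({COMPETITIVE, INDEPENDENT})


@dataclass
class LabeledPair:
    """A peak pair with its knockout-derived label and supporting evidence."""

    pair: PeakPair
    label: str  # cooperative | competitive | independent
    evidence: str  # peak_loss | rank_up | rank_down | rank_same


def rank_peaks(intensities: Sequence[float]) -> np.ndarray:
    """Descending-intensity ranks (rank 1 = strongest); ties get average rank."""
    a = np.asarray(intensities, dtype=float)
    if a.size == 0:
        return np.empty(0)
    return rankdata(-a, method="average")


class _OverlapIndex:
    """Largest-overlap interval matcher for one peak set."""

    def __init__(self, peaks: Sequence[PeakRecord]):
        self.by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, p in enumerate(peaks):
            self.by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
        for lst in self.by_chrom.values():
            lst.sort()
        self.starts = {c: [t[0] for t in lst] for c, lst in self.by_chrom.items()}

    def match(self, peak: PeakRecord) -> int | None:
        """Index of the peak with the largest overlap, or None."""
        lst = self.by_chrom.get(peak.chrom)
        if not lst:
            return None
        hi = bisect_left(self.starts[peak.chrom], peak.end)
        best, best_ov = None, 0
        for ps, pe, i in lst[:hi]:
            ov = min(pe, peak.end) - max(ps, peak.start)
            if ov > best_ov or (ov == best_ov and best is not None and i < best):
                if ov >= 1:
                    best, best_ov = i, ov
        return best


def _as_replicates(peaksets) -> list[list[PeakRecord]]:
    sets = list(peaksets)
    if sets and isinstance(sets[0], PeakRecord):
        return [sets]
    return [list(s) for s in sets]


def _normalized_ranks(peaks: Sequence[PeakRecord]) -> np.ndarray:
    return rank_peaks([p.signal for p in peaks]) / len(peaks)


def label_from_knockout(
    pairs: Sequence[PeakPair],
    ko_peaksets,
    wt_peaksets=None,
    mode: str = "loss_only",
    significance: float = 97.5,
) -> list[LabeledPair]:
    """Label each pair from the target TF's behaviour after partner knockout.

    Parameters
    ----------
    pairs
        Overlapping (target, partner) pairs from the wild type.
    ko_peaksets
        One or more replicate peak sets of the target TF after partner
        knockout.  A pair whose target peak overlaps (>= 1 bp) no knockout
        peak in any replicate is labelled cooperative with evidence
        ``peak_loss``.
    wt_peaksets
        Wild-type replicate peak sets of the target TF; required (>= 2) in
        ``rank_change`` mode.
    mode
        ``loss_only``: surviving pairs are labelled independent.
        ``rank_change``: for each surviving peak, the change in mean
        normalized rank (rank / peak count) between knockout and wild-type
        replicates is compared with an empirical null of rank changes
        between wild-type replicates; shifts above the ``significance``
        percentile are cooperative (``rank_up``), below the
        ``100 - significance`` percentile competitive (``rank_down``),
        otherwise independent (``rank_same``).
    significance
        Percentile level of the replicate-derived null (default 97.5).
    """
    if mode not in ("loss_only", "rank_change"):
        raise ValueError(f"unknown mode {mode!r}")
    ko_reps = _as_replicates(ko_peaksets)
    if not ko_reps:
        raise ValueError("at least one knockout peak set is required")
    ko_idx = [_OverlapIndex(rep) for rep in ko_reps]

    if mode == "rank_change":
        wt_reps = _as_replicates(wt_peaksets) if wt_peaksets is not None else []
        if len(wt_reps) < 2:
            raise ValueError(
                "rank_change mode requires at least two wild-type replicates"
            )
        wt_idx = [_OverlapIndex(rep) for rep in wt_reps]
        wt_nr = [_normalized_ranks(rep) for rep in wt_reps]
        ko_nr = [_normalized_ranks(rep) for rep in ko_reps]
        # Null: normalized-rank differences between wild-type replicates,
        # over all peaks, in both directions.
        null: list[float] = []
        for i, rep_i in enumerate(wt_reps):
            for j in range(len(wt_reps)):
                if i == j:
                    continue
                for k, peak in enumerate(rep_i):
                    m = wt_idx[j].match(peak)
                    if m is not None:
                        null.append(float(wt_nr[j][m] - wt_nr[i][k]))
        if not null:
            raise ValueError("wild-type replicates share no overlapping peaks")
        null_arr = np.asarray(null)
        upper = float(np.percentile(null_arr, significance))
        lower = float(np.percentile(null_arr, 100.0 - significance))

    labeled: list[LabeledPair] = []
    for pair in pairs:
        matches = [idx.match(pair.target) for idx in ko_idx]
        if all(m is None for m in matches):
            labeled.append(LabeledPair(pair, COOPERATIVE, "peak_loss"))
            continue
        if mode == "loss_only":
            labeled.append(LabeledPair(pair, INDEPENDENT, "rank_same"))
            continue
        wt_vals = []
        for idx, nr in zip(wt_idx, wt_nr):
            m = idx.match(pair.target)
            if m is not None:
                wt_vals.append(float(nr[m]))
        ko_vals = [
            float(nr[m]) for m, nr in zip(matches, ko_nr) if m is not None
        ]
        if not wt_vals:
            labeled.append(LabeledPair(pair, INDEPENDENT, "rank_same"))
            continue
        delta = float(np.mean(ko_vals) - np.mean(wt_vals))
        if delta > upper:
            labeled.append(LabeledPair(pair, COOPERATIVE, "rank_up"))
        elif delta < lower:
            labeled.append(LabeledPair(pair, COMPETITIVE, "rank_down"))
        else:
            labeled.append(LabeledPair(pair, INDEPENDENT, "rank_same"))
    return labeled


def write_labeled_pairs(labeled: Iterable[LabeledPair], path: str | Path) -> None:
    """Write labels as BED-like text: target interval, pair info, label, evidence."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tx\ty\tsummit_distance\tlabel\tevidence\n"
        )
        for lp in labeled:
            t = lp.pair.target
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\t{lp.pair.x}\t"
                f"{lp.pair.y}\t{lp.pair.summit_distance}\t{lp.label}\t"
                f"{lp.evidence}\n"
            )
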