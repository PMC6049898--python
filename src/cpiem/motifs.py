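"""PWM best-hit scanning and the indirect-binding filter.

A ChIP-seq peak can arise from indirect (tethered) binding, where the
assayed TF contacts DNA only through another protein.  Such peaks carry no
binding-site sequence for the TF, so their best motif-match score looks like
that of unbound background sequence.  The filter scores the strongest motif
match in every peak and in a negative-control set of unbound windows; peaks
scoring below the 90th percentile (threshold T) of the control distribution
are flagged indirect and removed.

PWM scores here are base-2 log-odds of a count matrix (pseudocount
0.01 * background per cell) against a zeroth-order background model.
Absolute score values are convention-dependent; only comparisons against a
threshold computed under the same convention are meaningful.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .peaks import PeakRecord

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}


class UnscannableSequenceWarning(UserWarning):
    pass


@dataclass
class PWM:
    """Position weight matrix: per-position log-odds over A, C, G, T.

    ``scores`` has shape (width, 4); ``background`` holds the zeroth-order
    letter frequencies the odds are taken against.  ``probs`` (if built from
    counts) retains the per-position letter probabilities, used for
    sampling motif sites.
    """

    scores: np.ndarray
    background: np.ndarray
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValueError("PWM scores must have shape (width, 4)")
        if self.scores.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PWM scores must be finite")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 strictly positive frequencies")
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @classmethod
    def from_counts(
        cls, counts, background=None, pseudocount: float = 0.01
    ) -> "PWM":
        """Log-odds PWM from a count (or frequency) matrix.

        ``pseudocount * background`` is added per cell before normalizing
        each position; scores are log2(p / background).
        """
        counts = np.asarray(counts, dtype=float)
        bg = (
            np.full(4, 0.25)
            if background is None
            else np.asarray(background, dtype=float)
        )
        bg = bg / bg.sum()
        p = counts + pseudocount * bg
        p = p / p.sum(axis=1, keepdims=True)
        return cls(scores=np.log2(p / bg), background=bg, probs=p)

    @classmethod
    def from_file(
        cls, path: str | Path, kind: str = "counts", background=None
    ) -> "PWM":
        """Read a whitespace-delimited 4-column (A C G T) matrix.

        The first line is a header (ignored); ``kind`` is ``counts`` (log-odds
        taken here) or ``logodds`` (values used as-is).
        """
        lines = [
            ln
            for ln in Path(path).read_text().splitlines()
            if ln.strip()
        ]
        rows = [list(map(float, ln.split())) for ln in lines[1:]]
        mat = np.asarray(rows, dtype=float)
        if kind == "counts":
            return cls.from_counts(mat, background=background)
        if kind != "logodds":
            raise ValueError(f"unknown PWM kind {kind!r}")
        bg = (
            np.full(4, 0.25)
            if background is None
            else np.asarray(background, dtype=float)
        )
        return cls(scores=mat, background=bg)

    def write(self, path: str | Path, name: str = "pwm") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for row in self.scores:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    def reverse_complement_scores(self) -> np.ndarray:
        return self.scores[::-1, ::-1]


@dataclass
class ScanHit:
    """Best motif match: log-odds score, 0-based offset, strand."""

    score: float
    position: int
    strand: str


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid letter {exc.args[0]!r} in sequence") from None


def _window_scores(codes: np.ndarray, score_rows: np.ndarray) -> np.ndarray:
    """Sum-of-position scores for every offset; N positions contribute 0."""
    width = score_rows.shape[0]
    n_off = codes.size - width + 1
    lut = np.hstack([score_rows, np.zeros((width, 1))])  # column 4 = N
    acc = np.zeros(n_off)
    for i in range(width):
        acc += lut[i, codes[i : i + n_off]]
    return acc


def best_hit_score(sequence: str, pwm: PWM) -> ScanHit:
    """Best motif match over all offsets on both strands.

    The reverse strand is scored on the reverse complement.  Ties resolve
    to the smaller position, then the + strand.  Positions holding ``N``
    contribute a neutral score of 0.
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than PWM width {pwm.width}"
        )
    codes = _encode(sequence)
    fwd = _window_scores(codes, pwm.scores)
    rev = _window_scores(codes, pwm.reverse_complement_scores())
    best = max(fwd.max(), rev.max())
    pos_f = int(np.argmax(fwd == best)) if (fwd == best).any() else None
    pos_r = int(np.argmax(rev == best)) if (rev == best).any() else None
    if pos_f is not None and (pos_r is None or pos_f <= pos_r):
        return ScanHit(score=float(best), position=pos_f, strand="+")
    return ScanHit(score=float(best), position=pos_r, strand="-")


def _peak_intervals(
    peaks: Iterable[PeakRecord],
) -> dict[str, tuple[list[int], list[int]]]:
    """Per chromosome: starts (sorted) and running max of ends."""
    by: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for c, lst in by.items():
        lst.sort()
        starts = [s for s, _ in lst]
        max_ends: list[int] = []
        m = 0
        for _, e in lst:
            m = max(m, e)
            max_ends.append(m)
        out[c] = (starts, max_ends)
    return out


def _overlaps_any(
    iv: tuple[list[int], list[int]] | None, start: int, end: int
) -> bool:
    if iv is None:
        return False
    starts, max_ends = iv
    i = bisect_left(starts, end)  # intervals with s < end
    return i > 0 and max_ends[i - 1] > start


def sample_unbound_windows(
    genome: dict[str, str],
    peaks: Sequence[PeakRecord],
    n_windows: int,
    window_length: int,
    seed: int,
) -> list[str]:
    """Draw N random genome windows of length l overlapping no peak.

    Windows containing ``N`` bases are rejected.  Reproducible for a given
    seed; raises when the unbound space cannot accommodate the draw.
    """
    rng = np.random.default_rng(seed)
    names = [c for c in genome if len(genome[c]) >= window_length]
    if not names:
        raise ValueError("no contig long enough for the window length")
    lengths = np.array([len(genome[c]) - window_length + 1 for c in names], float)
    weights = lengths / lengths.sum()
    iv = _peak_intervals(peaks)
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * n_windows + 10_000
    while len(out) < n_windows:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "insufficient unbound space to place the requested windows"
            )
        c = names[int(rng.choice(len(names), p=weights))]
        start = int(rng.integers(0, len(genome[c]) - window_length + 1))
        end = start + window_length
        if _overlaps_any(iv.get(c), start, end):
            continue
        seq = genome[c][start:end]
        if "N" in seq or "n" in seq:
            continue
        out.append(seq)
    return out


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank (ceil convention) percentile of a non-empty sample."""
    v = sorted(values)
    if not v:
        raise ValueError("empty sample")
    k = max(1, ceil(percentile / 100.0 * len(v)))
    return float(v[min(k, len(v)) - 1])


def indirect_binding_filter(
    peaks: Sequence[PeakRecord],
    genome: dict[str, str],
    pwm: PWM,
    control_scores: Sequence[float],
    percentile: float = 90.0,
) -> tuple[list[PeakRecord], list[PeakRecord], float]:
    """Flag indirectly bound peaks by sub-threshold best motif scores.

    T is the nearest-rank ``percentile`` of ``control_scores`` (best-hit
    scores of unbound control windows).  A peak whose best motif score is
    strictly below T is flagged indirect; the rest are retained.  Peaks
    whose sequence cannot be scanned (shorter than the PWM, or every window
    covered by N) are flagged with a warning.

    Returns ``(retained, flagged, T)``.
    """
    if len(list(control_scores)) == 0:
        raise ValueError("control scores must be non-empty")
    t = nearest_rank_percentile(control_scores, percentile)
    retained, flagged = [], []
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"contig {p.chrom!r} absent from genome")
        seq = genome[p.chrom][p.start : p.end]
        window = seq.upper()
        scannable = len(window) >= pwm.width and any(
            "N" not in window[i : i + pwm.width]
            for i in range(len(window) - pwm.width + 1)
        )
        if not scannable:
            warnings.warn(
                f"peak {p.name} at {p.chrom}:{p.start}-{p.end} is not "
                "scannable; flagged",
                UnscannableSequenceWarning,
            )
            flagged.append(p)
            continue
        hit = best_hit_score(window, pwm)
        (flagged if hit.score < t else retained).append(p)
    return retained, flagged, t
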