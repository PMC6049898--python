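"""Reading, writing and transforming ChIP-seq peak calls.

Peak calls are handled in the ENCODE narrowPeak (BED6+4) dialect, with plain
BED6 accepted as well.  Coordinates are BED-convention 0-based half-open
throughout.  The peak *intensity* is taken from a configurable column
(default: the narrowPeak ``signalValue`` field, 0-indexed column 6); the
*summit* is the within-peak offset of maximal read pile-up, stored in the
narrowPeak 10th field with ``-1`` meaning unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence


class PeakParseError(ValueError):
    """A malformed line in a peak-call file (message names the line number)."""


@dataclass
class PeakRecord:
    """One ChIP-seq peak call.

    ``summit_offset`` is the summit position relative to ``start`` (bp), or
    ``None`` when the caller did not report one; ``summit`` substitutes the
    interval midpoint in that case.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal: float = 0.0
    p_log10: float | None = None
    q_log10: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.signal < 0:
            raise ValueError(f"negative peak intensity {self.signal}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit coordinate; interval midpoint if unknown."""
        if self.summit_offset is None:
            return (self.start + self.end) // 2
        return self.start + self.summit_offset


def _opt_float(field: str) -> float | None:
    v = float(field)
    return None if v < 0 else v


def parse_narrowpeak(
    path: str | Path, intensity_column: int = 6
) -> list[PeakRecord]:
    """Parse a narrowPeak / BED6(+4) file into :class:`PeakRecord` objects.

    Parameters
    ----------
    path
        Peak-call file.  Lines starting with ``#``, ``track`` or ``browser``
        are skipped.  Data lines need at least 6 whitespace-separated fields.
    intensity_column
        0-indexed column holding the peak intensity.  Default 6 is the
        narrowPeak ``signalValue`` field; use 4 to read the BED score column
        instead.

    Raises
    ------
    PeakParseError
        On short lines, non-numeric coordinates, or ``start >= end``; the
        message names the offending line number.
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 6:
                raise PeakParseError(
                    f"line {lineno}: expected >= 6 fields, found {len(f)}"
                )
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise PeakParseError(
                    f"line {lineno}: non-numeric coordinates {f[1]!r}, {f[2]!r}"
                ) from exc
            if start < 0 or start >= end:
                raise PeakParseError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            if intensity_column >= len(f):
                raise PeakParseError(
                    f"line {lineno}: no intensity column {intensity_column} "
                    f"({len(f)} fields)"
                )
            try:
                signal = float(f[intensity_column])
            except ValueError as exc:
                raise PeakParseError(
                    f"line {lineno}: non-numeric intensity "
                    f"{f[intensity_column]!r}"
                ) from exc
            score = 0 if f[4] == "." else int(float(f[4]))
            p_log10 = _opt_float(f[7]) if len(f) > 7 else None
            q_log10 = _opt_float(f[8]) if len(f) > 8 else None
            summit: int | None = None
            if len(f) > 9:
                s = int(float(f[9]))
                if s >= 0:
                    if not (0 <= s < end - start):
                        raise PeakParseError(
                            f"line {lineno}: summit offset {s} outside peak"
                        )
                    summit = s
            try:
                rec = PeakRecord(
                    chrom=f[0],
                    start=start,
                    end=end,
                    name=f[3],
                    score=score,
                    strand=f[5],
                    signal=signal,
                    p_log10=p_log10,
                    q_log10=q_log10,
                    summit_offset=summit,
                )
            except ValueError as exc:
                raise PeakParseError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_narrowpeak(
    peaks: Iterable[PeakRecord],
    path: str | Path,
    posteriors: Sequence[float] | None = None,
) -> None:
    """Write peaks as narrowPeak; ``posteriors`` adds an 11th column."""
    peaks = list(peaks)
    if posteriors is not None and len(posteriors) != len(peaks):
        raise ValueError("posteriors length does not match peak count")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fields = [
                p.chrom,
                str(p.start),
                str(p.end),
                p.name,
                str(p.score),
                p.strand,
                str(p.signal),
                "-1" if p.p_log10 is None else str(p.p_log10),
                "-1" if p.q_log10 is None else str(p.q_log10),
                "-1" if p.summit_offset is None else str(p.summit_offset),
            ]
            if posteriors is not None:
                fields.append(str(float(posteriors[i])))
            fh.write("\t".join(fields) + "\n")


def trim_to_summit(peaks: Iterable[PeakRecord], flank: int) -> list[PeakRecord]:
    """Replace each peak by ``[summit - flank, summit + flank)``.

    The left edge is clamped at 0 (chromosome lengths are not known here, so
    no right clamp is applied).  Peaks without a summit annotation use the
    interval midpoint.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for p in peaks:
        s = p.summit
        start = max(0, s - flank)
        out.append(
            replace(p, start=start, end=s + flank, summit_offset=s - start)
        )
    return out
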