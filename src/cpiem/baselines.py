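"""Baseline cooperative-binding detectors used for comparison.

The peak-distance detector calls a doubly bound region cooperative when the
two peak summits are closer than a threshold distance d — the premise being
that physically close binding events are more likely to interact.  The
cooperative index scores regions by the relative change in an external
occupancy model's predicted intensity when a cooperative interaction term is
enabled: Delta = (I' - I) / I, where I and I' are the predictions without
and with the interaction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pairing import PeakPair


def peak_distance_detect(pairs: Sequence[PeakPair], d: float) -> np.ndarray:
    """Cooperative call (True) iff summit distance < d (strict)."""
    if d < 0:
        raise ValueError("distance threshold must be non-negative")
    dist = np.asarray([p.summit_distance for p in pairs], dtype=float)
    return dist < d


def distance_scores(pairs: Sequence[PeakPair]) -> np.ndarray:
    """Score for ROC sweeping: negated summit distance (closer = higher)."""
    return -np.asarray([p.summit_distance for p in pairs], dtype=float)


def cooperative_index(independent_prediction, cooperative_prediction):
    """Relative intensity change Delta = (I' - I) / I; vectorized.

    ``independent_prediction`` (I) must be strictly positive.  Delta can be
    positive or negative; downstream calls compare Delta > Delta_T.
    """
    i = np.asarray(independent_prediction, dtype=float)
    ip = np.asarray(cooperative_prediction, dtype=float)
    if np.any(i <= 0):
        raise ValueError("independent predictions must be strictly positive")
    out = (ip - i) / i
    return float(out) if out.ndim == 0 else out


def read_prediction_table(path: str | Path) -> pd.Series:
    """Read a two-column (region id, predicted intensity) prediction file."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["region", "intensity"],
        comment="#",
    )
    return df.set_index("region")["intensity"]
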