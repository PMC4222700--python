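"""Low-complexity regions and long disorder segments in protein sequences.

A low-complexity region (LCR) is a segment whose residue composition has
low Shannon entropy (in bits over the 20-letter amino-acid alphabet).  The
detector slides a window over the sequence, marks residues covered by any
window whose entropy falls below a threshold, merges nearby runs and
reports merged segments of at least ``min_len`` residues.  This is a
SEG-style entropy detector; window, threshold and merge gap are exposed so
the operating point can be calibrated.

Disorder is not predicted here: long intrinsically disordered regions
(IDRs) are extracted from supplied per-residue score tracks as maximal runs
of at least 30 residues above a score threshold.

All sequence coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import AMINO_ACIDS

__all__ = [
    "ProteinRecord",
    "LcrSegment",
    "FeatureSummary",
    "shannon_entropy",
    "detect_lcrs",
    "long_disorder_segments",
    "summarize_features",
    "compare_sets",
]

_VALID = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; X is allowed and ignored in entropy counts."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = [
            i + 1 for i, ch in enumerate(self.sequence) if ch not in _VALID
        ]
        if bad:
            raise ValueError(
                f"{self.id}: invalid residues at positions {bad[:10]}"
                + ("…" if len(bad) > 10 else "")
            )


@dataclass(frozen=True)
class LcrSegment:
    """One low-complexity interval, 1-based inclusive, with its entropy."""

    protein_id: str
    start: int
    end: int
    entropy_bits: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("need 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FeatureSummary:
    """Segment counts over a protein set, Table-style.

    ``mean_per_protein`` is reported to one decimal and
    ``pct_with_at_least_one`` as an integer percentage, matching the
    conventional summary layout.
    """

    n_proteins: int
    total_segments: int
    mean_per_protein: float
    pct_with_at_least_one: int


def shannon_entropy(segment: str) -> float:
    """Composition entropy in bits, X residues excluded from the counts."""
    counts = Counter(ch for ch in segment if ch != "X")
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


def detect_lcrs(
    record: ProteinRecord,
    window: int = 12,
    entropy_threshold_bits: float = 2.2,
    min_len: int = 12,
    merge_gap: int = 2,
) -> list[LcrSegment]:
    """Sliding-window entropy LCR detection.

    Residues covered by any window with entropy below the threshold are
    marked low-complexity; runs of marked residues separated by gaps of at
    most ``merge_gap`` are merged; merged spans shorter than ``min_len`` are
    dropped.  If a merged span's own entropy exceeds the threshold (possible
    after bridging a gap), terminal residues are trimmed greedily until it
    complies, so every reported segment satisfies entropy <= threshold.
    A window longer than the protein yields no segments.
    """
    seq = record.sequence
    L = len(seq)
    if window > L:
        return []
    low = np.zeros(L, dtype=bool)
    for i in range(L - window + 1):
        if shannon_entropy(seq[i : i + window]) < entropy_threshold_bits:
            low[i : i + window] = True

    segments: list[LcrSegment] = []
    runs = _runs(low)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    for a, b in merged:
        a, b = _trim(seq, a, b, entropy_threshold_bits)
        if b - a + 1 >= min_len:
            segments.append(
                LcrSegment(
                    protein_id=record.id,
                    start=a + 1,
                    end=b + 1,
                    entropy_bits=shannon_entropy(seq[a : b + 1]),
                )
            )
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based inclusive (start, end) runs of True."""
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _trim(seq: str, a: int, b: int, threshold: float) -> tuple[int, int]:
    """Trim segment ends until its entropy is within the threshold."""
    while b > a and shannon_entropy(seq[a : b + 1]) >= threshold:
        # drop whichever terminal residue lowers entropy more
        h_left = shannon_entropy(seq[a + 1 : b + 1])
        h_right = shannon_entropy(seq[a : b])
        if h_left <= h_right:
            a += 1
        else:
            b -= 1
    return a, b


def long_disorder_segments(
    protein_id: str,
    track: Sequence[float],
    score_threshold: float = 0.5,
    min_len: int = 30,
    protein_length: int | None = None,
) -> list[LcrSegment]:
    """Maximal runs of disorder score >= threshold, at least ``min_len`` long.

    The track must carry one score per residue (checked against
    ``protein_length`` when given).  Returned segments reuse the segment
    container with the mean score stored in place of entropy.
    """
    scores = np.asarray(track, dtype=float)
    if scores.ndim != 1 or len(scores) == 0:
        raise ValueError(f"{protein_id}: disorder track must be a non-empty vector")
    if protein_length is not None and len(scores) != protein_length:
        raise ValueError(
            f"{protein_id}: track length {len(scores)} != protein length "
            f"{protein_length}"
        )
    mask = scores >= score_threshold
    out = []
    for a, b in _runs(mask):
        if b - a + 1 >= min_len:
            out.append(
                LcrSegment(
                    protein_id=protein_id,
                    start=a + 1,
                    end=b + 1,
                    entropy_bits=float(scores[a : b + 1].mean()),
                )
            )
    return out


def summarize_features(
    per_protein: Mapping[str, Sequence[LcrSegment] | int],
) -> FeatureSummary:
    """Totals, mean per protein (1 decimal) and % with >= 1 segment.

    Values may be segment lists (from the detector) or plain per-protein
    counts (when summarizing externally tabulated features).  Every protein
    of the set must be present, with zero segments where none were found.
    """
    if not per_protein:
        raise ValueError("cannot summarize an empty protein set")
    counts = [
        v if isinstance(v, int) else len(v) for v in per_protein.values()
    ]
    n = len(counts)
    total = int(sum(counts))
    return FeatureSummary(
        n_proteins=n,
        total_segments=total,
        mean_per_protein=round(total / n, 1),
        pct_with_at_least_one=round(100 * sum(c > 0 for c in counts) / n),
    )


def compare_sets(
    query: FeatureSummary, background: FeatureSummary
) -> pd.DataFrame:
    """Side-by-side query-vs-background comparison with fold difference.

    The fold is the ratio of the reported (1-decimal) means, rounded to two
    decimals; NaN (flagged) when the background mean is 0.
    """
    fold = (
        round(query.mean_per_protein / background.mean_per_protein, 2)
        if background.mean_per_protein > 0
        else float("nan")
    )
    return pd.DataFrame(
        [
            {
                "set": "query",
                "n_proteins": query.n_proteins,
                "total_segments": query.total_segments,
                "mean_per_protein": query.mean_per_protein,
                "pct_with_at_least_one": query.pct_with_at_least_one,
                "fold_vs_background": fold,
                "pct_difference": query.pct_with_at_least_one
                - background.pct_with_at_least_one,
            },
            {
                "set": "background",
                "n_proteins": background.n_proteins,
                "total_segments": background.total_segments,
                "mean_per_protein": background.mean_per_protein,
                "pct_with_at_least_one": background.pct_with_at_least_one,
                "fold_vs_background": 1.0,
                "pct_difference": 0,
            },
        ]
    )
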