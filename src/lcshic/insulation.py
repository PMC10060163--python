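"""Insulation scores, boundary calling and top-boundary selection.

The insulation score of a 50 kb bin is the mean contact count in the
sliding diamond window of contacts crossing that bin (1 Mb to each
side), normalised by the chromosome-wise geometric mean and
log2-scaled, so tracks are centred at 0 and local minima mark
putative TAD boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InsulationTrack:
    """Per-bin insulation scores of one chromosome (NaN = missing)."""

    chrom: str
    bin_size: int
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.scores.size) * self.bin_size
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": starts,
            "end": starts + self.bin_size,
            "value": self.scores,
        })


def insulation_track(
    intra: np.ndarray,
    chrom: str = "chr",
    bin_size: int = 50_000,
    window: int = 1_000_000,
    max_missing_fraction: float = 0.2,
) -> InsulationTrack:
    """Diamond-window insulation score of a balanced intra map.

    The window at bin b covers contacts between the ``w`` bins before b
    and the ``w`` bins from b onward (all pairs crossing the b-1 | b
    gap), with ``w = window / bin_size``. Windows that do not fit the
    chromosome, or whose fraction of missing (NaN) pixels exceeds
    ``max_missing_fraction``, are missing. Valid window means are
    divided by their chromosome-wise geometric mean and log2-scaled.
    """
    n = intra.shape[0]
    w = window // bin_size
    scores = np.full(n, np.nan)
    if n < 2 * w:
        warnings.warn(f"{chrom}: shorter than the insulation window; all missing")
        return InsulationTrack(chrom, bin_size, scores)
    raw = np.full(n, np.nan)
    for b in range(w, n - w + 1):
        block = intra[b - w:b, b:b + w]
        finite = np.isfinite(block)
        if 1 - finite.mean() > max_missing_fraction:
            continue
        raw[b] = block[finite].mean() if finite.any() else np.nan
    valid = np.isfinite(raw) & (raw > 0)
    if not valid.any():
        return InsulationTrack(chrom, bin_size, scores)
    geo = np.exp(np.mean(np.log(raw[valid])))
    scores[valid] = np.log2(raw[valid] / geo)
    return InsulationTrack(chrom, bin_size, scores)


@dataclass
class Boundary:
    """A putative TAD boundary: lower score = stronger insulation."""

    chrom: str
    bin: int
    score: float

    @property
    def position(self) -> int:
        return self.bin  # bin index; bp position is bin * bin_size


def call_boundaries(track: InsulationTrack, window: int = 400_000) -> list[Boundary]:
    """Local minima of the insulation score within +-``window``.

    A bin is a boundary when its score is strictly below every valid
    score in the preceding half-window and no greater than any in the
    following half-window, so plateaus and exact ties yield their
    leftmost bin.
    """
    w = window // track.bin_size
    scores = track.scores
    n = scores.size
    out = []
    for b in range(n):
        s = scores[b]
        if not np.isfinite(s):
            continue
        left = scores[max(0, b - w):b]
        right = scores[b + 1:b + w + 1]
        lv = left[np.isfinite(left)]
        rv = right[np.isfinite(right)]
        neighbours = np.concatenate([lv, rv])
        if neighbours.size == 0 or not (s < neighbours).any():
            continue  # flat stretches are not minima
        if (lv.size == 0 or (s < lv).all()) and (rv.size == 0 or (s <= rv).all()):
            out.append(Boundary(track.chrom, b, float(s)))
    return out


def boundaries_to_frame(boundaries: list[Boundary], bin_size: int) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.bin * bin_size, (b.bin + 1) * bin_size, b.score) for b in boundaries],
        columns=["chrom", "start", "end", "score"],
    )


def _match_boundaries(
    bnd_a: list[Boundary], bnd_b: list[Boundary], max_dist_bins: int
) -> list[tuple[Boundary, Boundary]]:
    """Greedy one-to-one matching by distance, nearest pairs first."""
    cands = []
    for i, a in enumerate(bnd_a):
        for j, b in enumerate(bnd_b):
            if a.chrom == b.chrom and abs(a.bin - b.bin) <= max_dist_bins:
                cands.append((abs(a.bin - b.bin), i, j))
    cands.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((bnd_a[i], bnd_b[j]))
    return pairs


def shared_top_boundaries(
    boundaries_a: list[Boundary],
    boundaries_b: list[Boundary],
    k: int = 300,
    bin_size: int = 50_000,
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Shared boundaries restricted to the strongest ~k per condition.

    Boundaries are matched one-to-one within +-``max_dist``. Each
    condition's k-th smallest boundary score defines a per-condition
    threshold; the selection threshold is the larger (weaker) of the
    two, and shared pairs with both scores at or below it are kept —
    by construction the final count need not be exactly k.
    """

    def kth_score(boundaries: list[Boundary]) -> float:
        scores = np.sort([b.score for b in boundaries])
        if scores.size < k:
            warnings.warn(
                f"only {scores.size} boundaries available for top-{k} selection"
            )
            return float(scores[-1]) if scores.size else np.inf
        return float(scores[k - 1])

    threshold = max(kth_score(boundaries_a), kth_score(boundaries_b))
    pairs = _match_boundaries(boundaries_a, boundaries_b, max_dist // bin_size)
    rows = [
        (a.chrom, a.bin * bin_size, b.bin * bin_size, a.score, b.score)
        for a, b in pairs
        if a.score <= threshold and b.score <= threshold
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start_a", "start_b", "score_a", "score_b"]
    )
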