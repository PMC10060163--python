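"""Compartment-interaction profiles and loss-of-segregation statistics.

For every 50 kb bin the distance-normalised (observed/expected)
intra-chromosomal contacts are summed per 8-level sub-compartment,
corrected for the chromosome fraction each level covers, and
normalised to fractions f_b(comp) summing to 1. The bin's own-level
fraction is its compartment segregation score (CScore). Between two
conditions, per-level loss/gain counts form the segregation-change
ratios: values above 1 mean loss of segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .genome import SUBCOMPARTMENT_LABELS, CompartmentSegmentation, rank_to_level

F_COLUMNS = [f"f_{i}" for i in range(8)]


def coarsen_block(intra: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a square intra-chromosomal block into larger bins."""
    n = intra.shape[0]
    m = -(-n // factor)
    padded = np.zeros((m * factor, m * factor))
    padded[:n, :n] = intra
    return padded.reshape(m, factor, m, factor).sum(axis=(1, 3))


def distance_normalized_oe(
    intra_coarse: np.ndarray, n_fine: int, factor: int = 20
) -> np.ndarray:
    """Observed/expected map at coarse resolution, upscaled to fine bins.

    Each coarse pixel is divided by the mean contact count at its
    genomic distance (computed over the same chromosome); distances
    with zero total coverage are undefined and propagate as NaN. Every
    fine pixel then takes the value of the coarse superpixel it
    belongs to (exact ``factor``:1 nesting; a short terminal superpixel
    keeps the mean of the pixels it actually covers).
    """
    n = intra_coarse.shape[0]
    if intra_coarse.shape != (n, n):
        raise ValueError("intra map must be square")
    oe = np.full((n, n), np.nan)
    for d in range(n):
        diag = np.diagonal(intra_coarse, offset=d)
        mean = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
        if not np.isfinite(mean) or mean == 0:
            continue
        vals = diag / mean
        idx = np.arange(n - d)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    fine_idx = np.arange(n_fine) // factor
    if fine_idx.size and fine_idx[-1] >= n:
        raise ValueError("n_fine exceeds the coarse map extent")
    return oe[np.ix_(fine_idx, fine_idx)]


@dataclass
class SegregationProfile:
    """Per-bin compartment segregation fractions.

    ``df`` columns: chrom, bin, level (octile 0..7), f_0..f_7 (summing
    to 1 per bin), cscore (own-level fraction). Bins with no coverage
    or no rank are excluded; ``n_excluded`` reports how many.
    """

    df: pd.DataFrame
    n_excluded: int = 0

    def key(self) -> pd.DataFrame:
        return self.df.set_index(["chrom", "bin"])


def segregation_profile(
    oe: np.ndarray, binned_ranks: np.ndarray, chrom: str = "chr"
) -> SegregationProfile:
    """Segregation fractions of one chromosome.

    ``oe`` is the distance-normalised 50 kb map, ``binned_ranks`` the
    per-bin compartment rank (NaN = uncovered). The per-level coverage
    correction B_comp is the chromosome-wise fraction of ranked bins in
    each level, removing the bias of levels covering more of the
    chromosome.
    """
    n = oe.shape[0]
    if binned_ranks.size != n:
        raise ValueError("rank vector does not match map size")
    level = rank_to_level(binned_ranks)
    ranked = level >= 0
    b_comp = np.array([(level[ranked] == c).sum() for c in range(8)], dtype=float)
    b_comp /= max(b_comp.sum(), 1.0)

    rows = []
    n_excluded = 0
    oe_filled = np.where(np.isfinite(oe), oe, 0.0)
    valid_pix = np.isfinite(oe)
    for b in range(n):
        if not ranked[b]:
            n_excluded += 1
            continue
        cols = ranked & valid_pix[b]
        if not cols.any():
            n_excluded += 1
            continue
        s = np.zeros(8)
        np.add.at(s, level[cols], oe_filled[b, cols])
        total = s.sum()
        if total <= 0:
            n_excluded += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(b_comp > 0, s / (total * b_comp), np.nan)
        zsum = np.nansum(z)
        f = np.where(np.isfinite(z), z / zsum, np.nan)
        rows.append((chrom, b, level[b], *f, f[level[b]]))
    df = pd.DataFrame(rows, columns=["chrom", "bin", "level", *F_COLUMNS, "cscore"])
    return SegregationProfile(df, n_excluded)


def combine_profiles(profiles: list[SegregationProfile]) -> SegregationProfile:
    return SegregationProfile(
        pd.concat([p.df for p in profiles], ignore_index=True),
        sum(p.n_excluded for p in profiles),
    )


def segregation_pipeline(
    matrix: ContactMatrix,
    segmentation: CompartmentSegmentation,
    coarse_bin: int = 1_000_000,
    chroms: list[str] | None = None,
) -> SegregationProfile:
    """Full profile computation from a bulk contact matrix.

    Per chromosome: aggregate the intra map to ``coarse_bin``,
    distance-normalise, upscale back to the native bin size, then
    compute segregation fractions against the binned segmentation.
    """
    genome = matrix.genome
    factor = coarse_bin // genome.bin_size
    parts = []
    for chrom in chroms or genome.chrom_names:
        n_fine = genome.n_bins(chrom)
        coarse = coarsen_block(matrix.intra(chrom), factor)
        oe = distance_normalized_oe(coarse, n_fine, factor)
        ranks = segmentation.binned_ranks(chrom, genome.bin_size, n_fine)
        parts.append(segregation_profile(oe, ranks, chrom))
    return combine_profiles(parts)


def _loss_gain_ratio(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """(lose, gain, ties, ratio) with ties counted half to each side.

    "Lose" counts bins whose value decreased from condition a to b.
    """
    lose = float((b < a).sum())
    gain = float((b > a).sum())
    ties = float((b == a).sum())
    num = lose + ties / 2
    den = gain + ties / 2
    ratio = np.inf if den == 0 else num / den
    return lose, gain, ties, ratio


def segregation_change_matrix(
    profile_a: SegregationProfile, profile_b: SegregationProfile
) -> pd.DataFrame:
    """Symmetric 8x8 segregation-change matrix on the -log2 scale.

    Entry (c1, c2) averages the loss/gain ratio of f(c2) over bins of
    level c1 with its transpose, then takes -log2: positive values
    mean gain of contacts between the two levels, negative values loss.
    Pairs with an empty level are NaN.
    """
    a = profile_a.key()
    b = profile_b.key()
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    raw = np.full((8, 8), np.nan)
    for c1 in range(8):
        sel = a["level"] == c1
        if not sel.any():
            continue
        for c2 in range(8):
            fa = a.loc[sel, f"f_{c2}"].to_numpy()
            fb = b.loc[sel, f"f_{c2}"].to_numpy()
            ok = np.isfinite(fa) & np.isfinite(fb)
            if not ok.any():
                continue
            raw[c1, c2] = _loss_gain_ratio(fa[ok], fb[ok])[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        sym = -np.log2(0.5 * (raw + raw.T))
    return pd.DataFrame(sym, index=SUBCOMPARTMENT_LABELS, columns=SUBCOMPARTMENT_LABELS)


def loss_of_segregation_score(
    profile_a: SegregationProfile, profile_b: SegregationProfile
) -> pd.DataFrame:
    """Per-level loss-of-segregation score.

    For bins of each level, the ratio of bins whose own-level CScore
    decreased (condition a -> b) to bins whose CScore increased, ties
    counted half to each side. Values above 1 indicate loss of
    segregation in condition b. Zero denominators yield +inf with the
    ``undefined`` flag set.
    """
    a = profile_a.key()
    b = profile_b.key()
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    rows = []
    for c in range(8):
        sel = (a["level"] == c).to_numpy()
        if not sel.any():
            rows.append((SUBCOMPARTMENT_LABELS[c], 0, 0.0, 0.0, 0.0, np.nan, True))
            continue
        ca = a.loc[sel, "cscore"].to_numpy()
        cb = b.loc[sel, "cscore"].to_numpy()
        lose, gain, ties, ratio = _loss_gain_ratio(ca, cb)
        rows.append(
            (SUBCOMPARTMENT_LABELS[c], int(sel.sum()), lose, gain, ties,
             ratio, not np.isfinite(ratio))
        )
    return pd.DataFrame(
        rows, columns=["label", "n_bins", "lose", "gain", "ties", "sigma", "undefined"]
    )
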