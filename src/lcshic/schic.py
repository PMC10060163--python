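"""Single-cell Hi-C: QC, per-cell LCS scoring, chromosome-pair
ranking, simplified compartment imputation and pseudo-bulk comparison.

The per-cell loss-of-chromatin-segregation score is
LCS(x) = LS(x) / (LL(x) + SS(x)), computed on the cell's
iteratively-corrected 23x23 chromosome-pair matrix: balanced
long-short interactions over balanced long-long plus short-short
interactions. Higher scores mean weaker chromosome-territory
segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .contacts import CellContactSet
from .genome import CHROM_ORDER, DEFAULT_LONG_SET, DEFAULT_SHORT_SET, GenomeSpec
from .interchrom import aggregate_interchrom, ice_balance, pair_category

#: QC defaults: singleton fraction above 75% or fewer than 100,000
#: unfiltered interactions removes a cell.
MAX_SINGLETON_FRACTION = 0.75
MIN_UNFILTERED = 100_000


def qc_filter_cells(
    cells: list[CellContactSet],
    max_singleton_fraction: float = MAX_SINGLETON_FRACTION,
    min_unfiltered: int = MIN_UNFILTERED,
) -> tuple[list[CellContactSet], pd.DataFrame]:
    """Quality-filter cells and their contacts.

    A cell is removed when its singleton fraction exceeds
    ``max_singleton_fraction`` or it has fewer than ``min_unfiltered``
    interactions (strict). In retained cells, singleton contacts
    (read support 1) are dropped and duplicate records of the same
    contact collapse to one. Returns retained cells and the QC table.
    """
    retained, table = [], []
    for cell in cells:
        c = cell.contacts
        n_unfiltered = len(c)
        singleton = (c["read_support"] < 2).mean() if n_unfiltered else 1.0
        keep = singleton <= max_singleton_fraction and n_unfiltered >= min_unfiltered
        n_retained = 0
        if keep:
            filt = c[c["read_support"] >= 2]
            dedup = filt.drop_duplicates(
                subset=["chrom1", "pos1", "chrom2", "pos2"]
            ).reset_index(drop=True)
            n_retained = len(dedup)
            out = CellContactSet(cell.cell_id, dedup, qc={
                "n_unfiltered": n_unfiltered,
                "singleton_fraction": float(singleton),
                "n_retained": n_retained,
                "retained": True,
            })
            retained.append(out)
        table.append((cell.cell_id, n_unfiltered, float(singleton), n_retained, keep))
    qc = pd.DataFrame(
        table,
        columns=["cell_id", "n_unfiltered", "singleton_fraction", "n_contacts", "retained"],
    )
    return retained, qc


def _balanced_category_sums(
    cell: CellContactSet,
    order=CHROM_ORDER,
    long_set=DEFAULT_LONG_SET,
    short_set=DEFAULT_SHORT_SET,
) -> dict[str, float]:
    pair = aggregate_interchrom(cell, order=order)
    balanced = ice_balance(pair)
    sums = {"LL": 0.0, "LS": 0.0, "SS": 0.0}
    off = balanced.offdiag()
    n = len(order)
    for i in range(n):
        for j in range(i + 1, n):
            sums[pair_category(order[i], order[j], long_set, short_set)] += off[i, j]
    return sums


def lcs_score(
    cell: CellContactSet,
    order=CHROM_ORDER,
    long_set=DEFAULT_LONG_SET,
    short_set=DEFAULT_SHORT_SET,
) -> float:
    """Per-cell LCS score LS / (LL + SS) on balanced interactions.

    Raises when LL + SS is zero (undefined score).
    """
    sums = _balanced_category_sums(cell, order, long_set, short_set)
    denom = sums["LL"] + sums["SS"]
    if denom == 0:
        raise ValueError(f"cell {cell.cell_id}: LL + SS is zero; LCS undefined")
    return sums["LS"] / denom


def pair_rank_profile(cells: list[CellContactSet], order=CHROM_ORDER) -> pd.DataFrame:
    """Average rank of each chromosome pair by balanced interactions.

    Within each cell the unordered chromosome pairs are ranked by
    balanced count (rank 1 = most interacting; ties share the mean of
    tied ranks); ranks are averaged across cells.
    """
    if not cells:
        raise ValueError("no cells")
    n = len(order)
    iu = np.triu_indices(n, 1)
    acc = np.zeros(iu[0].size)
    for cell in cells:
        balanced = ice_balance(aggregate_interchrom(cell, order=order))
        vals = balanced.offdiag()[iu]
        acc += stats.rankdata(-vals, method="average")
    acc /= len(cells)
    return pd.DataFrame({
        "chrom1": [order[i] for i in iu[0]],
        "chrom2": [order[j] for j in iu[1]],
        "avg_rank": acc,
    })


# ---------------------------------------------------------------------------
# compartment imputation
# ---------------------------------------------------------------------------

def oe_log_binned(matrix: np.ndarray) -> np.ndarray:
    """Observed/expected with a log-spaced distance-decay profile.

    Distances are grouped into base-2 logarithmically increasing bins
    ({0}, {1}, {2,3}, {4..7}, ...); each pixel is divided by the mean
    of its distance group.
    """
    n = matrix.shape[0]
    i, j = np.indices((n, n))
    d = np.abs(i - j)
    group = np.zeros_like(d)
    nz = d > 0
    group[nz] = np.floor(np.log2(d[nz])).astype(int) + 1
    oe = np.full((n, n), np.nan)
    for g in np.unique(group):
        sel = group == g
        mean = matrix[sel].mean()
        if mean > 0:
            oe[sel] = matrix[sel] / mean
    return oe


@dataclass
class CellCompartmentCall:
    """Per-chromosome compartment imputation for one cell.

    ``per_chrom`` maps chromosome -> DataFrame(bin, pc1, pc2, ab_call,
    bulk_ab); ``silhouette``/``ari`` map chromosome -> score. A
    chromosome passes when its cluster agreement (adjusted Rand index
    against the bulk A/B assignment) is positive.
    """

    cell_id: str
    per_chrom: dict[str, pd.DataFrame] = field(default_factory=dict)
    silhouette: dict[str, float] = field(default_factory=dict)
    ari: dict[str, float] = field(default_factory=dict)

    def passed(self, chrom: str) -> bool:
        return self.ari.get(chrom, -1.0) > 0


def compartment_call_from_matrix(
    intra: np.ndarray,
    bulk_ab: np.ndarray,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float] | None:
    """Impute A/B structure of one chromosome's binned cell matrix.

    Zero-marginal bins are removed; the O/E matrix (log-spaced decay
    profile) is centred by subtracting 1, bin-bin Pearson correlations
    are computed, and the first two principal components of the
    correlation matrix give each bin a 2D coordinate. The silhouette
    score between the bulk-assigned A and B point sets measures
    compartment segregation; KMeans (k=2) clusters, relabelled to
    best match bulk, give the cell's own A/B calls scored by adjusted
    Rand index. Returns None when fewer than 4 usable bins or a single
    bulk class remains.
    """
    marginal = intra.sum(axis=1)
    keep = marginal > 0
    if keep.sum() < 4:
        return None
    sub = intra[np.ix_(keep, keep)]
    labels = np.asarray(bulk_ab)[keep]
    if len(set(labels)) < 2:
        return None
    oe = oe_log_binned(sub)
    centred = np.nan_to_num(oe - 1.0, nan=0.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(centred)
    corr = np.nan_to_num(corr, nan=0.0)
    x = corr - corr.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pcs = x @ vt[:2].T
    a_ind = (labels == "A").astype(float)
    if np.std(a_ind) > 0 and np.corrcoef(pcs[:, 0], a_ind)[0, 1] < 0:
        pcs[:, 0] *= -1
    sil = float(silhouette_score(pcs, labels))
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pcs)
    ari = float(adjusted_rand_score(labels, km.labels_))
    # relabel clusters so that cluster 'A' best matches bulk A
    a_frac = [np.mean(a_ind[km.labels_ == c]) if (km.labels_ == c).any() else 0.0
              for c in (0, 1)]
    a_cluster = int(np.argmax(a_frac))
    calls = np.where(km.labels_ == a_cluster, "A", "B")
    df = pd.DataFrame({
        "bin": np.flatnonzero(keep),
        "pc1": pcs[:, 0],
        "pc2": pcs[:, 1],
        "ab_call": calls,
        "bulk_ab": labels,
    })
    return df, sil, ari


def impute_cell_compartments(
    cell: CellContactSet,
    bulk_ab: dict[str, np.ndarray],
    genome: GenomeSpec,
    bin_size: int = 1_000_000,
    seed: int = 0,
) -> CellCompartmentCall:
    """Run compartment imputation on every chromosome of one cell."""
    coarse = GenomeSpec(
        chromosomes=genome.chromosomes,
        bin_size=bin_size,
        long_set=genome.long_set,
        short_set=genome.short_set,
    )
    matrix = cell.to_matrix(coarse)
    call = CellCompartmentCall(cell_id=cell.cell_id)
    for chrom in coarse.chrom_names:
        if chrom not in bulk_ab:
            continue
        res = compartment_call_from_matrix(matrix.intra(chrom), bulk_ab[chrom], seed)
        if res is None:
            continue
        df, sil, ari = res
        call.per_chrom[chrom] = df
        call.silhouette[chrom] = sil
        call.ari[chrom] = ari
    return call


def bulk_ab_from_ranks(
    genome: GenomeSpec, bin_size: int = 1_000_000
) -> dict[str, np.ndarray]:
    """Aggregate 50 kb compartment ranks into per-``bin_size`` A/B labels
    (A where the mean rank is >= 0.5)."""
    out = {}
    factor = bin_size // genome.bin_size
    for chrom in genome.chrom_names:
        track = genome.rank_track[chrom]
        n_coarse = -(-track.size // factor)
        means = np.array([
            np.nanmean(track[k * factor:(k + 1) * factor]) for k in range(n_coarse)
        ])
        out[chrom] = np.where(means >= 0.5, "A", "B")
    return out


def cell_compartment_consistency(
    calls: list[CellCompartmentCall],
) -> pd.DataFrame:
    """Per-bin consistency of A/B calls across cells.

    Chromosomes with non-positive bulk agreement are excluded per
    cell. For each (chrom, bin), consistency = max(A, B) / (A + B)
    over the cells contributing a call.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        for chrom, df in call.per_chrom.items():
            if not call.passed(chrom):
                continue
            for b, ab in zip(df["bin"], df["ab_call"]):
                a, total = counts.setdefault((chrom, int(b)), [0, 0])
                counts[(chrom, int(b))] = [a + (ab == "A"), total + 1]
    rows = [
        (chrom, b, total, max(a, total - a) / total)
        for (chrom, b), (a, total) in sorted(counts.items())
        if total > 0
    ]
    return pd.DataFrame(rows, columns=["chrom", "bin", "n_cells", "consistency"])


# ---------------------------------------------------------------------------
# pseudo-bulk
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulk:
    """Summed interchromosomal counts of one condition with O/E and
    row-correlation matrices."""

    order: tuple[str, ...]
    counts: np.ndarray           # 23x23 summed, diagonal zeroed
    oe: np.ndarray               # I / E with E_ij = C_i C_j / 2N
    rho: np.ndarray              # Spearman correlation of OE rows
    mask: np.ndarray             # zero-marginal chromosomes


def pseudo_bulk(cells: list[CellContactSet], order=CHROM_ORDER) -> PseudoBulk:
    if not cells:
        raise ValueError("no cells")
    n = len(order)
    counts = np.zeros((n, n))
    for cell in cells:
        counts += aggregate_interchrom(cell, order=order).counts
    np.fill_diagonal(counts, 0.0)
    c = counts.sum(axis=1)
    mask = c == 0
    total = counts.sum() / 2  # N: each interaction counted once
    oe = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.outer(c, c) / (2 * total)
        ok = e > 0
        oe[ok] = counts[ok] / e[ok]
    np.fill_diagonal(oe, np.nan)
    rho = np.full((n, n), np.nan)
    for i in range(n):
        if mask[i]:
            continue
        rho[i, i] = 1.0
        for j in range(i + 1, n):
            if mask[j]:
                continue
            cols = np.array([k for k in range(n) if k not in (i, j) and not mask[k]])
            r = stats.spearmanr(oe[i, cols], oe[j, cols]).statistic
            rho[i, j] = rho[j, i] = r
    return PseudoBulk(tuple(order), counts, oe, rho, mask)


def pseudo_bulk_compare(
    cells_a: list[CellContactSet],
    cells_b: list[CellContactSet],
    order=CHROM_ORDER,
) -> tuple[PseudoBulk, PseudoBulk, np.ndarray]:
    """Pseudo-bulk both conditions and their correlation difference
    sigma = log2((rho_b + 1) / (rho_a + 1))."""
    pa = pseudo_bulk(cells_a, order)
    pb = pseudo_bulk(cells_b, order)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.log2((pb.rho + 1.0) / (pa.rho + 1.0))
    return pa, pb, sigma
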