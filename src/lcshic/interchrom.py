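"""Chromosome-scale interchromosomal analysis.

Contacts are aggregated to a 23x23 chromosome-pair matrix, balanced by
iterative correction so that every chromosome's off-diagonal marginal
equals 1, and compared between conditions as log2 ratios split into
long-long / long-short / short-short categories. Also implements the
haplotype-phased trans/cis ratio expected to rise by 4/3 after
whole-genome doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import CellContactSet, ContactMatrix
from .genome import CHROM_ORDER, DEFAULT_LONG_SET, DEFAULT_SHORT_SET
from .synthetic import PhasedContactCounts


class BalanceError(RuntimeError):
    """Iterative correction failed to converge."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"iterative correction did not converge in {max_iter} iterations "
            f"(last residual {residual:.3g})"
        )


@dataclass
class ChromPairMatrix:
    """Symmetric chromosome-pair contact totals.

    The diagonal carries intra-chromosomal totals; they are excluded
    from all interchromosomal statistics and from balancing.
    """

    order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.order)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match chromosome order")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("chromosome-pair matrix must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise ValueError("chromosome-pair matrix must be non-negative")

    def offdiag(self) -> np.ndarray:
        out = self.counts.astype(float).copy()
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class BalancedChromPairMatrix(ChromPairMatrix):
    """Chromosome-pair matrix after iterative correction: every
    unmasked chromosome's off-diagonal marginal sums to 1."""

    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def marginals(self) -> np.ndarray:
        return self.offdiag().sum(axis=1)


def aggregate_interchrom(
    contacts: ContactMatrix | CellContactSet | pd.DataFrame,
    order: tuple[str, ...] = CHROM_ORDER,
) -> ChromPairMatrix:
    """Aggregate contacts between each pair of chromosomes.

    Accepts a bulk contact matrix, a single cell, or a raw record
    table with columns chrom1/chrom2 (and optional count).
    Intra-chromosomal records populate only the diagonal.
    """
    if isinstance(contacts, ContactMatrix):
        native = tuple(contacts.genome.chrom_names)
        totals = contacts.chrom_pair_totals()
        if native == tuple(order):
            return ChromPairMatrix(tuple(order), totals)
        idx = []
        for name in order:
            if name not in native:
                raise ValueError(f"chromosome {name!r} absent from contact map")
            idx.append(native.index(name))
        idx = np.array(idx)
        return ChromPairMatrix(tuple(order), totals[np.ix_(idx, idx)])

    if isinstance(contacts, CellContactSet):
        records = contacts.contacts
    else:
        records = contacts
    pos = {name: k for k, name in enumerate(order)}
    n = len(order)
    counts = np.zeros((n, n))
    c1 = records["chrom1"].to_numpy()
    c2 = records["chrom2"].to_numpy()
    w = records["count"].to_numpy(dtype=float) if "count" in records else np.ones(len(records))
    for name in pd.unique(np.concatenate([c1, c2])):
        if name not in pos:
            raise ValueError(f"unknown chromosome name in contact records: {name!r}")
    i = np.array([pos[c] for c in c1])
    j = np.array([pos[c] for c in c2])
    np.add.at(counts, (np.minimum(i, j), np.maximum(i, j)), w)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ChromPairMatrix(tuple(order), counts)


def _sinkhorn(
    offdiag: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric iterative proportional scaling toward unit marginals.

    Returns (balanced, weights, mask); masked rows (zero marginal) are
    left out of the constraint and zeroed.
    """
    w = offdiag.astype(float).copy()
    mask = w.sum(axis=1) == 0
    w[mask, :] = 0.0
    w[:, mask] = 0.0
    weights = np.ones(w.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        m = w.sum(axis=1)
        m[mask] = 1.0
        residual = float(np.max(np.abs(m[~mask] - 1.0))) if (~mask).any() else 0.0
        if residual <= tol:
            return w, weights, mask
        s = np.sqrt(m)
        w /= np.outer(s, s)
        weights *= s
    raise BalanceError(residual, max_iter)


def ice_balance(
    matrix: ChromPairMatrix, max_iter: int = 200, tol: float = 1e-8
) -> BalancedChromPairMatrix:
    """Iterative correction of the chromosome-pair matrix.

    Balancing acts on off-diagonal entries only; chromosomes with zero
    interchromosomal counts are masked and reported via ``mask``.
    """
    balanced, weights, mask = _sinkhorn(matrix.offdiag(), tol, max_iter)
    return BalancedChromPairMatrix(
        order=matrix.order, counts=balanced, weights=weights, mask=mask
    )


def balance_10mb_interchrom(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a bin-level interchromosomal map to unit bin marginals.

    Intra-chromosomal blocks are removed before balancing (each bin's
    marginal counts interchromosomal interactions only), matching the
    normalisation used for 10 Mb visualisation maps. Returns the
    balanced dense matrix and the mask of excluded (all-zero) bins.
    """
    genome = matrix.genome
    w = matrix.data.astype(float).copy()
    off = genome.chrom_offsets()
    for name in genome.chrom_names:
        a = off[name]
        b = a + genome.n_bins(name)
        w[a:b, a:b] = 0.0
    balanced, _, mask = _sinkhorn(w, tol, max_iter)
    return balanced, mask


@dataclass
class InterchromComparison:
    """log2 ratio matrix between two balanced conditions plus the
    long/short category comparison."""

    order: tuple[str, ...]
    ratio: np.ndarray              # log2(b/a), NaN on diagonal/masked
    categories: pd.DataFrame       # chrom1, chrom2, category, log2_ratio
    pvalues: pd.DataFrame          # category1, category2, mannwhitney_p


def pair_category(chrom_a: str, chrom_b: str, long_set=DEFAULT_LONG_SET,
                  short_set=DEFAULT_SHORT_SET) -> str:
    cls = {True: "L", False: "S"}
    a = cls[chrom_a in long_set]
    b = cls[chrom_b in long_set]
    return "".join(sorted((a, b)))  # LL, LS or SS


def interchrom_log_ratio(
    balanced_a: BalancedChromPairMatrix,
    balanced_b: BalancedChromPairMatrix,
    long_set=DEFAULT_LONG_SET,
    short_set=DEFAULT_SHORT_SET,
) -> InterchromComparison:
    """R = log2(balanced_b / balanced_a) on unmasked off-diagonal pairs,
    with Mann-Whitney tests between LL/LS/SS categories.

    Zero-denominator entries are masked (NaN) and excluded from the
    category statistics.
    """
    if balanced_a.order != balanced_b.order:
        raise ValueError("chromosome orders differ")
    n = len(balanced_a.order)
    a = balanced_a.offdiag()
    b = balanced_b.offdiag()
    ratio = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (b > 0)
        ratio[ok] = np.log2(b[ok] / a[ok])
    np.fill_diagonal(ratio, np.nan)
    masked = balanced_a.mask | balanced_b.mask
    ratio[masked, :] = np.nan
    ratio[:, masked] = np.nan

    rows = []
    for i, j in combinations(range(n), 2):
        if np.isnan(ratio[i, j]):
            continue
        cat = pair_category(balanced_a.order[i], balanced_a.order[j], long_set, short_set)
        rows.append((balanced_a.order[i], balanced_a.order[j], cat, ratio[i, j]))
    cats = pd.DataFrame(rows, columns=["chrom1", "chrom2", "category", "log2_ratio"])

    prow = []
    for c1, c2 in combinations(("LL", "LS", "SS"), 2):
        x = cats.loc[cats["category"] == c1, "log2_ratio"]
        y = cats.loc[cats["category"] == c2, "log2_ratio"]
        if len(x) and len(y):
            if x.nunique() <= 1 and y.nunique() <= 1 and set(x.unique()) == set(y.unique()):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        else:
            p = np.nan
        prow.append((c1, c2, p))
    pvals = pd.DataFrame(prow, columns=["category1", "category2", "mannwhitney_p"])
    return InterchromComparison(balanced_a.order, ratio, cats, pvals)


def cis_trans_ratio(
    control: PhasedContactCounts, wgd: PhasedContactCounts
) -> tuple[float, float, float]:
    """Trans/cis phased ratio per condition and their fold change.

    r = trans / (cis_hap1 + cis_hap2); the homolog-doubling model
    predicts fold = (4T/6C) / (T/2C) = 4/3.
    """
    for counts in (control, wgd):
        if counts.hap1_hap1 + counts.hap2_hap2 <= 0:
            raise ValueError("cis counts are zero; trans/cis ratio undefined")
    r_control = control.hap1_hap2 / (control.hap1_hap1 + control.hap2_hap2)
    r_wgd = wgd.hap1_hap2 / (wgd.hap1_hap1 + wgd.hap2_hap2)
    return r_control, r_wgd, r_wgd / r_control
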