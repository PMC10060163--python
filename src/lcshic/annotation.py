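"""Relating CoREs to gene expression and chromatin-mark signal.

Genes are associated to the 50 kb bin containing their transcription
start site. Differential-expression enrichment on CoREs and the
correlation between CoRE scores and chromatin-signal differences are
assessed with empirical permutation nulls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .insulation import Boundary, InsulationTrack

GENE_COLUMNS = ["id", "chrom", "strand", "tss", "de_status", "log2fc"]


def tss_from_interval(start: int, end: int, strand: str) -> int:
    """TSS of a gene interval: start on '+', end on '-'."""
    return start if strand == "+" else end


def bin_signal(
    track: pd.DataFrame, bin_size: int = 50_000
) -> pd.DataFrame:
    """Bin a high-resolution signal track to ``bin_size``.

    Per source interval the value is log2(x + 1)-scaled; scaled values
    falling in each bin are averaged, then each bin is divided by its
    chromosome's median binned value. Returns chrom, bin, start, value.
    All-zero chromosomes have undefined normalisation and are flagged
    with NaN values.
    """
    if (track["value"] < 0).any():
        raise ValueError("signal must be non-negative")
    df = track.copy()
    df["scaled"] = np.log2(df["value"] + 1.0)
    df["bin"] = df["start"] // bin_size
    binned = (
        df.groupby(["chrom", "bin"], sort=True)["scaled"].mean().rename("value").reset_index()
    )
    out = []
    for chrom, sub in binned.groupby("chrom", sort=True):
        med = sub["value"].median()
        vals = sub["value"] / med if med > 0 else np.nan
        out.append(pd.DataFrame({
            "chrom": chrom,
            "bin": sub["bin"],
            "start": sub["bin"] * bin_size,
            "value": vals,
        }))
    return pd.concat(out, ignore_index=True)


def _gene_bins(genes: pd.DataFrame, bin_size: int) -> np.ndarray:
    return genes["tss"].to_numpy() // bin_size


def _overlap_flags(
    genes: pd.DataFrame, cores: pd.DataFrame, bin_size: int, proximity: int
) -> np.ndarray:
    """True where a gene's TSS bin intersects a CoRE span (+- proximity)."""
    flags = np.zeros(len(genes), dtype=bool)
    gb = _gene_bins(genes, bin_size)
    gchrom = genes["chrom"].to_numpy()
    for core in cores.itertuples(index=False):
        lo = (core.start - proximity) // bin_size
        hi = -(-(core.end + proximity) // bin_size)
        flags |= (gchrom == core.chrom) & (gb >= lo) & (gb < hi)
    return flags


def de_core_enrichment(
    genes: pd.DataFrame,
    cores: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    bin_size: int = 50_000,
    proximity: int = 0,
) -> pd.DataFrame:
    """Enrichment of DE genes on CoREs, one row per (DE x CoRE) class.

    Effect size: log2 of the percentage of DE genes of a direction
    overlapping CoREs of a direction over the percentage among all
    genes. Null: random gene sets of the same size drawn from all
    genes (sampled as hypergeometric overlap counts, which is the
    exact permutation distribution); empirical p is the fraction of
    null sets with overlap percentage >= observed.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    rows = []
    for core_dir in ("activating", "inactivating"):
        sub_cores = cores[cores["direction"] == core_dir]
        overlap = _overlap_flags(genes, sub_cores, bin_size, proximity)
        background_pct = overlap.mean()
        for de_dir in ("up", "down"):
            de_mask = (genes["de_status"] == de_dir).to_numpy()
            n_de = int(de_mask.sum())
            if n_de == 0 or background_pct == 0:
                rows.append((core_dir, de_dir, n_de, np.nan, np.nan, True))
                continue
            obs = int((overlap & de_mask).sum())
            obs_pct = obs / n_de
            effect = np.log2(obs_pct / background_pct) if obs_pct > 0 else -np.inf
            null = rng.hypergeometric(
                int(overlap.sum()), n_genes - int(overlap.sum()), n_de, size=n_perm
            )
            p = float((null >= obs).mean())
            rows.append((core_dir, de_dir, n_de, effect, p, False))
    return pd.DataFrame(
        rows,
        columns=["core_direction", "de_direction", "n_de", "effect", "p", "undefined"],
    )


def _region_mean_signal(
    signal: dict[str, np.ndarray], chrom: str, start: int, end: int, bin_size: int
) -> float:
    vec = signal.get(chrom)
    if vec is None:
        return np.nan
    b0 = start // bin_size
    b1 = min(-(-end // bin_size), vec.size)
    if b1 <= b0:
        return np.nan
    vals = vec[b0:b1]
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan


def signal_core_correlation(
    delta_signal: dict[str, np.ndarray],
    cores: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    bin_size: int = 50_000,
) -> tuple[float, float]:
    """Spearman correlation of CoRE scores with mean signal difference.

    ``delta_signal`` maps chromosome -> per-bin condition difference.
    The null re-places each CoRE uniformly on its own chromosome
    (length preserved) and recomputes the correlation; p is the
    fraction of null |rho| >= |observed rho|.
    """
    if len(cores) < 3:
        raise ValueError("need at least 3 CoREs for a correlation")
    rng = np.random.default_rng(seed)
    obs_means = np.array([
        _region_mean_signal(delta_signal, c.chrom, c.start, c.end, bin_size)
        for c in cores.itertuples(index=False)
    ])
    scores = cores["score"].to_numpy()
    ok = np.isfinite(obs_means)
    rho_obs = float(stats.spearmanr(scores[ok], obs_means[ok]).statistic)
    sizes = {c: delta_signal[c].size * bin_size for c in delta_signal}
    null = np.empty(n_perm)
    core_list = list(cores.itertuples(index=False))
    for p in range(n_perm):
        means = np.empty(len(core_list))
        for k, core in enumerate(core_list):
            span = core.end - core.start
            limit = sizes.get(core.chrom, span) - span
            start = int(rng.integers(0, max(limit, 1)))
            means[k] = _region_mean_signal(
                delta_signal, core.chrom, start, start + span, bin_size
            )
        okn = np.isfinite(means)
        null[p] = stats.spearmanr(scores[okn], means[okn]).statistic
    p_val = float((np.abs(null) >= abs(rho_obs)).mean())
    return rho_obs, p_val


def gene_compartment_context(
    genes: pd.DataFrame,
    ranks_a: dict[str, np.ndarray],
    ranks_b: dict[str, np.ndarray],
    track_a: dict[str, InsulationTrack],
    track_b: dict[str, InsulationTrack],
    boundaries_a: list[Boundary],
    bin_size: int = 50_000,
    boundary_score_max: float = -0.1,
    proximity: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene compartment change and boundary-proximity report.

    Each gene gets the rank difference (condition b - a) at its TSS
    bin, and a proximal-boundary flag when a boundary with insulation
    score below ``boundary_score_max`` lies within +-``proximity``.
    Proximal boundaries are classed as gaining insulation when their
    score decreases from a to b, losing otherwise; the report gives the
    percentage of up/down-regulated genes near each class with fold
    changes against the full gene set.
    """
    w = proximity // bin_size
    qual = [b for b in boundaries_a if b.score < boundary_score_max]
    by_chrom: dict[str, list[Boundary]] = {}
    for b in qual:
        by_chrom.setdefault(b.chrom, []).append(b)

    rows = []
    for gene in genes.itertuples(index=False):
        tss_bin = gene.tss // bin_size
        va = ranks_a.get(gene.chrom)
        vb = ranks_b.get(gene.chrom)
        d = np.nan
        if va is not None and vb is not None and tss_bin < min(va.size, vb.size):
            d = vb[tss_bin] - va[tss_bin]
        near = None
        for b in by_chrom.get(gene.chrom, []):
            if abs(b.bin - tss_bin) <= w:
                near = b
                break
        bclass = "none"
        if near is not None:
            sa = track_a[gene.chrom].scores[near.bin]
            sb = track_b[gene.chrom].scores[near.bin]
            if np.isfinite(sa) and np.isfinite(sb):
                bclass = "gaining" if sb < sa else "losing"
        rows.append((gene.id, gene.chrom, gene.de_status, d, near is not None, bclass))
    per_gene = pd.DataFrame(
        rows,
        columns=["id", "chrom", "de_status", "delta_compartment",
                 "boundary_proximal", "boundary_class"],
    )

    report_rows = []
    n_all = len(per_gene)
    for bclass in ("gaining", "losing"):
        near = per_gene[per_gene["boundary_class"] == bclass]
        pct_all = len(near) / n_all * 100 if n_all else np.nan
        for de in ("up", "down"):
            de_genes = per_gene[per_gene["de_status"] == de]
            pct = (
                (de_genes["boundary_class"] == bclass).mean() * 100
                if len(de_genes) else np.nan
            )
            fold = pct / pct_all if pct_all else np.nan
            report_rows.append((bclass, de, pct, pct_all, fold))
    report = pd.DataFrame(
        report_rows,
        columns=["boundary_class", "de_direction", "pct_de", "pct_all", "fold"],
    )
    return per_gene, report
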