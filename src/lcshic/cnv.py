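"""Copy-number calling from Hi-C coverage.

Broad CNVs are imputed from the per-bin contact coverage of a Hi-C
map: gap/low-coverage bins are masked, coverage is normalised by the
chromosome median, segmented by binary changepoint segmentation, and
each segment is scored by the median of its genome-wide-normalised
coverage w_s; segments with |w_s - 1| >= t are called gains (w_s > 1)
or losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import changepoint
from .contacts import CellContactSet, ContactMatrix
from .genome import GenomeSpec


@dataclass(frozen=True)
class CNVParams:
    """bin_size in bp; gamma scales the MAD low-coverage cutoff;
    t is the minimum |w_s - 1| for a CNV call."""

    bin_size: int
    gamma: float
    t: float
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.t <= 0 or self.bin_size <= 0:
            raise ValueError("bin_size, gamma and t must be positive")


#: Parameterisations used for bulk colonies, phased reads and single cells.
PRESETS = {
    "bulk": CNVParams(bin_size=2_000_000, gamma=7.0, t=0.4),
    "phased": CNVParams(bin_size=2_000_000, gamma=4.0, t=0.4),
    "schic": CNVParams(bin_size=5_000_000, gamma=4.0, t=0.4),
}


@dataclass
class CoverageTrack:
    """Masked, per-chromosome-normalised Hi-C coverage."""

    genome: GenomeSpec
    coverage: np.ndarray          # raw per-bin coverage n_b
    mask: np.ndarray              # True = excluded (gap or low coverage)
    median: float                 # genome-wide median R over unmasked bins
    mad: float                    # unscaled median absolute deviation M
    normalized: np.ndarray        # n_b / chromosome median, NaN where masked


def coverage_track(
    matrix: ContactMatrix,
    gaps: pd.DataFrame | None = None,
    gamma: float = 7.0,
) -> CoverageTrack:
    """Mask gap bins and low-coverage bins (n_b < R - gamma * M), then
    normalise by chromosome medians."""
    genome = matrix.genome
    cov = matrix.coverage().astype(float)
    mask = np.zeros(cov.size, dtype=bool)
    # partial terminal bins have structurally reduced coverage
    offsets = genome.chrom_offsets()
    for chrom in genome.chrom_names:
        if genome.length(chrom) % genome.bin_size:
            mask[offsets[chrom] + genome.n_bins(chrom) - 1] = True
    if gaps is not None and len(gaps):
        offsets = genome.chrom_offsets()
        for row in gaps.itertuples(index=False):
            if row.chrom not in offsets:
                continue
            b0 = offsets[row.chrom] + row.start // genome.bin_size
            b1 = offsets[row.chrom] + (-(-row.end // genome.bin_size))
            mask[b0:b1] = True
    median = float(np.median(cov[~mask]))
    mad = float(np.median(np.abs(cov[~mask] - median)))
    mask |= cov < median - gamma * mad
    # recompute stats on the final unmasked set
    median = float(np.median(cov[~mask]))
    mad = float(np.median(np.abs(cov[~mask] - median)))
    normalized = np.full(cov.size, np.nan)
    offsets = genome.chrom_offsets()
    for chrom in genome.chrom_names:
        a = offsets[chrom]
        b = a + genome.n_bins(chrom)
        sel = ~mask[a:b]
        if sel.any():
            chrom_median = np.median(cov[a:b][sel])
            if chrom_median > 0:
                normalized[a:b][sel] = cov[a:b][sel] / chrom_median
    return CoverageTrack(genome, cov, mask, median, mad, normalized)


def call_cnv(
    contacts: ContactMatrix | CellContactSet,
    gaps: pd.DataFrame | None = None,
    params: CNVParams = PRESETS["bulk"],
    genome: GenomeSpec | None = None,
) -> pd.DataFrame:
    """CNV segments from Hi-C coverage.

    Coverage (total contact ends per bin, cis + trans) is computed at
    ``params.bin_size``; segmentation runs on the chromosome-median-
    normalised coverage of each chromosome's unmasked bins, and a
    chromosome without accepted breakpoints is one segment. Returns a
    BED-like DataFrame (chrom, start, end, w_s, call) of segments with
    |w_s - 1| >= t.
    """
    if isinstance(contacts, CellContactSet):
        if genome is None:
            raise ValueError("genome required to bin cell contacts")
        matrix = contacts.to_matrix(genome)
    else:
        matrix = contacts
    binned = matrix.coarsen(params.bin_size) if matrix.genome.bin_size != params.bin_size else matrix
    track = coverage_track(binned, gaps, params.gamma)
    g = binned.genome
    offsets = g.chrom_offsets()
    rng = np.random.default_rng(params.seed)
    rows = []
    for chrom in g.chrom_names:
        a = offsets[chrom]
        b = a + g.n_bins(chrom)
        keep = ~track.mask[a:b]
        if not keep.any():
            warnings.warn(f"{chrom}: fully masked, skipped")
            continue
        idx = np.flatnonzero(keep)
        values = track.normalized[a:b][keep]
        segs = changepoint.segment(
            values, alpha=params.cbs_alpha, n_perm=params.cbs_n_perm, rng=rng
        )
        for lo, hi in segs:
            bins = idx[lo:hi]
            w_s = float(np.median(track.coverage[a:b][bins] / track.median))
            if abs(w_s - 1.0) >= params.t:
                rows.append((
                    chrom,
                    int(bins[0]) * g.bin_size,
                    min((int(bins[-1]) + 1) * g.bin_size, g.length(chrom)),
                    w_s,
                    "gain" if w_s > 1 else "loss",
                ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "w_s", "call"])


def merge_cnv_consensus(
    cnv_lists: list[pd.DataFrame], tol: int = 50_000
) -> pd.DataFrame:
    """Consensus CNVs across samples.

    Same-type (gain/loss) intervals within +-``tol`` of one another are
    merged transitively; each consensus interval reports how many
    samples support it.
    """
    if len(cnv_lists) < 2:
        raise ValueError("consensus requires at least two samples")
    stacked = pd.concat(
        [df.assign(sample=i) for i, df in enumerate(cnv_lists)], ignore_index=True
    )
    rows = []
    for (chrom, call), sub in stacked.groupby(["chrom", "call"], sort=True):
        sub = sub.sort_values("start")
        cur = None
        for rec in sub.itertuples(index=False):
            if cur is None:
                cur = [rec.start, rec.end, {rec.sample}]
            elif rec.start <= cur[1] + tol:
                cur[1] = max(cur[1], rec.end)
                cur[2].add(rec.sample)
            else:
                rows.append((chrom, cur[0], cur[1], call, len(cur[2])))
                cur = [rec.start, rec.end, {rec.sample}]
        if cur is not None:
            rows.append((chrom, cur[0], cur[1], call, len(cur[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "call", "n_samples"])
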