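"""Synthetic Hi-C generator with known ground truth.

Bulk and single-cell contact maps are drawn from an expected matrix
combining four ingredients of 3D genome organisation:

* power-law distance decay within chromosomes;
* compartment affinity — bins of similar compartment rank interact
  preferentially, via the kernel ``exp(-|rank_i - rank_j| / tau)``;
* TAD insulation — contacts crossing a planted boundary are depleted
  by a multiplicative factor per crossing;
* chromosome territories — contacts between a long and a short
  chromosome are suppressed relative to within-class contacts.

Whole-genome doubling is modelled as a loss-of-segregation mixing
parameter ``lcs_mix`` (lambda in [0, 1]): the expected map is
``(1 - lambda) * structured + lambda * unstructured``, where the
unstructured map keeps distance decay and chromosome lengths but drops
compartment affinity, insulation and territory bias. Counts are Poisson
around the expected map; single cells are multinomial draws from it.

Planted CNVs scale expected coverage by their copy ratio; planted
compartment repositioning events (CoREs) shift the rank track of a
second condition. Replicate-level noise on compartment ranks is
segment-wise Gaussian, calibrated so that the expected-difference
vector of two replicates has standard deviation ~0.077 (the detection
threshold sigma* = 0.1 is then ~1.3x that spread).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contacts import CellContactSet, ContactMatrix
from .genome import (
    CompartmentSegmentation,
    GenomeSpec,
    default_genome_chromosomes,
    rank_to_label,
)

#: Per-replicate segment-rank noise; two independent replicates differ
#: with sd ~ 0.077 per segment.
DEFAULT_RANK_NOISE_SD = 0.054


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the bulk/single-cell Hi-C generator.

    Defaults describe a diploid control population: standard ~ d^-1
    contact decay, moderate compartment affinity, 3-fold insulation at
    boundaries, 2-fold long/short territory bias and no mixing.
    """

    decay_exponent: float = -1.0
    affinity_strength: float = 1.0
    affinity_tau: float = 0.25
    territory_bias: float = 2.0
    insulation_depth: float = 3.0
    lcs_mix: float = 0.0
    #: fraction of contacts that are intra-chromosomal (~80% cis in Hi-C)
    intra_fraction: float = 0.8
    total_contacts: int = 5_000_000
    #: log-normal sd of per-bin visibility bias (mappability / GC /
    #: fragment density); 0 = balanced map, the default, since every
    #: downstream analysis except coverage-based CNV calling takes
    #: normalised input. Raw-read analyses should simulate with ~0.3,
    #: which leaves ~10% residual coverage dispersion at 250 kb bins —
    #: the regime the median/MAD masking rule of CNV calling assumes.
    bin_bias_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lcs_mix <= 1.0:
            raise ValueError("lcs_mix must be in [0, 1]")
        if self.total_contacts <= 0:
            raise ValueError("total_contacts must be positive")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if self.territory_bias <= 0 or self.insulation_depth <= 0:
            raise ValueError("territory_bias and insulation_depth must be positive")
        if not 0.0 < self.intra_fraction < 1.0:
            raise ValueError("intra_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CompartmentConfig:
    """Shape of the planted compartment/boundary landscape.

    Segment lengths are ``min_segment_bins`` plus a geometric tail with
    the given mean; with 50 kb bins the defaults give 450 kb minimum
    and ~600 kb mean compartment domains. The minimum strictly exceeds
    the 400 kb half-window of the local-minimum boundary caller, so
    adjacent planted boundaries never fall inside each other's calling
    window (two dips within one window can yield only one minimum).
    """

    mean_segment_bins: float = 12.0
    min_segment_bins: int = 9
    active_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.mean_segment_bins <= self.min_segment_bins:
            raise ValueError("mean_segment_bins must exceed min_segment_bins")


def generate_genome(
    n_chrom: int = 23,
    chrom_lengths: list[int] | None = None,
    bin_size: int = 50_000,
    compartment_config: CompartmentConfig | None = None,
    seed: int = 0,
) -> GenomeSpec:
    """Generate a genome with a piecewise-constant compartment-rank
    track, octile labels and boundaries at compartment-segment edges.

    Segment ranks are drawn uniformly from the active half [0.5, 1]
    with probability ``active_fraction`` and from the inactive half
    otherwise, so the expected fraction of bins with rank > 0.5 equals
    ``active_fraction``.
    """
    cfg = compartment_config or CompartmentConfig()
    if chrom_lengths is None:
        chromosomes = default_genome_chromosomes(n_chrom)
    else:
        if len(chrom_lengths) != n_chrom:
            raise ValueError("chrom_lengths length must equal n_chrom")
        chromosomes = tuple(
            (name, int(length))
            for (name, _), length in zip(default_genome_chromosomes(n_chrom), chrom_lengths)
        )
    for name, length in chromosomes:
        if length < 2 * bin_size:
            raise ValueError(f"{name}: length must be at least 2 bins")

    rng = np.random.default_rng(seed)
    rank_track: dict[str, np.ndarray] = {}
    boundaries: dict[str, np.ndarray] = {}
    for name, length in chromosomes:
        n_bins = -(-length // bin_size)
        seg_lens = []
        pos = 0
        while pos < n_bins:
            extra = rng.geometric(1.0 / (cfg.mean_segment_bins - cfg.min_segment_bins))
            seg_len = min(cfg.min_segment_bins + extra - 1, n_bins - pos)
            seg_lens.append(seg_len)
            pos += seg_len
        # quota assignment keeps per-chromosome compartment composition
        # close to the requested active fraction
        n_seg = len(seg_lens)
        n_active = int(round(cfg.active_fraction * n_seg))
        active = np.zeros(n_seg, dtype=bool)
        active[:n_active] = True
        rng.shuffle(active)
        track = np.empty(n_bins)
        edges = []
        pos = 0
        for seg_len, is_active in zip(seg_lens, active):
            rank = rng.uniform(0.5, 1.0) if is_active else rng.uniform(0.0, 0.5)
            track[pos:pos + seg_len] = rank
            pos += seg_len
            if pos < n_bins:
                edges.append(pos)
        rank_track[name] = track
        boundaries[name] = np.array(edges, dtype=int)

    names = {c for c, _ in chromosomes}
    return GenomeSpec(
        chromosomes=chromosomes,
        bin_size=bin_size,
        long_set=_default_long(names),
        short_set=_default_short(names),
        rank_track=rank_track,
        boundary_positions=boundaries,
    )


def _default_long(names: set[str]) -> frozenset[str]:
    from .genome import DEFAULT_LONG_SET

    if names <= (set(DEFAULT_LONG_SET) | {f"chr{i}" for i in range(15, 23)}):
        return frozenset(n for n in names if n in DEFAULT_LONG_SET)
    # fall back: first 60% of chromosomes (by name order) are long
    ordered = sorted(names)
    cut = max(1, int(0.6 * len(ordered)))
    return frozenset(ordered[:cut])


def _default_short(names: set[str]) -> frozenset[str]:
    return frozenset(names - _default_long(names))


def plant_cores(
    genome: GenomeSpec,
    n_cores: int = 8,
    shift: float = 0.3,
    fraction_of_chrom: float = 0.3,
    min_bins: int = 10,
    seed: int = 0,
) -> GenomeSpec:
    """Plant compartment repositioning events on distinct chromosomes.

    Each event spans ``fraction_of_chrom`` of its chromosome (at least
    ``min_bins`` bins), with alternating shift sign. Spans are chosen
    where the full shift stays inside the rank range [0, 1] —
    activations land on regions with headroom toward A, inactivations
    on regions with headroom toward B — so the planted magnitude is
    realised exactly. The span fraction makes repositioning the
    dominant contribution to chromosome-level rank-difference variance
    (the regime in which mean/SD recursion can see the event), and
    keeps total planted coverage near the ~10-20%-of-genome scale of
    repositioning observed after genome doubling.
    """
    rng = np.random.default_rng(seed)
    cores = []
    k = 0
    for chrom in rng.permutation(genome.chrom_names):
        if k >= n_cores:
            break
        n_bins = genome.n_bins(chrom)
        span = max(min_bins, int(round(fraction_of_chrom * n_bins)))
        if span >= n_bins:
            span = n_bins - 2
        sgn = 1.0 if k % 2 == 0 else -1.0
        track = genome.rank_track[chrom]
        shifted = track + sgn * shift
        fits = (shifted >= 0) & (shifted <= 1)
        ok_bins = np.concatenate([[0], np.cumsum(fits)])
        n_ok = ok_bins[span:] - ok_bins[:-span]  # admissible bins per start
        admissible = np.flatnonzero(n_ok == span)
        if not admissible.size:
            continue  # no span fits the full shift on this chromosome
        start_bin = int(rng.choice(admissible))
        cores.append(
            (chrom, start_bin * genome.bin_size,
             (start_bin + span) * genome.bin_size, sgn * shift)
        )
        k += 1
    if len(cores) < n_cores:
        raise ValueError(
            f"could only place {len(cores)} of {n_cores} repositioning events; "
            "reduce shift, span or n_cores"
        )
    return replace(genome, planted_core=tuple(cores))


def plant_cnvs(
    genome: GenomeSpec,
    events: list[tuple[str, int, int, float]],
) -> GenomeSpec:
    """Attach ground-truth CNVs ``(chrom, start, end, copy_ratio)``."""
    for chrom, start, end, ratio in events:
        if ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        if not 0 <= start < end <= genome.length(chrom):
            raise ValueError(f"CNV outside {chrom}")
    return replace(genome, planted_cnv=tuple(events))


# ---------------------------------------------------------------------------
# expected maps
# ---------------------------------------------------------------------------

def _copy_factor(genome: GenomeSpec) -> np.ndarray:
    """Per-bin copy-number factor from planted CNVs (1 elsewhere)."""
    factor = np.ones(genome.total_bins)
    offsets = genome.chrom_offsets()
    for chrom, start, end, ratio in genome.planted_cnv:
        b0 = offsets[chrom] + start // genome.bin_size
        b1 = offsets[chrom] + (-(-end // genome.bin_size))
        factor[b0:b1] = ratio
    return factor


def _flatten_marginals(block: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Symmetric scaling of an intra block toward constant marginals.

    Emulates matrix balancing: per-bin expected cis coverage becomes
    uniform (as in a balanced map, and as for bins far from chromosome
    ends in real data), while distance-decay, affinity and insulation
    structure is preserved up to the row/column reweighting.
    """
    w = block.copy()
    for _ in range(n_iter):
        m = w.sum(axis=1)
        m /= m.mean()
        s = np.sqrt(m)
        w /= np.outer(s, s)
    return w


def expected_matrix(genome: GenomeSpec, params: SimulationParams) -> ContactMatrix:
    """Expected (noise-free) genome-wide contact matrix.

    The matrix sums to ``total_contacts`` over the upper triangle
    before CNV scaling; planted CNVs then scale rows/columns by their
    copy ratio.
    """
    lam = params.lcs_mix
    n = genome.total_bins
    exp = np.zeros((n, n))
    offsets = genome.chrom_offsets()
    lengths = dict(genome.chromosomes)

    # intra-chromosomal blocks
    intra_weights = np.array([lengths[c] for c in genome.chrom_names], dtype=float)
    intra_weights /= intra_weights.sum()
    for ci, chrom in enumerate(genome.chrom_names):
        nb = genome.n_bins(chrom)
        off = offsets[chrom]
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        decay = (d + 1.0) ** params.decay_exponent
        rank = genome.rank_track[chrom]
        affinity = np.exp(
            -np.abs(np.subtract.outer(rank, rank)) / params.affinity_tau
        ) ** params.affinity_strength
        bpos = genome.boundary_positions.get(chrom, np.array([], dtype=int))
        nb_count = np.searchsorted(bpos, np.arange(nb), side="right")
        crossings = np.abs(np.subtract.outer(nb_count, nb_count))
        insul = params.insulation_depth ** (-crossings.astype(float))
        structured = _flatten_marginals(decay * affinity * insul)
        unstructured = _flatten_marginals(decay)
        tri = np.triu_indices(nb)
        s_norm = structured / structured[tri].sum()
        u_norm = unstructured / unstructured[tri].sum()
        block = (1 - lam) * s_norm + lam * u_norm
        budget = params.total_contacts * params.intra_fraction * intra_weights[ci]
        exp[off:off + nb, off:off + nb] = block * budget / block[tri].sum()

    # inter-chromosomal blocks: uniform within a pair, weighted by
    # chromosome lengths and (structured part only) territory bias
    names = genome.chrom_names
    nc = len(names)
    w_struct = np.zeros((nc, nc))
    w_flat = np.zeros((nc, nc))
    for i in range(nc):
        for j in range(i + 1, nc):
            base = lengths[names[i]] * lengths[names[j]]
            cross = genome.chrom_class(names[i]) != genome.chrom_class(names[j])
            w_struct[i, j] = base / (params.territory_bias if cross else 1.0)
            w_flat[i, j] = base
    w = (1 - lam) * w_struct / w_struct.sum() + lam * w_flat / w_flat.sum()
    inter_budget = params.total_contacts * (1 - params.intra_fraction)
    for i in range(nc):
        ni = genome.n_bins(names[i])
        for j in range(i + 1, nc):
            nj = genome.n_bins(names[j])
            pair = inter_budget * w[i, j] / (ni * nj)
            exp[offsets[names[i]]:offsets[names[i]] + ni,
                offsets[names[j]]:offsets[names[j]] + nj] = pair

    iu = np.triu_indices(n, 1)
    exp[(iu[1], iu[0])] = exp[iu]

    # equalise total (cis + trans) expected coverage across bins, as in
    # a balanced map; relative intra structure and the within-row
    # territory pattern survive the row/column rescaling, and every
    # interchromosomal statistic downstream re-balances anyway
    total = exp.sum()
    exp = _flatten_marginals(exp, n_iter=15)
    exp *= total / exp.sum()

    if genome.planted_cnv:
        # symmetric scaling to target marginals: each bin's expected
        # coverage scales by exactly its copy ratio, as Hi-C read
        # depth scales with copy number
        factor = _copy_factor(genome)
        target = exp.sum(axis=1) * factor
        for _ in range(50):
            ratio = target / exp.sum(axis=1)
            if np.max(np.abs(ratio - 1.0)) < 1e-10:
                break
            root = np.sqrt(ratio)
            exp *= np.outer(root, root)

    if params.bin_bias_sd > 0:
        # independent per-bin visibility bias (log-normal, median 1)
        rng = np.random.default_rng([params.seed, 0xB1A5])
        bias = rng.lognormal(0.0, params.bin_bias_sd, size=n)
        exp *= np.outer(bias, bias)
    return ContactMatrix(genome, exp)


def simulate_bulk_hic(genome: GenomeSpec, params: SimulationParams) -> ContactMatrix:
    """Poisson-sampled bulk Hi-C contact matrix (intra + inter)."""
    expected = expected_matrix(genome, params)
    rng = np.random.default_rng(params.seed)
    n = genome.total_bins
    upper = np.triu(expected.data)
    counts = rng.poisson(upper).astype(float)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMatrix(genome, counts)


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def simulate_single_cells(
    genome: GenomeSpec,
    params: SimulationParams,
    n_cells: int,
    contacts_per_cell: int,
    lcs_positive_fraction: float,
    seed: int = 0,
    positive_lcs_mix: float = 0.5,
    dup_fraction: float = 0.6,
) -> tuple[list[CellContactSet], pd.DataFrame]:
    """Draw single cells from the expected map.

    A ``lcs_positive_fraction`` of cells is drawn with mixing level
    ``positive_lcs_mix`` instead of ``params.lcs_mix`` (the
    LCS-positive subpopulation). Returns the cells plus a ground-truth
    sidecar table (cell_id, lcs_positive, lcs_mix); no label is stored
    in the contact records themselves.

    ``dup_fraction`` of contacts receive read support >= 2 (the rest
    are singletons), to exercise downstream QC deduplication.
    """
    if contacts_per_cell < 1:
        raise ValueError("contacts_per_cell must be >= 1")
    if not 0.0 <= lcs_positive_fraction <= 1.0:
        raise ValueError("lcs_positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = genome.total_bins
    iu, ju = np.triu_indices(n)

    def pvec(lam: float) -> np.ndarray:
        e = expected_matrix(genome, replace(params, lcs_mix=lam)).data[(iu, ju)]
        return e / e.sum()

    p_neg = pvec(params.lcs_mix)
    p_pos = pvec(positive_lcs_mix) if lcs_positive_fraction > 0 else p_neg

    n_pos = int(round(n_cells * lcs_positive_fraction))
    labels = np.zeros(n_cells, dtype=bool)
    labels[rng.choice(n_cells, size=n_pos, replace=False)] = True

    cid = genome.chrom_of_bins()
    names = np.array(genome.chrom_names, dtype=object)
    starts = np.concatenate([genome.bin_starts(c) for c in genome.chrom_names])

    cells, truth = [], []
    for k in range(n_cells):
        lam = positive_lcs_mix if labels[k] else params.lcs_mix
        draw = rng.multinomial(contacts_per_cell, p_pos if labels[k] else p_neg)
        nz = np.flatnonzero(draw)
        rep = np.repeat(nz, draw[nz])
        i, j = iu[rep], ju[rep]
        support = np.ones(rep.size, dtype=int)
        dup = rng.random(rep.size) < dup_fraction
        support[dup] = 2 + rng.poisson(0.5, size=int(dup.sum()))
        cell_id = f"cell_{k:04d}"
        contacts = pd.DataFrame({
            "chrom1": names[cid[i]],
            "pos1": starts[i],
            "chrom2": names[cid[j]],
            "pos2": starts[j],
            "read_support": support,
        })
        cells.append(CellContactSet(cell_id=cell_id, contacts=contacts))
        truth.append((cell_id, bool(labels[k]), lam))
    truth_df = pd.DataFrame(truth, columns=["cell_id", "lcs_positive", "lcs_mix"])
    return cells, truth_df


# ---------------------------------------------------------------------------
# phased contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedContactCounts:
    """Haplotype-resolved contact totals: C per same-haplotype class,
    T across haplotypes."""

    hap1_hap1: float
    hap1_hap2: float
    hap2_hap2: float
    scope: str = "genome-wide"

    def __post_init__(self) -> None:
        if min(self.hap1_hap1, self.hap1_hap2, self.hap2_hap2) < 0:
            raise ValueError("phased counts must be non-negative")


def simulate_phased_contacts(
    base_cis: float,
    base_trans: float,
    wgd: bool,
    noise: float = 0.0,
    seed: int = 0,
) -> PhasedContactCounts:
    """Homolog-doubling contact model.

    A control diploid with per-haplotype cis contacts C and
    cross-haplotype contacts T emits (C, T, C). After doubling each
    haplotype to two copies, same-haplotype molecule pairs triple
    (1 -> 3 pair classes per haplotype) and cross-haplotype pairs
    quadruple (1 -> 4), so WGD emits (3C, 4T, 3C). Multiplicative
    log-normal noise with coefficient ``noise`` is applied per class.
    """
    if base_cis <= 0 or base_trans <= 0:
        raise ValueError("base counts must be positive")
    rng = np.random.default_rng(seed)
    if wgd:
        vals = np.array([3 * base_cis, 4 * base_trans, 3 * base_cis], dtype=float)
    else:
        vals = np.array([base_cis, base_trans, base_cis], dtype=float)
    if noise > 0:
        vals = vals * rng.lognormal(mean=0.0, sigma=noise, size=3)
    return PhasedContactCounts(hap1_hap1=vals[0], hap1_hap2=vals[1], hap2_hap2=vals[2])


# ---------------------------------------------------------------------------
# replicate noise on segmentations
# ---------------------------------------------------------------------------

def noisy_segmentation(
    genome: GenomeSpec,
    noise_sd: float = DEFAULT_RANK_NOISE_SD,
    seed: int = 0,
) -> CompartmentSegmentation:
    """Segmentation with segment-wise Gaussian rank noise (a replicate).

    Noise is applied per compartment segment (rank calls vary at the
    segment level between replicates, not per bin), clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, length in genome.chromosomes:
        track = genome.rank_track[name]
        change = np.flatnonzero(np.diff(track) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [track.size]])
        for s, e in zip(starts, ends):
            rank = float(np.clip(track[s] + rng.normal(0.0, noise_sd), 0.0, 1.0))
            rows.append((
                name, int(s) * genome.bin_size,
                min(int(e) * genome.bin_size, length),
                rank, rank_to_label(rank),
            ))
    return CompartmentSegmentation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "rank", "label"])
    )
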