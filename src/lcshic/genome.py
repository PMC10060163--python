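"""Binned genome model and compartment-rank segmentations.

A genome is an ordered set of chromosomes cut into fixed-size bins
(0-based, half-open; the last bin of a chromosome may be short).
Chromosomes carry a long/short class: in the human karyotype analysed
here, chr1-chr14 and chrX behave as the "long" territory cluster and
chr15-chr22 as the "short" one.

Compartment state is a continuous rank in [0, 1] per bin (0 = most
inactive / B-like, 1 = most active / A-like), discretised into eight
sub-compartment labels B.2.2 ... A.1.1 by rank octile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Eight sub-compartment labels ordered from most B-like to most A-like.
SUBCOMPARTMENT_LABELS = (
    "B.2.2", "B.2.1", "B.1.2", "B.1.1",
    "A.2.2", "A.2.1", "A.1.2", "A.1.1",
)

#: Chromosome order used for all 23x23 chromosome-pair matrices.
CHROM_ORDER = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

#: Territory classes: chr1-chr14 plus chrX are long, chr15-chr22 short.
DEFAULT_LONG_SET = frozenset(f"chr{i}" for i in range(1, 15)) | {"chrX"}
DEFAULT_SHORT_SET = frozenset(f"chr{i}" for i in range(15, 23))


def rank_to_label(rank: float) -> str:
    """Map a compartment rank in [0, 1] to its octile label.

    Ranks close to 0 map to B.2.2, ranks close to 1 to A.1.1; rank 1.0
    falls in the top octile.
    """
    if not 0.0 <= rank <= 1.0:
        raise ValueError(f"compartment rank must be in [0, 1], got {rank}")
    return SUBCOMPARTMENT_LABELS[min(int(rank * 8), 7)]


def rank_to_level(rank: np.ndarray) -> np.ndarray:
    """Vectorised octile index (0..7) of compartment ranks; NaN -> -1."""
    rank = np.asarray(rank, dtype=float)
    level = np.full(rank.shape, -1, dtype=int)
    ok = np.isfinite(rank)
    level[ok] = np.minimum((rank[ok] * 8).astype(int), 7)
    return level


@dataclass(frozen=True)
class GenomeSpec:
    """A binned genome with per-bin compartment ranks and planted truth.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp. Bins tile each chromosome; the last bin may be
        shorter than ``bin_size``.
    long_set, short_set
        Disjoint chromosome-name sets covering all chromosomes.
    rank_track
        Per-chromosome array of per-bin compartment ranks in [0, 1].
    boundary_positions
        Per-chromosome sorted bin indices of insulating boundaries.
    planted_cnv
        ``(chrom, start_bp, end_bp, copy_ratio)`` ground-truth CNVs.
    planted_core
        ``(chrom, start_bp, end_bp, rank_shift)`` ground-truth
        compartment repositioning events, applied to a second condition.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    long_set: frozenset[str] = DEFAULT_LONG_SET
    short_set: frozenset[str] = DEFAULT_SHORT_SET
    rank_track: dict[str, np.ndarray] = field(default_factory=dict)
    boundary_positions: dict[str, np.ndarray] = field(default_factory=dict)
    planted_cnv: tuple[tuple[str, int, int, float], ...] = ()
    planted_core: tuple[tuple[str, int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        all_names = set(names)
        if self.long_set | self.short_set != all_names or (self.long_set & self.short_set):
            raise ValueError("long_set and short_set must partition the chromosomes")
        for name, track in self.rank_track.items():
            if track.size and (np.nanmin(track) < 0 or np.nanmax(track) > 1):
                raise ValueError(f"rank_track of {name} outside [0, 1]")

    # -- bin bookkeeping ------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def chrom_offsets(self) -> dict[str, int]:
        """Offset of each chromosome's first bin in the genome-wide order."""
        offsets, total = {}, 0
        for name, _ in self.chromosomes:
            offsets[name] = total
            total += self.n_bins(name)
        return offsets

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def chrom_of_bins(self) -> np.ndarray:
        """Genome-wide array mapping bin index -> chromosome-order index."""
        parts = [
            np.full(self.n_bins(name), i, dtype=np.int32)
            for i, (name, _) in enumerate(self.chromosomes)
        ]
        return np.concatenate(parts)

    def chrom_class(self, chrom: str) -> str:
        return "long" if chrom in self.long_set else "short"

    # -- segmentations --------------------------------------------------

    def segmentation(self) -> "CompartmentSegmentation":
        """Piecewise-constant rank track as a compartment segmentation."""
        rows = []
        for name, length in self.chromosomes:
            track = self.rank_track[name]
            change = np.flatnonzero(np.diff(track) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [track.size]])
            for s, e in zip(starts, ends):
                rank = float(track[s])
                rows.append((
                    name, int(s) * self.bin_size,
                    min(int(e) * self.bin_size, length),
                    rank, rank_to_label(rank),
                ))
        return CompartmentSegmentation(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "rank", "label"])
        )

    def with_core_shifts(self) -> "GenomeSpec":
        """Second-condition genome with planted CoRE rank shifts applied."""
        track = {c: t.copy() for c, t in self.rank_track.items()}
        for chrom, start, end, shift in self.planted_core:
            b0 = start // self.bin_size
            b1 = -(-end // self.bin_size)
            track[chrom][b0:b1] = np.clip(track[chrom][b0:b1] + shift, 0.0, 1.0)
        return GenomeSpec(
            chromosomes=self.chromosomes,
            bin_size=self.bin_size,
            long_set=self.long_set,
            short_set=self.short_set,
            rank_track=track,
            boundary_positions=self.boundary_positions,
            planted_cnv=self.planted_cnv,
            planted_core=self.planted_core,
        )


class CompartmentSegmentation:
    """Genome segments carrying a compartment rank and octile label.

    Thin wrapper over a BED-like DataFrame with columns
    ``chrom, start, end, rank, label`` (0-based half-open intervals,
    non-overlapping and sorted within each chromosome).
    """

    COLUMNS = ["chrom", "start", "end", "rank", "label"]

    def __init__(self, df: pd.DataFrame):
        df = df[self.COLUMNS].copy()
        if ((df["rank"] < 0) | (df["rank"] > 1)).any():
            raise ValueError("segment ranks must lie in [0, 1]")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for _, sub in df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError("segments overlap")
        self.df = df

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def binned_ranks(self, chrom: str, bin_size: int, n_bins: int) -> np.ndarray:
        """Per-bin rank vector; NaN where no segment covers the bin start.

        Each bin takes the rank of the segment containing its midpoint.
        """
        out = np.full(n_bins, np.nan)
        sub = self.df[self.df["chrom"] == chrom]
        mids = np.arange(n_bins) * bin_size + bin_size // 2
        for start, end, rank in zip(sub["start"], sub["end"], sub["rank"]):
            sel = (mids >= start) & (mids < end)
            out[sel] = rank
        return out

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "CompartmentSegmentation":
        df = pd.read_csv(path, sep="\t", header=None, names=cls.COLUMNS)
        return cls(df)


def default_genome_chromosomes(
    n_chrom: int = 23,
    max_length: int = 10_000_000,
    min_length: int = 2_650_000,
) -> tuple[tuple[str, int], ...]:
    """Scaled-down karyotype: chr1..chr22 with linearly decreasing
    lengths plus a long chrX (placed at chr7 scale)."""
    if n_chrom != 23:
        step = (max_length - min_length) / max(n_chrom - 1, 1)
        return tuple(
            (f"chr{i + 1}", int(max_length - i * step)) for i in range(n_chrom)
        )
    step = (max_length - min_length) / 21
    auto = [(f"chr{i + 1}", int(max_length - i * step)) for i in range(22)]
    return tuple(auto) + (("chrX", int(max_length - 6 * step)),)
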