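"""In-memory contact containers: bulk contact matrices and per-cell
contact lists.

Bulk maps are held as a dense symmetric matrix over the genome-wide bin
order of a :class:`~lcshic.genome.GenomeSpec` (at desk scale a few
thousand bins, so dense storage is cheap and keeps every downstream
operation a slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import GenomeSpec


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix over a whole genome.

    ``data[i, j]`` is the (raw or expected) contact count between
    genome-wide bins i and j at ``genome.bin_size`` resolution.
    """

    genome: GenomeSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        n = self.genome.total_bins
        if self.data.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match {n} genome bins"
            )

    # -- views ----------------------------------------------------------

    def intra(self, chrom: str) -> np.ndarray:
        """Dense intra-chromosomal block (a view, not a copy)."""
        off = self.genome.chrom_offsets()[chrom]
        n = self.genome.n_bins(chrom)
        return self.data[off:off + n, off:off + n]

    def inter_block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        off = self.genome.chrom_offsets()
        na, nb = self.genome.n_bins(chrom_a), self.genome.n_bins(chrom_b)
        a, b = off[chrom_a], off[chrom_b]
        return self.data[a:a + na, b:b + nb]

    def chrom_pair_totals(self) -> np.ndarray:
        """Aggregate to a n_chrom x n_chrom matrix of total contacts.

        Diagonal entries hold intra-chromosomal totals (each unordered
        bin pair counted once).
        """
        cid = self.genome.chrom_of_bins()
        nc = len(self.genome.chromosomes)
        ind = sparse.csr_matrix(
            (np.ones(cid.size), (cid, np.arange(cid.size))), shape=(nc, cid.size)
        )
        out = np.asarray(ind @ self.data @ ind.T)
        # off-diagonal entries already count each unordered bin pair once;
        # intra blocks count them twice (minus the bin-level diagonal)
        diag = np.diag(out) / 2 + np.array(
            [self.intra(c).diagonal().sum() / 2 for c in self.genome.chrom_names]
        )
        np.fill_diagonal(out, diag)
        return out

    # -- resolution changes ---------------------------------------------

    def coarsen(self, new_bin_size: int) -> "ContactMatrix":
        """Aggregate counts into larger bins (integer multiple of the
        current bin size; chromosome boundaries are respected)."""
        if new_bin_size % self.genome.bin_size:
            raise ValueError("new_bin_size must be a multiple of bin_size")
        factor = new_bin_size // self.genome.bin_size
        if factor == 1:
            return ContactMatrix(self.genome, self.data.copy())
        coarse_genome = GenomeSpec(
            chromosomes=self.genome.chromosomes,
            bin_size=new_bin_size,
            long_set=self.genome.long_set,
            short_set=self.genome.short_set,
        )
        idx = []
        for name in self.genome.chrom_names:
            off = coarse_genome.chrom_offsets()[name]
            fine = np.arange(self.genome.n_bins(name))
            idx.append(off + fine // factor)
        idx = np.concatenate(idx)
        ind = sparse.csr_matrix(
            (np.ones(idx.size), (idx, np.arange(idx.size))),
            shape=(coarse_genome.total_bins, idx.size),
        )
        coarse = np.asarray(ind @ self.data @ ind.T)
        return ContactMatrix(coarse_genome, coarse)

    def coverage(self) -> np.ndarray:
        """Per-bin coverage: total contact ends falling in each bin."""
        return self.data.sum(axis=1)

    @property
    def total_contacts(self) -> float:
        """Total contacts counting each unordered bin pair once."""
        return float(np.triu(self.data).sum())

    # -- construction ---------------------------------------------------

    @classmethod
    def zeros(cls, genome: GenomeSpec) -> "ContactMatrix":
        return cls(genome, np.zeros((genome.total_bins, genome.total_bins)))

    @classmethod
    def from_records(
        cls,
        genome: GenomeSpec,
        chrom1,
        pos1,
        chrom2,
        pos2,
        count=None,
    ) -> "ContactMatrix":
        """Build a matrix from contact records (positions in bp)."""
        offsets = genome.chrom_offsets()
        n = genome.total_bins
        chrom1 = np.asarray(chrom1, dtype=object)
        chrom2 = np.asarray(chrom2, dtype=object)
        unknown = set(chrom1) | set(chrom2) - set(offsets)
        unknown -= set(offsets)
        if unknown:
            raise ValueError(f"unknown chromosome in contact records: {sorted(unknown)!r}")
        off1 = np.array([offsets[c] for c in chrom1], dtype=np.int64)
        off2 = np.array([offsets[c] for c in chrom2], dtype=np.int64)
        i = off1 + np.asarray(pos1, dtype=np.int64) // genome.bin_size
        j = off2 + np.asarray(pos2, dtype=np.int64) // genome.bin_size
        w = np.ones(i.size) if count is None else np.asarray(count, dtype=float)
        data = np.zeros((n, n))
        np.add.at(data, (i, j), w)
        data = data + data.T - np.diag(np.diag(data))
        return cls(genome, data)


@dataclass
class CellContactSet:
    """One single cell's contact records plus QC metrics.

    ``contacts`` columns: chrom1, pos1, chrom2, pos2, read_support.
    QC fields are filled by :func:`lcshic.schic.qc_filter_cells`.
    """

    cell_id: str
    contacts: pd.DataFrame
    qc: dict = field(default_factory=dict)

    REQUIRED = ("chrom1", "pos1", "chrom2", "pos2", "read_support")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.contacts.columns]
        if missing:
            raise ValueError(f"cell {self.cell_id} missing columns {missing}")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def to_matrix(self, genome: GenomeSpec) -> ContactMatrix:
        c = self.contacts
        return ContactMatrix.from_records(
            genome, c["chrom1"], c["pos1"], c["chrom2"], c["pos2"]
        )
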