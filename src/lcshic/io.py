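"""Text IO: COO triplet contact maps, pairs-like cell contacts,
bedGraph tracks and BED interval tables.

All coordinates are 0-based half-open. Contact maps travel as COO
triplet text with columns ``chrom1 start1 chrom2 start2 count`` where
the starts are bin start positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import CellContactSet, ContactMatrix
from .genome import GenomeSpec

COO_COLUMNS = ["chrom1", "start1", "chrom2", "start2", "count"]
PAIRS_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "read_support"]


def write_coo(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (including diagonal) of a contact map."""
    genome = matrix.genome
    names = genome.chrom_names
    cid = genome.chrom_of_bins()
    starts = np.concatenate([genome.bin_starts(c) for c in names])
    i, j = np.nonzero(np.triu(matrix.data))
    df = pd.DataFrame({
        "chrom1": [names[k] for k in cid[i]],
        "start1": starts[i],
        "chrom2": [names[k] for k in cid[j]],
        "start2": starts[j],
        "count": matrix.data[i, j],
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def read_coo(path, genome: GenomeSpec) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", header=None, names=COO_COLUMNS)
    return ContactMatrix.from_records(
        genome, df["chrom1"], df["start1"], df["chrom2"], df["start2"], df["count"]
    )


def write_pairs(cell: CellContactSet, path) -> None:
    cell.contacts[list(PAIRS_COLUMNS)].to_csv(path, sep="\t", index=False, header=False)


def read_pairs(path, cell_id: str) -> CellContactSet:
    df = pd.read_csv(path, sep="\t", header=None, names=PAIRS_COLUMNS)
    return CellContactSet(cell_id=cell_id, contacts=df)


def write_bedgraph(path, chroms, starts, ends, values) -> None:
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": values})
    df = df[np.isfinite(df["value"])]
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, columns) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(columns))
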