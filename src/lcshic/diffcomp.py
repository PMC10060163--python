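"""DiffComp: detection of compartment repositioning events (CoREs).

Two compartment-rank segmentations are binned at 50 kb and subtracted
(delta rank in [-1, 1]; positive = shift toward active compartments).
The delta vector is recursively segmented: a segment whose standard
deviation is below sigma* keeps its mean as repositioning score,
otherwise it is split into maximal runs above/below the segment mean
and each run is recursed. Per segment, an empirical p-value is the
fraction of replicate-null delta values exceeding the segment's max
absolute delta. Segments passing score/p/length filters are CoREs.
An alternative engine applies binary changepoint segmentation (CBS
style) to the same vector with identical scoring and filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import changepoint
from .genome import CompartmentSegmentation


@dataclass
class DeltaRankVector:
    """Per-chromosome binned compartment-rank differences (NaN = missing)."""

    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def pooled_abs(self) -> np.ndarray:
        vals = np.concatenate([v[np.isfinite(v)] for v in self.values.values()])
        return np.abs(vals)


@dataclass(frozen=True)
class DiffCompParams:
    """CoRE detection thresholds.

    sigma_star is the maximum within-segment standard deviation before
    a split (0.1, ~1.3x the spread of the replicate null); CoREs must
    have |score| >= 0.1, empirical p <= 0.01 and length >= 300 kb.
    epsilon is the minimum rank change used when tracing events
    through an intermediate time point.
    """

    sigma_star: float = 0.1
    min_abs_score: float = 0.1
    max_p: float = 0.01
    min_length: int = 300_000
    epsilon: float = 0.05
    method: str = "recursive"
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_star, self.min_abs_score, self.max_p,
               self.min_length, self.epsilon) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.method not in ("recursive", "cbs"):
            raise ValueError("method must be 'recursive' or 'cbs'")


def _chrom_bins(
    seg_x: CompartmentSegmentation, seg_y: CompartmentSegmentation, bin_size: int
) -> dict[str, int]:
    chroms = set(seg_x.chroms) & set(seg_y.chroms)
    if not chroms:
        raise ValueError("segmentations share no chromosomes")
    out = {}
    for chrom in sorted(chroms):
        end = max(
            seg_x.df.loc[seg_x.df["chrom"] == chrom, "end"].max(),
            seg_y.df.loc[seg_y.df["chrom"] == chrom, "end"].max(),
        )
        out[chrom] = -(-int(end) // bin_size)
    return out


def delta_rank(
    seg_x: CompartmentSegmentation,
    seg_y: CompartmentSegmentation,
    bin_size: int = 50_000,
) -> DeltaRankVector:
    """Per-bin rank difference C_X - C_Y; missing bins propagate NaN."""
    values = {}
    for chrom, n_bins in _chrom_bins(seg_x, seg_y, bin_size).items():
        rx = seg_x.binned_ranks(chrom, bin_size, n_bins)
        ry = seg_y.binned_ranks(chrom, bin_size, n_bins)
        values[chrom] = rx - ry
    return DeltaRankVector(bin_size=bin_size, values=values)


def segment_recursive(values: np.ndarray, sigma_star: float) -> list[tuple[int, int]]:
    """Mean/SD recursion on a gap-free vector.

    A segment with sd < sigma_star (or a single bin) terminates;
    otherwise it splits into maximal runs at or above vs below its
    mean, recursing into each run.
    """
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = values[lo:hi]
        if hi - lo == 1 or seg.std() < sigma_star:
            out.append((lo, hi))
            return
        above = seg >= seg.mean()
        change = np.flatnonzero(np.diff(above.astype(int))) + 1
        cuts = np.concatenate([[0], change, [seg.size]])
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(lo + int(a), lo + int(b))

    recurse(0, values.size)
    return sorted(out)


def call_cores(
    delta: DeltaRankVector,
    delta_expected: DeltaRankVector,
    params: DiffCompParams = DiffCompParams(),
) -> pd.DataFrame:
    """Detect CoREs on a delta-rank vector against a replicate null.

    The null is pooled genome-wide from ``delta_expected`` (built from
    two replicates of the same condition); p(s) is the fraction of null
    |values| exceeding max |delta| over the segment. Missing bins break
    segments: the recursion never spans a gap. Returns a BED-like
    DataFrame (chrom, start, end, score, p, direction, n_bins) of the
    segments passing all filters.
    """
    null_abs = delta_expected.pooled_abs()
    if null_abs.size == 0:
        raise ValueError("empty replicate null vector")
    rng = np.random.default_rng(params.seed)
    rows = []
    for chrom, vec in delta.values.items():
        finite = np.isfinite(vec)
        if not finite.any():
            continue
        # contiguous non-missing runs
        edges = np.flatnonzero(np.diff(finite.astype(int)))
        starts = np.concatenate([[0], edges + 1])
        ends = np.concatenate([edges + 1, [vec.size]])
        for run_lo, run_hi in zip(starts, ends):
            if not finite[run_lo]:
                continue
            run = vec[run_lo:run_hi]
            if params.method == "recursive":
                segs = segment_recursive(run, params.sigma_star)
            else:
                segs = changepoint.segment(
                    run, alpha=params.cbs_alpha, n_perm=params.cbs_n_perm, rng=rng
                )
            for lo, hi in segs:
                score = float(run[lo:hi].mean())
                max_abs = float(np.abs(run[lo:hi]).max())
                p = float((null_abs > max_abs).mean())
                rows.append((
                    chrom,
                    (run_lo + lo) * delta.bin_size,
                    (run_lo + hi) * delta.bin_size,
                    score, p,
                    "activating" if score > 0 else "inactivating",
                    hi - lo,
                ))
    cores = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "p", "direction", "n_bins"]
    )
    keep = (
        (cores["score"].abs() >= params.min_abs_score)
        & (cores["p"] <= params.max_p)
        & ((cores["end"] - cores["start"]) >= params.min_length)
    )
    return cores[keep].reset_index(drop=True)


def trace_cores(
    cores: pd.DataFrame,
    seg_control: CompartmentSegmentation,
    seg_mid: CompartmentSegmentation,
    params: DiffCompParams = DiffCompParams(),
    bin_size: int = 50_000,
) -> pd.DataFrame:
    """Trace CoREs through an intermediate time point.

    Per CoRE: r_control and r_mid are the mean binned ranks over the
    CoRE span in the two earlier segmentations; the final rank is
    r_control + score. The intermediate class is activating /
    inactivating when |r_mid - r_control| >= epsilon (sign decides),
    else unchanged; the final class is the CoRE's direction. A CoRE is
    consistent when intermediate and final classes are both activating
    or both inactivating.
    """
    chrom_bins = _chrom_bins(seg_control, seg_mid, bin_size)
    ranks_c = {c: seg_control.binned_ranks(c, bin_size, n) for c, n in chrom_bins.items()}
    ranks_m = {c: seg_mid.binned_ranks(c, bin_size, n) for c, n in chrom_bins.items()}
    rows = []
    for core in cores.itertuples(index=False):
        chrom = core.chrom
        if chrom not in chrom_bins:
            rows.append((chrom, core.start, core.end, core.score,
                         np.nan, np.nan, np.nan, "missing", core.direction, False, True))
            continue
        b0 = core.start // bin_size
        b1 = -(-core.end // bin_size)
        rc = ranks_c[chrom][b0:b1]
        rm = ranks_m[chrom][b0:b1]
        if not (np.isfinite(rc).any() and np.isfinite(rm).any()):
            rows.append((chrom, core.start, core.end, core.score,
                         np.nan, np.nan, np.nan, "missing", core.direction, False, True))
            continue
        r_control = float(np.nanmean(rc))
        r_mid = float(np.nanmean(rm))
        d = r_mid - r_control
        if d >= params.epsilon:
            mid_class = "activating"
        elif d <= -params.epsilon:
            mid_class = "inactivating"
        else:
            mid_class = "unchanged"
        final_class = core.direction
        consistent = mid_class == final_class and mid_class != "unchanged"
        rows.append((
            chrom, core.start, core.end, core.score,
            r_control, r_mid, r_control + core.score,
            mid_class, final_class, consistent, False,
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "score",
        "r_control", "r_wgd", "r_tumour",
        "intermediate_class", "final_class", "consistent", "trace_missing",
    ])


def trace_class_counts(traces: pd.DataFrame) -> pd.DataFrame:
    """Six-class counts (intermediate x final) over traceable CoREs."""
    ok = traces[~traces["trace_missing"]]
    counts = (
        ok.groupby(["intermediate_class", "final_class"]).size().rename("n").reset_index()
    )
    return counts


def _merge_intervals(df: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge overlapping (>= 1 bp) intervals per chromosome."""
    merged = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # book-ended intervals merge
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, int(cur_s), int(cur_e)))
    return merged


def core_overlap(
    cores_a: pd.DataFrame,
    cores_b: pd.DataFrame,
    consistent_only: bool = False,
) -> pd.DataFrame:
    """Overlap report between two CoRE sets, handled per direction.

    Same-direction CoREs from both lists are stacked and merged into
    union regions; a region is ``common`` when CoREs of that direction
    from both lists overlap it (and, with ``consistent_only``, at least
    one overlapping CoRE is flagged consistent), otherwise specific to
    the list that produced it.
    """
    rows = []
    for direction in ("activating", "inactivating"):
        a = cores_a[cores_a["direction"] == direction]
        b = cores_b[cores_b["direction"] == direction]
        if a.empty and b.empty:
            continue
        union = _merge_intervals(pd.concat([a, b], ignore_index=True))
        for chrom, start, end in union:
            hits_a = a[(a["chrom"] == chrom) & (a["start"] < end) & (a["end"] > start)]
            hits_b = b[(b["chrom"] == chrom) & (b["start"] < end) & (b["end"] > start)]
            common = not hits_a.empty and not hits_b.empty
            if common and consistent_only:
                cons = pd.concat([hits_a, hits_b])
                common = bool(cons.get("consistent", pd.Series(dtype=bool)).any())
            if common:
                status = "common"
            elif not hits_a.empty:
                status = "specific_a"
            else:
                status = "specific_b"
            rows.append((chrom, start, end, direction, status))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "status"])
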