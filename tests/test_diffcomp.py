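"""Compartment repositioning (CoRE) detection, tracing and overlap."""

import numpy as np
import pandas as pd
import pytest

import lcshic as L
from lcshic.diffcomp import (
    DeltaRankVector,
    DiffCompParams,
    call_cores,
    core_overlap,
    delta_rank,
    segment_recursive,
    trace_cores,
)
from lcshic.genome import CompartmentSegmentation

BIN = 50_000


def _seg(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rank"])
    df["label"] = [L.rank_to_label(r) for r in df["rank"]]
    return CompartmentSegmentation(df[["chrom", "start", "end", "rank", "label"]])


def _null(values=(0.05, -0.05, 0.02, -0.02), size=400):
    reps = np.resize(np.asarray(values, float), size)
    return DeltaRankVector(BIN, {"chrN": reps})


class TestDeltaRank:
    def test_identical_segmentations_give_zero(self):
        seg = _seg([("chr1", 0, 500_000, 0.4), ("chr1", 500_000, 900_000, 0.8)])
        delta = delta_rank(seg, seg, BIN)
        np.testing.assert_allclose(delta.values["chr1"], 0.0)

    def test_sign_convention_toward_active(self):
        a = _seg([("chr1", 0, 500_000, 0.9)])
        b = _seg([("chr1", 0, 500_000, 0.3)])
        delta = delta_rank(a, b, BIN)
        np.testing.assert_allclose(delta.values["chr1"], 0.6)

    def test_random_segmentations_match_per_bin_subtraction(self, genome):
        a = L.noisy_segmentation(genome, seed=1)
        b = L.noisy_segmentation(genome, seed=2)
        delta = delta_rank(a, b, BIN)
        for chrom in ("chr4", "chr21"):
            n = genome.n_bins(chrom)
            expected = (a.binned_ranks(chrom, BIN, n) - b.binned_ranks(chrom, BIN, n))
            np.testing.assert_allclose(delta.values[chrom], expected)

    def test_disjoint_chromosomes_error(self):
        a = _seg([("chr1", 0, 500_000, 0.5)])
        b = _seg([("chr2", 0, 500_000, 0.5)])
        with pytest.raises(ValueError, match="share no chromosomes"):
            delta_rank(a, b, BIN)

    def test_missing_bins_propagate(self):
        a = _seg([("chr1", 0, 200_000, 0.5), ("chr1", 400_000, 600_000, 0.5)])
        b = _seg([("chr1", 0, 600_000, 0.2)])
        delta = delta_rank(a, b, BIN)
        assert np.isnan(delta.values["chr1"][4:8]).all()  # uncovered gap in a
        np.testing.assert_allclose(delta.values["chr1"][:4], 0.3)


class TestRecursion:
    def test_constant_vector_single_core(self):
        """Constant delta of 0.3 (sd 0 < sigma*) yields one activating
        CoRE with score 0.3 and empirical p = 0."""
        delta = DeltaRankVector(BIN, {"chr1": np.full(20, 0.3)})
        cores = call_cores(delta, _null())
        assert len(cores) == 1
        core = cores.iloc[0]
        assert core["score"] == pytest.approx(0.3)
        assert core["p"] == 0.0
        assert core["direction"] == "activating"
        assert (core["start"], core["end"]) == (0, 20 * BIN)

    def test_step_vector_splits_at_step(self):
        """20 bins at +0.4 then 20 at -0.4 recurse into two opposite
        CoREs split exactly at the step."""
        delta = DeltaRankVector(BIN, {"chr1": np.r_[np.full(20, 0.4), np.full(20, -0.4)]})
        cores = call_cores(delta, _null()).sort_values("start")
        assert len(cores) == 2
        assert cores.iloc[0]["end"] == 20 * BIN == cores.iloc[1]["start"]
        assert cores.iloc[0]["score"] == pytest.approx(0.4)
        assert cores.iloc[1]["score"] == pytest.approx(-0.4)
        assert list(cores["direction"]) == ["activating", "inactivating"]

    def test_short_segment_removed_by_length_filter(self):
        """A 4-bin (200 kb) segment of score 0.5 fails the 300 kb
        minimum length."""
        delta = DeltaRankVector(BIN, {"chr1": np.r_[np.zeros(20), np.full(4, 0.5), np.zeros(20)]})
        cores = call_cores(delta, _null())
        assert cores.empty

    def test_recursion_partitions_every_bin(self, rng):
        values = rng.normal(0, 0.2, 150)
        segs = segment_recursive(values, 0.1)
        covered = np.zeros(150, dtype=int)
        for lo, hi in segs:
            covered[lo:hi] += 1
        np.testing.assert_array_equal(covered, 1)

    def test_mirrored_input_gives_negated_cores(self, rng):
        values = rng.normal(0, 0.25, 120)
        delta_pos = DeltaRankVector(BIN, {"chr1": values})
        delta_neg = DeltaRankVector(BIN, {"chr1": -values})
        params = DiffCompParams(max_p=1.0)
        a = call_cores(delta_pos, _null(), params)
        b = call_cores(delta_neg, _null(), params)
        pd.testing.assert_frame_equal(
            a.assign(score=-a["score"]).drop(columns="direction"),
            b.drop(columns="direction"),
        )

    def test_p_value_non_increasing_in_max_delta(self):
        null = _null(np.linspace(-0.3, 0.3, 100))
        rows = []
        for amp in (0.05, 0.15, 0.25, 0.35):
            delta = DeltaRankVector(BIN, {"chr1": np.full(10, amp)})
            cores = call_cores(delta, null, DiffCompParams(min_abs_score=1e-9, max_p=1.0))
            rows.append(cores.iloc[0]["p"])
        assert rows == sorted(rows, reverse=True)

    def test_missing_bins_break_segments(self):
        """The recursion never bridges a gap of missing bins."""
        vec = np.r_[np.full(10, 0.4), [np.nan] * 3, np.full(10, 0.4)]
        cores = call_cores(DeltaRankVector(BIN, {"chr1": vec}), _null())
        assert len(cores) == 2
        assert cores["end"].iloc[0] <= 10 * BIN
        assert cores["start"].iloc[1] >= 13 * BIN

    def test_empty_null_rejected(self):
        delta = DeltaRankVector(BIN, {"chr1": np.full(10, 0.3)})
        with pytest.raises(ValueError, match="null"):
            call_cores(delta, DeltaRankVector(BIN, {"chr1": np.full(5, np.nan)}))

    def test_cbs_method_agrees_on_planted_steps(self):
        """Recursive and changepoint engines find the same CoREs on a
        planted step signal (breakpoints within +-2 bins)."""
        rng = np.random.default_rng(0)
        vec = rng.normal(0, 0.04, 120)
        vec[30:60] += 0.35
        delta = DeltaRankVector(BIN, {"chr1": vec})
        rec = call_cores(delta, _null(), DiffCompParams(method="recursive"))
        cbs = call_cores(delta, _null(), DiffCompParams(method="cbs", seed=5))
        assert len(rec) == len(cbs) == 1
        assert abs(rec.iloc[0]["start"] - cbs.iloc[0]["start"]) <= 2 * BIN
        assert abs(rec.iloc[0]["end"] - cbs.iloc[0]["end"]) <= 2 * BIN
        assert np.sign(rec.iloc[0]["score"]) == np.sign(cbs.iloc[0]["score"])


class TestTracing:
    def _core(self, score, chrom="chr1", start=0, end=500_000):
        return pd.DataFrame([{
            "chrom": chrom, "start": start, "end": end,
            "score": score, "p": 0.0,
            "direction": "activating" if score > 0 else "inactivating",
            "n_bins": (end - start) // BIN,
        }])

    def test_consistent_activation(self):
        """r_control 0.20 -> r_mid 0.30 with score +0.25: activating at
        the intermediate point (0.10 >= eps) and consistent."""
        seg_c = _seg([("chr1", 0, 500_000, 0.20)])
        seg_m = _seg([("chr1", 0, 500_000, 0.30)])
        tr = trace_cores(self._core(0.25), seg_c, seg_m).iloc[0]
        assert tr["intermediate_class"] == "activating"
        assert tr["final_class"] == "activating"
        assert tr["consistent"]
        assert tr["r_tumour"] == pytest.approx(0.45)

    def test_small_intermediate_change_is_unchanged(self):
        """|r_mid - r_control| = 0.03 < eps = 0.05 -> unchanged, not
        consistent."""
        seg_c = _seg([("chr1", 0, 500_000, 0.20)])
        seg_m = _seg([("chr1", 0, 500_000, 0.23)])
        tr = trace_cores(self._core(0.25), seg_c, seg_m).iloc[0]
        assert tr["intermediate_class"] == "unchanged"
        assert not tr["consistent"]

    def test_monotonic_synthetic_trajectory_fully_consistent(self, genome):
        """Planted same-sign control -> mid -> final shifts trace as
        100% consistent."""
        g = L.plant_cores(genome, n_cores=6, shift=0.3, seed=3)
        final = g.with_core_shifts()
        # intermediate time point: half the shift
        import dataclasses

        half = dataclasses.replace(
            g, planted_core=tuple((c, s, e, sh / 2) for c, s, e, sh in g.planted_core)
        )
        seg_mid = half.with_core_shifts().segmentation()
        seg_control = g.segmentation()
        delta = delta_rank(final.segmentation(), seg_control, BIN)
        cores = call_cores(delta, _null())
        traces = trace_cores(cores, seg_control, seg_mid)
        assert len(traces) >= 6
        assert traces["consistent"].all()

    def test_core_outside_coverage_flagged_missing(self):
        seg_c = _seg([("chr1", 0, 500_000, 0.2)])
        seg_m = _seg([("chr1", 0, 500_000, 0.3)])
        tr = trace_cores(self._core(0.3, chrom="chr9"), seg_c, seg_m).iloc[0]
        assert tr["trace_missing"]


class TestOverlap:
    def _cores(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"]).assign(
            score=lambda d: np.where(d["direction"] == "activating", 0.3, -0.3)
        )

    def test_disjoint_lists_have_no_common(self):
        a = self._cores([("chr1", 0, 500_000, "activating")])
        b = self._cores([("chr1", 1_000_000, 1_500_000, "activating")])
        report = core_overlap(a, b)
        assert (report["status"] != "common").all()

    def test_opposite_directions_never_common(self):
        a = self._cores([("chr1", 0, 500_000, "activating")])
        b = self._cores([("chr1", 0, 500_000, "inactivating")])
        report = core_overlap(a, b)
        assert (report["status"] != "common").all()
        assert len(report) == 2  # one union region per direction

    def test_overlapping_same_direction_common(self):
        a = self._cores([("chr1", 0, 500_000, "activating")])
        b = self._cores([("chr1", 400_000, 900_000, "activating")])
        report = core_overlap(a, b)
        assert list(report["status"]) == ["common"]
        assert report.iloc[0]["end"] == 900_000

    def test_toy_sets_match_brute_force_merge(self, rng):
        """Random interval sets against an exhaustive bin-level oracle."""
        def random_cores(seed):
            r = np.random.default_rng(seed)
            rows = []
            for _ in range(8):
                s = int(r.integers(0, 50)) * BIN
                e = s + int(r.integers(1, 8)) * BIN
                rows.append(("chr1", s, e,
                             "activating" if r.random() < 0.5 else "inactivating"))
            return self._cores(rows)

        a, b = random_cores(1), random_cores(2)
        report = core_overlap(a, b)
        # oracle: per-direction bin occupancy
        for direction in ("activating", "inactivating"):
            occ_a = np.zeros(100, bool)
            occ_b = np.zeros(100, bool)
            for df, occ in ((a, occ_a), (b, occ_b)):
                for r in df[df["direction"] == direction].itertuples():
                    occ[r.start // BIN:r.end // BIN] = True
            union = occ_a | occ_b
            # reconstruct union regions and statuses from the report
            sub = report[report["direction"] == direction]
            occ_rep = np.zeros(100, bool)
            for r in sub.itertuples():
                seg = slice(r.start // BIN, r.end // BIN)
                occ_rep[seg] = True
                has_a, has_b = occ_a[seg].any(), occ_b[seg].any()
                expected = "common" if has_a and has_b else (
                    "specific_a" if has_a else "specific_b")
                assert r.status == expected
            np.testing.assert_array_equal(occ_rep, union)

    def test_consistent_only_requires_a_consistent_member(self):
        a = self._cores([("chr1", 0, 500_000, "activating")]).assign(consistent=False)
        b = self._cores([("chr1", 100_000, 600_000, "activating")]).assign(consistent=False)
        assert (core_overlap(a, b, consistent_only=True)["status"] != "common").all()
        b2 = b.assign(consistent=True)
        assert list(core_overlap(a, b2, consistent_only=True)["status"]) == ["common"]
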