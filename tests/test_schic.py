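"""Single-cell Hi-C QC, LCS scoring and compartment imputation."""

import numpy as np
import pandas as pd
import pytest

import lcshic as L
from lcshic.contacts import CellContactSet
from lcshic.genome import CHROM_ORDER
from lcshic.interchrom import aggregate_interchrom, ice_balance, pair_category
from lcshic.schic import (
    bulk_ab_from_ranks,
    cell_compartment_consistency,
    CellCompartmentCall,
    compartment_call_from_matrix,
    lcs_score,
    oe_log_binned,
    pair_rank_profile,
    pseudo_bulk,
    pseudo_bulk_compare,
    qc_filter_cells,
)


def _cell(rows, cell_id="c0"):
    return CellContactSet(
        cell_id,
        pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2", "read_support"]),
    )


def _bulk_cell(n, support=2, seed=0, cell_id="c0"):
    """n interchromosomal contacts spread over all chromosome pairs."""
    rng = np.random.default_rng(seed)
    chroms = np.array(CHROM_ORDER)
    i = rng.integers(0, 23, n)
    j = rng.integers(0, 23, n)
    swap = i == j
    j[swap] = (j[swap] + 1) % 23
    return _cell(
        list(zip(chroms[i], rng.integers(0, 2_000_000, n),
                 chroms[j], rng.integers(0, 2_000_000, n),
                 np.full(n, support))),
        cell_id,
    )


class TestQC:
    def test_high_singleton_fraction_removed(self):
        rows = [("chr1", 0, "chr2", 0, 1)] * 80 + [("chr1", 0, "chr3", 0, 2)] * 20
        retained, qc = qc_filter_cells([_cell(rows)], min_unfiltered=10)
        assert retained == []
        assert not qc.iloc[0]["retained"]
        assert qc.iloc[0]["singleton_fraction"] == pytest.approx(0.8)

    @pytest.mark.parametrize("n,kept", [(99_999, False), (100_000, True)])
    def test_min_interactions_boundary_is_strict(self, n, kept):
        """Fewer than 100,000 unfiltered interactions removes the cell;
        exactly 100,000 keeps it."""
        cell = _bulk_cell(n)
        retained, qc = qc_filter_cells([cell])
        assert bool(retained) is kept
        assert qc.iloc[0]["retained"] == kept

    def test_multiread_contact_collapses_to_one(self):
        rows = [("chr1", 100, "chr2", 200, 3)] * 3 + [("chr1", 500, "chr3", 0, 2)]
        retained, _ = qc_filter_cells([_cell(rows)], min_unfiltered=1)
        assert retained[0].n_contacts == 2

    def test_singleton_contacts_dropped_in_retained_cells(self):
        rows = [("chr1", 0, "chr2", 0, 1)] * 3 + [("chr1", 0, "chr3", 0, 2)] * 7
        retained, _ = qc_filter_cells([_cell(rows)], min_unfiltered=1)
        assert retained[0].n_contacts == 1
        assert (retained[0].contacts["read_support"] >= 2).all()

    def test_filter_order_independent(self):
        cells = [_bulk_cell(200, seed=s, cell_id=f"c{s}") for s in range(4)]
        fwd, _ = qc_filter_cells(cells, min_unfiltered=10)
        rev, _ = qc_filter_cells(cells[::-1], min_unfiltered=10)
        assert {c.cell_id for c in fwd} == {c.cell_id for c in rev}


class TestLCSScore:
    def test_matches_hand_computed_balanced_ratio(self):
        """LCS equals LS/(LL+SS) recomputed directly from the balanced
        chromosome-pair matrix."""
        cell = _bulk_cell(5000, seed=1)
        score = lcs_score(cell)
        balanced = ice_balance(aggregate_interchrom(cell))
        off = balanced.offdiag()
        sums = {"LL": 0.0, "LS": 0.0, "SS": 0.0}
        for i in range(23):
            for j in range(i + 1, 23):
                sums[pair_category(CHROM_ORDER[i], CHROM_ORDER[j])] += off[i, j]
        assert score == pytest.approx(sums["LS"] / (sums["LL"] + sums["SS"]))

    def test_invariant_to_duplicating_records(self):
        cell = _bulk_cell(3000, seed=2)
        doubled = CellContactSet(
            "dup", pd.concat([cell.contacts, cell.contacts], ignore_index=True)
        )
        assert lcs_score(doubled) == pytest.approx(lcs_score(cell))

    def test_positive_cells_score_higher(self, genome):
        """Simulated LCS-positive cells outscore negatives."""
        cells, truth = L.simulate_single_cells(
            genome, L.SimulationParams(seed=4), n_cells=10,
            contacts_per_cell=100_000, lcs_positive_fraction=0.5, seed=4,
        )
        retained, _ = qc_filter_cells(cells)
        order = tuple(genome.chrom_names)
        truth = truth.set_index("cell_id")
        pos, neg = [], []
        for cell in retained:
            s = lcs_score(cell, order=order, long_set=genome.long_set,
                          short_set=genome.short_set)
            (pos if truth.loc[cell.cell_id, "lcs_positive"] else neg).append(s)
        assert np.median(pos) > np.median(neg)


class TestPairRanks:
    def test_single_cell_equals_own_ranking(self):
        cell = _bulk_cell(4000, seed=3)
        profile = pair_rank_profile([cell])
        balanced = ice_balance(aggregate_interchrom(cell))
        iu = np.triu_indices(23, 1)
        from scipy.stats import rankdata

        expected = rankdata(-balanced.offdiag()[iu], method="average")
        np.testing.assert_allclose(profile["avg_rank"], expected)

    def test_planted_excess_pair_ranks_first(self):
        cells = []
        for s in range(5):
            cell = _bulk_cell(2000, seed=10 + s, cell_id=f"c{s}")
            extra = pd.DataFrame(
                [("chr1", 0, "chr2", 0, 2)] * 4000,
                columns=["chrom1", "pos1", "chrom2", "pos2", "read_support"],
            )
            cells.append(CellContactSet(
                f"c{s}", pd.concat([cell.contacts, extra], ignore_index=True)
            ))
        profile = pair_rank_profile(cells)
        top = profile.sort_values("avg_rank").iloc[0]
        assert {top["chrom1"], top["chrom2"]} == {"chr1", "chr2"}
        assert top["avg_rank"] == 1.0

    def test_ties_share_mean_rank(self):
        # two contacts on two distinct pairs, zero elsewhere
        cell = _cell([("chr1", 0, "chr2", 0, 2), ("chr3", 0, "chr4", 0, 2)])
        profile = pair_rank_profile([cell])
        ranks = profile.set_index(["chrom1", "chrom2"])["avg_rank"]
        assert ranks[("chr1", "chr2")] == ranks[("chr3", "chr4")] == 1.5


class TestCompartmentImputation:
    def test_checkerboard_silhouette_high(self):
        """A perfect two-block checkerboard separates A from B with
        silhouette > 0.9 and matching clusters."""
        n = 20
        labels = np.array(["A", "B"] * (n // 2))
        same = np.equal.outer(labels, labels)
        m = np.where(same, 8.0, 1.0) + np.eye(n)
        res = compartment_call_from_matrix(m, labels, seed=0)
        assert res is not None
        df, sil, ari = res
        assert sil > 0.9
        assert ari == pytest.approx(1.0)
        assert (df["ab_call"] == df["bulk_ab"]).all()

    def test_zero_marginal_bin_absent(self):
        n = 12
        labels = np.array(["A"] * 6 + ["B"] * 6)
        m = np.where(np.equal.outer(labels, labels), 5.0, 1.0)
        m[3, :] = m[:, 3] = 0.0
        res = compartment_call_from_matrix(m, labels, seed=0)
        df, _, _ = res
        assert 3 not in set(df["bin"])

    def test_decay_only_oe_centres_at_zero(self):
        n = 30
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 100.0 / (d + 1.0)
        oe = oe_log_binned(m)
        centred = oe - 1.0
        # per log-distance group means are exactly 0 by construction
        assert np.nanmax(np.abs(centred)) < 0.6
        assert abs(np.nanmean(centred)) < 1e-10

    def test_too_few_bins_skipped(self):
        m = np.ones((3, 3))
        assert compartment_call_from_matrix(m, np.array(["A", "B", "A"])) is None

    def test_bulk_ab_aggregation(self, genome):
        ab = bulk_ab_from_ranks(genome)
        for chrom, labels in ab.items():
            assert set(labels) <= {"A", "B"}
            assert labels.size == -(-genome.length(chrom) // 1_000_000)


class TestConsistency:
    def _call(self, cell_id, chrom, bins, calls, ari=0.5):
        df = pd.DataFrame({"bin": bins, "pc1": 0.0, "pc2": 0.0,
                           "ab_call": calls, "bulk_ab": calls})
        out = CellCompartmentCall(cell_id=cell_id)
        out.per_chrom[chrom] = df
        out.ari[chrom] = ari
        out.silhouette[chrom] = 0.5
        return out

    def test_unanimous_bin_is_one(self):
        calls = [self._call(f"c{i}", "chr1", [0], ["A"]) for i in range(4)]
        table = cell_compartment_consistency(calls)
        assert table.iloc[0]["consistency"] == 1.0

    def test_three_vs_one_gives_three_quarters(self):
        calls = [self._call(f"c{i}", "chr1", [0], ["A"]) for i in range(3)]
        calls.append(self._call("c3", "chr1", [0], ["B"]))
        table = cell_compartment_consistency(calls)
        assert table.iloc[0]["consistency"] == 0.75
        assert table.iloc[0]["n_cells"] == 4

    def test_non_positive_agreement_excluded(self):
        calls = [
            self._call("c0", "chr1", [0], ["A"], ari=0.5),
            self._call("c1", "chr1", [0], ["B"], ari=-0.1),
        ]
        table = cell_compartment_consistency(calls)
        assert table.iloc[0]["n_cells"] == 1

    def test_random_labels_concentrate_near_half(self, rng):
        n_cells = 400
        calls = [
            self._call(f"c{i}", "chr1", [0], [rng.choice(["A", "B"])])
            for i in range(n_cells)
        ]
        table = cell_compartment_consistency(calls)
        assert 0.5 <= table.iloc[0]["consistency"] < 0.5 + 3 / np.sqrt(n_cells)


class TestPseudoBulk:
    def test_identical_conditions_give_zero_sigma(self):
        cells = [_bulk_cell(3000, seed=s, cell_id=f"c{s}") for s in range(3)]
        _, _, sigma = pseudo_bulk_compare(cells, cells)
        iu = np.triu_indices(23, 1)
        np.testing.assert_allclose(np.nan_to_num(sigma[iu]), 0.0, atol=1e-12)

    def test_toy_oe_matches_hand_computation(self):
        order = ("chrA", "chrB", "chrC")
        cell = CellContactSet("c0", pd.DataFrame(
            [("chrA", 0, "chrB", 0, 2)] * 6
            + [("chrA", 0, "chrC", 0, 2)] * 2
            + [("chrB", 0, "chrC", 0, 2)] * 2,
            columns=["chrom1", "pos1", "chrom2", "pos2", "read_support"],
        ))
        pb = pseudo_bulk([cell], order=order)
        # C = (8, 8, 4), N = 10; E_AB = 8*8/20 = 3.2 -> OE = 6/3.2
        assert pb.oe[0, 1] == pytest.approx(6 / 3.2)
        assert pb.oe[0, 2] == pytest.approx(2 / 1.6)
        assert pb.oe[1, 2] == pytest.approx(2 / 1.6)

    def test_marginals_sum_to_twice_total(self):
        """Each interaction contributes both ends: sum of C_i = 2N."""
        cells = [_bulk_cell(2000, seed=s, cell_id=f"c{s}") for s in range(2)]
        pb = pseudo_bulk(cells)
        n_interactions = sum(c.n_contacts for c in cells)  # all inter
        c = pb.counts.sum(axis=1)
        assert c.sum() == pytest.approx(2 * n_interactions)

    def test_pseudo_bulk_reproduces_territory_depletion(self, genome):
        """Control pseudo-bulk shows long-short OE depletion relative
        to within-class pairs, as the bulk analysis does."""
        cells, _ = L.simulate_single_cells(
            genome, L.SimulationParams(seed=6), n_cells=6,
            contacts_per_cell=60_000, lcs_positive_fraction=0.0, seed=6,
        )
        retained, _ = qc_filter_cells(cells, min_unfiltered=1)
        pb = pseudo_bulk(retained, order=tuple(genome.chrom_names))
        iu = np.triu_indices(23, 1)
        cats = np.array([
            pair_category(genome.chrom_names[i], genome.chrom_names[j],
                          genome.long_set, genome.short_set)
            for i, j in zip(*iu)
        ])
        oe = pb.oe[iu]
        assert np.nanmedian(oe[cats == "LS"]) < np.nanmedian(oe[cats == "LL"])
        assert np.nanmedian(oe[cats == "LS"]) < np.nanmedian(oe[cats == "SS"])
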