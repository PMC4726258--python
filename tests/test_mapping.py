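"""Two-point linkage, grouping, binning, anchoring and map statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lowmap.mapping import (AnchorParams, LinkageParams,
                            anchored_fraction_percent, anchoring_summary,
                            bin_markers, bins_from_map, build_map,
                            concordance_percent, doublet_concordance,
                            group_markers, haldane_cm, map_summary,
                            mean_interbin_spacing, order_within_group,
                            pairwise_linkage, place_scaffold, two_point)


class TestTwoPoint:
    def test_closed_form_lod(self):
        a = np.array([0.0] * 80 + [1.0] * 20)
        b = np.zeros(100)
        rf, lod = two_point(a, b)
        assert rf == pytest.approx(0.20)
        expected = 20 * math.log10(0.2) + 80 * math.log10(0.8) \
            + 100 * math.log10(2)
        assert lod == pytest.approx(expected, abs=1e-9)
        assert lod == pytest.approx(8.37, abs=0.01)

    def test_identical_vectors_hit_limit(self):
        a = np.array([0.0, 1.0] * 50)
        rf, lod = two_point(a, a.copy())
        assert rf == 0.0
        assert lod == pytest.approx(100 * math.log10(2), abs=1e-9)

    def test_half_recombination_is_null(self):
        a = np.array([0.0] * 50 + [1.0] * 50)
        b = np.array([0.0, 1.0] * 50)
        rf, lod = two_point(a, b)
        assert rf == 0.5
        assert lod == pytest.approx(0.0, abs=1e-9)

    def test_phase_ambiguity_minimises_rf(self):
        a = np.array([0.0] * 90 + [1.0] * 10)
        b = 1.0 - a  # opposite phase
        b[:10] = a[:10]  # 10 recombinants after the phase flip
        rf, _ = two_point(a, b)
        assert rf == pytest.approx(0.10)

    def test_too_few_shared_calls_undefined(self):
        a = np.array([0.0] * 5 + [np.nan] * 5)
        b = np.array([0.0] * 5 + [np.nan] * 5)
        rf, lod = two_point(a, b)
        assert math.isnan(rf) and math.isnan(lod)

    def test_pairwise_matches_scalar(self, rng):
        G = rng.integers(0, 2, size=(8, 40)).astype(float)
        G[rng.random((8, 40)) < 0.2] = np.nan
        rf, lod, n = pairwise_linkage(G)
        for i in range(8):
            for j in range(i + 1, 8):
                s_rf, s_lod = two_point(G[i], G[j])
                if math.isnan(s_rf):
                    assert math.isnan(rf[i, j])
                else:
                    assert rf[i, j] == pytest.approx(s_rf, abs=1e-12)
                    assert lod[i, j] == pytest.approx(s_lod, abs=1e-9)


class TestGrouping:
    def test_two_unlinked_clusters(self, rng):
        half = rng.integers(0, 2, 60).astype(float)
        G = np.vstack([half, half, 1 - half,
                       rng.integers(0, 2, 60).astype(float)])
        G[3] = G[3]
        rf, lod, _ = pairwise_linkage(G)
        groups, singles = group_markers(["a", "b", "c", "d"], rf, lod)
        assert sorted(map(len, groups)) == [3]
        assert singles == [3]

    def test_lod_threshold_is_strict(self):
        rf = np.array([[0.0, 0.1], [0.1, 0.0]])
        lod = np.array([[np.nan, 9.9], [9.9, np.nan]])
        groups, singles = group_markers(["a", "b"], rf, lod,
                                        LinkageParams(min_lod=10.0))
        assert not groups and singles == [0, 1]


class TestBinning:
    def test_identical_markers_collapse(self):
        G = np.array([[0, 1, 0, 1], [0, 1, 0, 1], [0, 1, 1, 1]], float)
        bins = bin_markers(G, [0, 1, 2])
        assert [m for m, _ in bins] == [[0, 1], [2]]

    def test_missing_mismatches_ignored(self):
        G = np.array([[0, 1, np.nan], [0, np.nan, 0]], float)
        bins = bin_markers(G, [0, 1])
        assert len(bins) == 1
        np.testing.assert_array_equal(bins[0][1], [0, 1, 0])

    def test_single_called_difference_separates(self):
        G = np.array([[0, 1, 0], [0, 1, 1]], float)
        assert len(bin_markers(G, [0, 1])) == 2


class TestOrdering:
    def test_triangle_order(self):
        rf = np.array([[0.0, 0.05, 0.10],
                       [0.05, 0.0, 0.05],
                       [0.10, 0.05, 0.0]])
        order = order_within_group(rf)
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_two_markers(self):
        assert sorted(order_within_group(np.array([[0.0, 0.1],
                                                   [0.1, 0.0]]))) == [0, 1]

    def test_chain_recovery_on_simulated_chromosome(self, rng):
        # 20 markers at known positions; rf from the Haldane model
        n_ind = 300
        pos = np.sort(rng.uniform(0, 80, 20))
        xo = [np.sort(rng.uniform(0, 80, rng.poisson(0.8)))
              for _ in range(n_ind)]
        start = rng.integers(0, 2, n_ind)
        G = np.array([[(s + np.searchsorted(x, p)) % 2
                       for s, x in zip(start, xo)] for p in pos], float)
        rf, lod, _ = pairwise_linkage(G)
        order = order_within_group(np.where(np.isnan(rf), 0.5, rf))
        tau = abs(stats.kendalltau(order, np.arange(20)).statistic)
        assert tau >= 0.9


class TestPlacement:
    def make(self, phys, cm, lg=None):
        n = len(phys)
        return pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(n)],
            "scaffold_id": ["s"] * n,
            "physical_pos": phys,
            "linkage_group": lg if lg is not None else [1] * n,
            "position_cM": cm,
        })

    def test_position_is_mean_of_markers(self):
        placed = place_scaffold(self.make([1e4, 5e4, 9e4],
                                          [10.0, 12.0, 14.0]))
        assert placed.position_cM == pytest.approx(12.0)
        assert placed.n_markers == 3

    def test_perfect_correlation_orients_forward(self):
        placed = place_scaffold(self.make([1e4, 5e4, 9e4], [5.0, 5.2, 5.4]))
        assert placed.orientation == "+"

    def test_anticorrelation_orients_reverse(self):
        placed = place_scaffold(self.make([1e4, 5e4, 9e4], [5.4, 5.2, 5.0]))
        assert placed.orientation == "-"

    def test_weak_correlation_leaves_unoriented(self):
        placed = place_scaffold(self.make([1e4, 5e4, 9e4], [5.0, 5.4, 5.0]))
        assert placed.orientation == "."

    def test_tied_positions_leave_unoriented(self):
        placed = place_scaffold(self.make([1e4, 9e4], [7.0, 7.0]))
        assert placed.orientation == "."

    def test_group_tie_is_ambiguous(self):
        markers = self.make([1e4, 5e4], [1.0, 50.0], lg=[1, 2])
        assert place_scaffold(markers) is None

    def test_majority_group_wins(self):
        markers = self.make([1e4, 5e4, 9e4], [1.0, 2.0, 50.0],
                            lg=[1, 1, 2])
        placed = place_scaffold(markers)
        assert placed.chromosome == 1
        assert placed.n_markers == 2
        assert placed.position_cM == pytest.approx(1.5)


def anchoring(rows):
    return pd.DataFrame(rows, columns=["scaffold_id", "chromosome",
                                       "position_cM", "orientation",
                                       "n_markers"])


class TestDoubletConcordance:
    def test_agreeing_pair_concordant(self):
        m1 = anchoring([("A", 1, 1.0, "+", 2), ("B", 1, 3.0, "+", 2)])
        m2 = anchoring([("A", 5, 10.0, "+", 2), ("B", 5, 12.0, "+", 2)])
        res = doublet_concordance(m1, m2)
        assert (res["n_concordant"], res["n_discordant"]) == (1, 0)

    def test_swapped_pair_discordant(self):
        m1 = anchoring([("A", 1, 1.0, "+", 2), ("B", 1, 3.0, "+", 2)])
        m2 = anchoring([("A", 5, 12.0, "+", 2), ("B", 5, 10.0, "+", 2)])
        res = doublet_concordance(m1, m2)
        assert (res["n_concordant"], res["n_discordant"]) == (0, 1)

    def test_window_excludes_distant_pairs(self):
        m1 = anchoring([("A", 1, 1.0, "+", 2), ("B", 1, 9.0, "+", 2)])
        m2 = anchoring([("A", 5, 30.0, "+", 2), ("B", 5, 22.0, "+", 2)])
        res = doublet_concordance(m1, m2)
        assert res["n_concordant"] + res["n_discordant"] == 0

    def test_tied_pair_skipped(self):
        m1 = anchoring([("A", 1, 1.0, "+", 2), ("B", 1, 1.0, "+", 2)])
        m2 = anchoring([("A", 5, 1.0, "+", 2), ("B", 5, 2.0, "+", 2)])
        res = doublet_concordance(m1, m2)
        assert res["n_tied_skipped"] == 1

    def test_reflection_of_one_map_preserves_concordance(self, rng):
        n = 12
        pos = np.sort(rng.uniform(0, 20, n))
        m1 = anchoring([(f"s{i}", 1, float(p), "+", 2)
                        for i, p in enumerate(pos)])
        jitter = pos + rng.normal(0, 0.3, n)
        m2 = anchoring([(f"s{i}", 3, float(p), "+", 2)
                        for i, p in enumerate(jitter)])
        base = doublet_concordance(m1, m2)
        m2_flip = m2.assign(position_cM=m2["position_cM"].max()
                            - m2["position_cM"])
        flipped = doublet_concordance(m1, m2_flip)
        # reversing a whole group swaps every pair consistently
        assert flipped["n_concordant"] == base["n_discordant"]
        assert flipped["n_discordant"] == base["n_concordant"]

    def test_printed_counts_give_87_percent(self):
        assert round(concordance_percent(23_558, 3_480)) == 87

    def test_group_direction_alignment_restores_concordance(self, rng):
        from lowmap.mapping import align_group_directions

        n = 10
        pos = np.sort(rng.uniform(0, 20, n))
        m1 = anchoring([(f"s{i}", 1, float(p), "+", 2)
                        for i, p in enumerate(pos)])
        reversed_m2 = anchoring([(f"s{i}", 4, float(pos.max() - p), "+", 2)
                                 for i, p in enumerate(pos)])
        before = doublet_concordance(m1, reversed_m2)
        assert before["n_concordant"] == 0
        aligned = align_group_directions(m1, reversed_m2)
        after = doublet_concordance(m1, aligned)
        assert after["n_discordant"] == 0
        assert after["n_concordant"] == before["n_discordant"]


class TestMapSummary:
    def test_two_bin_map(self):
        df = pd.DataFrame({"marker_id": ["a", "b"], "linkage_group": [1, 1],
                           "position_cM": [0.0, 10.0]})
        s = map_summary(df)
        assert s["total_length_cM"] == 10.0
        assert s["mean_spacing_cM"] == 10.0

    def test_single_bin_group_contributes_nothing(self):
        df = pd.DataFrame({"marker_id": ["a", "b", "c"],
                           "linkage_group": [1, 1, 2],
                           "position_cM": [0.0, 10.0, 4.0]})
        s = map_summary(df)
        assert s["total_length_cM"] == 10.0
        assert s["mean_spacing_cM"] == 10.0

    def test_published_map_spacings(self):
        assert mean_interbin_spacing(1460, 1157, 17) \
            == pytest.approx(1.28, abs=0.005)
        assert mean_interbin_spacing(1748, 1497, 17) \
            == pytest.approx(1.18, abs=0.005)

    def test_bins_from_map_collapses_shared_positions(self):
        df = pd.DataFrame({"marker_id": ["a", "b", "c"],
                           "linkage_group": [1, 1, 1],
                           "position_cM": [0.0, 0.0, 5.0]})
        bins = bins_from_map(df)
        assert len(bins) == 2
        assert bins["n_markers"].tolist() == [2, 1]


class TestAnchoringSummary:
    def test_published_anchored_fraction(self):
        assert anchored_fraction_percent(526e6, 724.7e6) == 73

    def test_empty_and_full(self):
        empty = anchoring([])
        s = anchoring_summary(empty, {"s1": 100}, 1000)
        assert s["anchored_bp"] == 0
        assert s["anchored_fraction_pct"] == 0
        full = anchoring([("s1", 1, 0.0, "+", 2)])
        s = anchoring_summary(full, {"s1": 1000}, 1000)
        assert s["anchored_fraction_pct"] == 100
        assert s["oriented_bp"] == 1000

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(KeyError):
            anchoring_summary(anchoring([("sX", 1, 0.0, ".", 1)]), {}, 1e6)


def test_haldane_cm_inverts_small_rf():
    assert haldane_cm(0.0) == 0.0
    rf_10cm = (1 - math.exp(-0.2)) / 2
    assert haldane_cm(rf_10cm) == pytest.approx(10.0, rel=1e-9)


def test_build_map_on_two_known_chromosomes(rng):
    """Markers from two simulated chromosomes come back as two ordered
    groups with bin positions increasing along the true order."""
    n_ind = 200
    frames = {}
    truth_order = {}
    for chrom in (1, 2):
        pos = np.sort(rng.uniform(0, 60, 12))
        xo = [np.sort(rng.uniform(0, 60, rng.poisson(0.6)))
              for _ in range(n_ind)]
        start = rng.integers(0, 2, n_ind)
        for i, p in enumerate(pos):
            marker = f"c{chrom}m{i}"
            frames[marker] = [
                "h0" if (s + np.searchsorted(x, p)) % 2 == 0 else "h1"
                for s, x in zip(start, xo)]
            truth_order[marker] = (chrom, p)
    calls = pd.DataFrame.from_dict(frames, orient="index",
                                   columns=[f"i{k}" for k in range(n_ind)])
    calls.index.name = "marker_id"
    map_df, details = build_map(calls)
    assert details["n_groups"] == 2
    for g, grp in map_df.groupby("linkage_group"):
        chroms = {truth_order[m][0] for m in grp["marker_id"]}
        assert len(chroms) == 1
        true_pos = [truth_order[m][1] for m in grp["marker_id"]]
        tau = abs(stats.kendalltau(grp["position_cM"],
                                   true_pos).statistic)
        assert tau >= 0.9
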