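"""Positional tallies, Fisher tails, BH-FDR and family statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from leadscan.enrichment import (
    bh_fdr,
    family_majority_annotation,
    family_orientation,
    fisher_one_sided,
    tally_positions,
    test_family_enrichment as family_enrichment_test,
    test_position_enrichment as position_enrichment_test,
    windowed_frequency,
)
from leadscan.geometry import ContigGeometry


def geo(cid, positions, flags=None):
    rel = {f"{cid}_g{i}": p for i, p in enumerate(positions)}
    t = {g: (flags or {}).get(g, True) for g in rel}
    return ContigGeometry(cid, 1, rel, t)


def hypergeom_tail_oracle(k, K, n, N):
    """Brute-force tail summation of the hypergeometric pmf via comb()."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
    return total / comb(N, n, exact=True)


class TestTally:
    def test_counts_aggregate_over_contigs(self):
        g1 = geo("c1", [0, 1, -1])
        g2 = geo("c2", [0, -1])
        cats = {"c1_g0": "anti_crispr", "c2_g0": "anti_crispr"}
        table = tally_positions([g1, g2], cats)
        assert table.loc[0, "n_anti_crispr"] == 2
        assert table.loc[0, "n_total"] == 2
        assert table.loc[0, "n_anti_defence"] == 2
        assert table.loc[1, "n_total"] == 1

    def test_order_invariant(self):
        g1, g2 = geo("c1", [0, 1]), geo("c2", [0, -1])
        cats = {}
        pd.testing.assert_frame_equal(
            tally_positions([g1, g2], cats), tally_positions([g2, g1], cats)
        )


class TestWindowedFrequency:
    def make_table(self, n_cat, n_total):
        idx = pd.Index(range(len(n_cat)), name="position")
        return pd.DataFrame(
            {"n_total": n_total, "n_anti_defence": n_cat}, index=idx
        )

    def test_centered_window(self):
        t = self.make_table([0, 0, 5, 0, 0], [10] * 5)
        fw = windowed_frequency(t)
        assert fw.loc[2] == pytest.approx(5 / 50)

    def test_saturated_counts(self):
        t = self.make_table([7] * 6, [7] * 6)
        assert (windowed_frequency(t) == 1.0).all()

    def test_edge_truncation(self):
        t = self.make_table([1, 1, 1, 1, 1], [10] * 5)
        fw = windowed_frequency(t)
        # position 0: window truncated to positions 0..2
        assert fw.loc[0] == pytest.approx(3 / 30)

    def test_even_window_rejected(self):
        t = self.make_table([0], [1])
        with pytest.raises(ValueError, match="odd"):
            windowed_frequency(t, window=4)


class TestFisher:
    def test_zero_count_gives_one(self):
        assert fisher_one_sided(0, 50, 10, 100) == 1.0

    def test_unit_margins_give_half(self):
        assert fisher_one_sided(1, 1, 1, 2) == pytest.approx(0.5)

    def test_matches_brute_force_tail(self):
        cases = [(5, 105, 50, 10050), (3, 10, 20, 100), (7, 30, 12, 60)]
        for k, K, n, N in cases:
            assert fisher_one_sided(k, K, n, N) == pytest.approx(
                hypergeom_tail_oracle(k, K, n, N), abs=1e-12
            )

    def test_margin_validation(self):
        with pytest.raises(ValueError):
            fisher_one_sided(5, 10, 3, 100)  # k > n
        with pytest.raises(ValueError):
            fisher_one_sided(1, 200, 5, 100)  # K > N


class TestBHFDR:
    def test_all_ones_no_rejections(self):
        q, rej = bh_fdr([1.0] * 5, alpha=0.05)
        assert not rej.any()

    def test_single_small_p_rejected(self):
        q, rej = bh_fdr([0.0005], alpha=0.001)
        assert rej.tolist() == [True]

    def test_hand_worked_example(self):
        # thresholds i/m * alpha = 0.0125, 0.025, 0.0375, 0.05 -> 3 rejections
        q, rej = bh_fdr([0.001, 0.01, 0.02, 0.8], alpha=0.05)
        assert rej.tolist() == [True, True, True, False]
        assert q == pytest.approx([0.004, 0.02, 0.8 / 30, 0.8])

    def test_q_monotone_in_sorted_p_order(self, rng):
        p = rng.random(200)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPositionEnrichment:
    def test_min_orfs_excludes_positions(self):
        idx = pd.Index([0, 1], name="position")
        t = pd.DataFrame(
            {"n_total": [49, 60], "n_anti_defence": [30, 5]}, index=idx
        )
        res = position_enrichment_test(t, min_orfs=50, categories=("anti_defence",))
        assert np.isnan(res.loc[0, "p_anti_defence"])
        assert not res.loc[0, "sig_anti_defence"]
        assert np.isfinite(res.loc[1, "p_anti_defence"])

    def test_empty_when_nothing_testable(self, caplog):
        idx = pd.Index([0], name="position")
        t = pd.DataFrame({"n_total": [10], "n_anti_defence": [1]}, index=idx)
        res = position_enrichment_test(t, min_orfs=50, categories=("anti_defence",))
        assert not res["sig_anti_defence"].any()

    def test_planted_enrichment_flagged(self):
        # strong planted signal at positions 0-4, uniform elsewhere
        idx = pd.Index(range(-5, 15), name="position")
        n_total = [100] * 20
        n_cat = [20 if 0 <= p <= 4 else 1 for p in idx]
        t = pd.DataFrame({"n_total": n_total, "n_anti_defence": n_cat}, index=idx)
        res = position_enrichment_test(t, categories=("anti_defence",))
        assert sorted(res.index[res["sig_anti_defence"]]) == [0, 1, 2, 3, 4]


class TestFamilies:
    def test_orientation_majority_and_ties(self):
        assert family_orientation([True, True, True, False, False]) == "t_strand"
        assert family_orientation([True, True, False, False]) == "tie"
        assert family_orientation([False, False]) == "opposite"
        with pytest.raises(ValueError):
            family_orientation([])

    def test_majority_annotation(self):
        assert family_majority_annotation(["A", "A", "B"]) == "A"
        assert family_majority_annotation([]) == "uncharacterized"
        assert family_majority_annotation(["B", "A"]) == "A"

    def test_leading_family_enriched_and_scattered_not(self):
        geos = []
        families = {}
        for c in range(30):
            cid = f"c{c}"
            positions = list(range(-50, 50))
            geos.append(geo(cid, positions))
            # fam_lead always sits at positions 0..5; fam_flat every 25th gene
            for i, p in enumerate(positions):
                gid = f"{cid}_g{i}"
                if 0 <= p <= 5:
                    families[gid] = "fam_lead"
                elif p % 25 == 3:
                    families[gid] = "fam_flat"
        res = family_enrichment_test(families, geos, min_size=5)
        assert bool(res.loc["fam_lead", "enriched"])
        assert not bool(res.loc["fam_flat", "enriched"])
        oracle_p = hypergeom_tail_oracle(
            k=int(res.loc["fam_lead", "leading_count"]),
            K=30 * 28,
            n=int(res.loc["fam_lead", "size"]),
            N=30 * 100,
        )
        assert res.loc["fam_lead", "p"] == pytest.approx(oracle_p, rel=1e-9)

    def test_family_without_leading_members_not_enriched(self):
        geos = [geo("c1", list(range(-10, 40)))]
        families = {f"c1_g{i}": "famX" for i in range(0, 8)}  # positions -10..-3
        res = family_enrichment_test(families, geos, min_size=5)
        assert res.loc["famX", "p"] == 1.0
        assert not bool(res.loc["famX", "enriched"])
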