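"""Upstream regions, sigma70 scanning, folding and tier classification."""

import numpy as np
import pytest

from leadscan._seq import revcomp
from leadscan.frpo_scan import (
    MINUS10,
    MINUS35,
    BasePairStructure,
    best_element,
    classify_candidate,
    extract_upstream_regions,
    hairpin_evidence,
    max_basepairs,
    scan_region,
    scan_sigma70_elements,
)
from leadscan.geometry import ContigGeometry
from leadscan.io_formats import GeneRecord
from leadscan.synthetic_data import dinucleotide_shuffle, plant_frpo

NT = np.array(list("ACGT"))

PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_max_pairs(s, i=None, j=None, min_loop=3):
    """Exponential-time enumeration oracle over all nested structures."""
    if i is None:
        i, j = 0, len(s) - 1
    if j - i < min_loop + 1:
        return 0
    best = enumerate_max_pairs(s, i, j - 1, min_loop)  # j unpaired
    for k in range(i, j - min_loop):
        if (s[k], s[j]) in PAIRABLE:
            left = enumerate_max_pairs(s, i, k - 1, min_loop) if k > i else 0
            inner = enumerate_max_pairs(s, k + 1, j - 1, min_loop)
            best = max(best, left + inner + 1)
    return best


class TestUpstreamRegions:
    def make_setup(self):
        genes = [
            GeneRecord("c1", 100, 700, "+", "relax", 0),
            GeneRecord("c1", 800, 1000, "+", "g0", 1),
            GeneRecord("c1", 1200, 1500, "+", "g1", 2),
            GeneRecord("c1", 1540, 1800, "-", "g2", 3),
            GeneRecord("c1", 2100, 2400, "+", "g3", 4),
        ]
        rel = {"relax": -1, "g0": 0, "g1": 1, "g2": 2, "g3": 3}
        flags = {g: True for g in rel}
        geometry = ContigGeometry("c1", 1, rel, flags)
        rng = np.random.default_rng(5)
        seq = "".join(NT[rng.integers(0, 4, size=2600)])
        return geometry, genes, seq

    def test_plus_strand_region_is_previous_gap(self):
        geometry, genes, seq = self.make_setup()
        regions = {r.gene_id: r for r in extract_upstream_regions(geometry, genes, seq)}
        assert (regions["g1"].start, regions["g1"].end) == (1000, 1200)
        assert regions["g1"].sequence == seq[1000:1200]

    def test_minus_strand_region_is_reverse_complement_of_next_gap(self):
        geometry, genes, seq = self.make_setup()
        regions = {r.gene_id: r for r in extract_upstream_regions(geometry, genes, seq)}
        assert (regions["g2"].start, regions["g2"].end) == (1800, 2100)
        assert regions["g2"].sequence == revcomp(seq[1800:2100])

    def test_short_gap_excluded(self):
        geometry, genes, seq = self.make_setup()
        regions = {r.gene_id: r for r in extract_upstream_regions(geometry, genes, seq)}
        # a plus-strand gene whose upstream gap is only 40 nt is dropped
        genes2 = genes + [GeneRecord("c1", 1840, 1900, "+", "g4", 5)]
        geometry.relative_position["g4"] = 4
        geometry.t_strand_expressible["g4"] = True
        regions2 = {r.gene_id: r for r in extract_upstream_regions(geometry, genes2, seq)}
        assert "g4" not in regions2  # gap 1800..1840 is 40 nt < 50

    def test_missing_sequence_errors(self):
        geometry, genes, _ = self.make_setup()
        with pytest.raises(ValueError, match="c1"):
            extract_upstream_regions(geometry, genes, None)


class TestSigma70Scan:
    def test_perfect_consensus_found(self):
        region = "G" * 30 + MINUS35 + "A" * 17 + MINUS10 + "G" * 30
        hits = scan_sigma70_elements(region)
        perfect = [h for h in hits if h.total_mismatches == 0]
        assert len(perfect) == 1
        h = perfect[0]
        assert (h.minus35_offset, h.minus10_offset, h.spacer) == (30, 53, 17)
        assert h.up_at_fraction == 0.0  # poly-G upstream

    def test_single_substitution_counted(self):
        region = "A" * 30 + "TTGACA" + "C" * 16 + "TACAAT" + "A" * 30
        hits = scan_sigma70_elements(region)
        best = best_element(hits)
        assert (best.minus35_mismatches, best.minus10_mismatches) == (0, 1)
        assert best.spacer == 16
        assert best.up_at_fraction == 1.0

    def test_poly_g_has_no_hits(self):
        assert scan_sigma70_elements("G" * 120) == []

    def test_spacer_bounds_enforced(self):
        region = "A" * 20 + MINUS35 + "C" * 10 + MINUS10 + "A" * 20  # spacer 10
        hits = [h for h in scan_sigma70_elements(region) if h.total_mismatches == 0]
        assert hits == []


class TestMaxBasepairs:
    def test_simple_hairpin(self):
        st = max_basepairs("GGGAAACCC")
        assert st.n_pairs == 3
        assert set(st.pairs) == {(0, 8), (1, 7), (2, 6)}

    def test_unpairable_sequence(self):
        assert max_basepairs("AAAAAA").n_pairs == 0

    def test_min_loop_respected(self):
        # GAAAC: loop of 3 between G and C -> one pair; GAAC cannot pair
        assert max_basepairs("GAAAC").n_pairs == 1
        assert max_basepairs("GAAC").n_pairs == 0

    def test_length_cap(self):
        with pytest.raises(ValueError, match="cap"):
            max_basepairs("A" * 401)

    def test_constructed_stem_lower_bound(self, rng):
        for _ in range(5):
            core = "".join(NT[rng.integers(0, 4, size=15)])
            seq = core + "AAA" + revcomp(core)
            assert max_basepairs(seq).n_pairs >= len(core)

    @pytest.mark.parametrize("length", [8, 10, 12, 14])
    def test_matches_enumeration_oracle(self, length, rng):
        for _ in range(12):
            s = "".join(NT[rng.integers(0, 4, size=length)])
            assert max_basepairs(s).n_pairs == enumerate_max_pairs(s)

    def test_traceback_pairs_are_valid_nested_structure(self, rng):
        s = "".join(NT[rng.integers(0, 4, size=60)])
        st = max_basepairs(s)
        assert len(st.pairs) == st.n_pairs
        used = set()
        for i, j in st.pairs:
            assert (s[i], s[j]) in PAIRABLE
            assert j - i - 1 >= 3
            assert i not in used and j not in used
            used |= {i, j}
        for (i1, j1) in st.pairs:  # nesting: no crossing pairs
            for (i2, j2) in st.pairs:
                if i1 < i2:
                    assert j2 < j1 or i2 > j1
        assert st.dot_bracket().count("(") == st.n_pairs


class TestDotBracketHook:
    def test_round_trip_with_internal_structure(self):
        from leadscan.frpo_scan import structure_from_dot_bracket

        st = max_basepairs("GGGAAACCCTTTAAAGGG")
        back = structure_from_dot_bracket(st.dot_bracket())
        assert back.pairs == st.pairs and back.n_pairs == st.n_pairs

    def test_malformed_strings_rejected(self):
        from leadscan.frpo_scan import structure_from_dot_bracket

        with pytest.raises(ValueError):
            structure_from_dot_bracket("(()")
        with pytest.raises(ValueError):
            structure_from_dot_bracket("().x")


class TestHairpinEvidence:
    def test_perfect_stem_fully_pairs_elements(self, rng):
        seq, info = plant_frpo(120, "frpo_prime", rng)
        hits = scan_sigma70_elements(seq)
        el = best_element(hits)
        st = max_basepairs(seq)
        ev = hairpin_evidence(seq, el, st)
        assert ev.paired_fraction >= 0.5
        assert ev.stem_flag and ev.supported

    def test_element_unpaired_in_structure_scores_zero(self):
        # contract: with no pairs touching the element, the fraction is 0 and
        # a region without any complementary block is unsupported
        region = "A" * 25 + MINUS35 + "A" * 17 + MINUS10 + "A" * 25
        el = best_element(scan_sigma70_elements(region))
        empty = BasePairStructure(len(region), [], 0)
        ev = hairpin_evidence(region, el, empty)
        assert ev.paired_fraction == 0.0
        assert not ev.stem_flag and not ev.supported

    def test_partial_pairing_counted_from_traceback(self):
        region = "A" * 25 + MINUS35 + "A" * 17 + MINUS10 + "A" * 25
        el = best_element(scan_sigma70_elements(region))
        pairs = [(el.minus35_offset + i, 90 + i) for i in range(3)]  # 3 of 12 paired
        st = BasePairStructure(len(region), pairs, len(pairs))
        ev = hairpin_evidence(region, el, st)
        assert ev.paired_fraction == pytest.approx(3 / 12)
        assert not ev.stem_flag


class TestClassification:
    def test_tier_rules(self):
        from leadscan.frpo_scan import AlignmentHit, HairpinEvidence, PromoterElementHit

        hom = AlignmentHit("q", "s", 0, 50, "+", 45, 85.0, 50)
        el_1_1 = PromoterElementHit(10, 1, 33, 1, 17, 0.9)
        el_2_2 = PromoterElementHit(10, 2, 33, 2, 17, 0.9)
        stem = HairpinEvidence(1.0, True, 29, True)
        no_stem = HairpinEvidence(0.2, False, 0, False)
        assert classify_candidate(hom, None, None) == "frpo"
        assert classify_candidate(None, el_1_1, stem) == "frpo_prime"
        assert classify_candidate(None, el_2_2, stem) == "frpo_star"
        assert classify_candidate(None, el_1_1, no_stem) == "none"
        assert classify_candidate(None, None, None) == "none"

    def test_planted_star_construct_classified_star(self, rng):
        hits = 0
        for _ in range(10):
            seq, _ = plant_frpo(120, "frpo_star", rng)
            from leadscan.frpo_scan import UpstreamRegion

            region = UpstreamRegion("c", "g", 0, len(seq), "+", seq)
            cand = scan_region(region)
            if cand.tier == "frpo_star":
                hits += 1
        assert hits >= 8

    def test_homology_tier_strand_symmetric(self, rng):
        from leadscan.frpo_scan import UpstreamRegion
        from leadscan.synthetic_data import load_frpo_standins

        known = load_frpo_standins()
        qid = sorted(known)[0]
        pad = "".join(NT[rng.integers(0, 4, size=30)])
        seq = pad + known[qid] + pad
        fwd = scan_region(UpstreamRegion("c", "g", 0, len(seq), "+", seq), known)
        rev = scan_region(UpstreamRegion("c", "g", 0, len(seq), "+", revcomp(seq)), known)
        assert fwd.tier == "frpo" and rev.tier == "frpo"
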