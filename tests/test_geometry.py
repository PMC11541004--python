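"""oriT selection, QC filters, relative positions and strand invariance."""

import pytest

from conftest import mirror_contig_input
from leadscan.geometry import (
    ContigInput,
    DegenerateGeometryError,
    assign_relative_positions,
    qc_filter_contigs,
    select_best_orit,
    t_strand_expressible,
)
from leadscan.io_formats import GeneRecord, HomologyHit


def orit_hit(sstart, send, score=50.0, e=1e-20, qid="oriT_q", cid="c1"):
    return HomologyHit(qid, cid, sstart, send, "+", 99.0, score, e)


class TestSelectBestOrit:
    def test_highest_score_wins(self):
        hits = [orit_hit(100, 200, 40), orit_hit(500, 600, 55)]
        assert select_best_orit(hits).bit_score == 55

    def test_single_hit(self):
        h = orit_hit(10, 50)
        assert select_best_orit([h]) is h

    def test_tie_broken_by_leftmost_start(self):
        hits = [orit_hit(900, 1000, 40), orit_hit(100, 200, 40)]
        assert select_best_orit(hits).sstart == 100

    def test_empty_gives_none(self):
        assert select_best_orit([]) is None


def make_contig(
    cid="c1",
    gene_spans=((0, 500), (1000, 2000), (2300, 2600), (2700, 3000), (3500, 4000)),
    strands=("+", "+", "-", "-", "+"),
    relaxase=("c1_g1",),
    orit=(2100, 2200),
    orit_score=50.0,
):
    genes = [
        GeneRecord(cid, s, e, st, f"{cid}_g{i}", i)
        for i, ((s, e), st) in enumerate(zip(gene_spans, strands))
    ]
    hits = [orit_hit(*orit, orit_score, cid=cid)] if orit else []
    return ContigInput(cid, genes, list(relaxase), hits)


class TestQCFilter:
    def test_clean_contig_passes(self):
        passing, rejected = qc_filter_contigs([make_contig()])
        assert len(passing) == 1 and not rejected

    def test_three_relaxase_hits_rejected(self):
        ci = make_contig(relaxase=("c1_g1", "c1_g2", "c1_g3"))
        _, rejected = qc_filter_contigs([ci])
        assert rejected == {"c1": "too_many_relaxases"}

    def test_two_relaxase_hits_allowed(self):
        ci = make_contig(relaxase=("c1_g1", "c1_g2"))
        passing, rejected = qc_filter_contigs([ci])
        assert len(passing) == 1

    def test_distance_above_3500_rejected(self):
        # relaxase gene ends at 2000; oriT starts at 5601 -> distance 3601
        ci = make_contig(
            gene_spans=((0, 500), (1000, 2000), (5800, 6100), (6200, 6500), (7000, 7400)),
            orit=(5601, 5700),
        )
        _, rejected = qc_filter_contigs([ci])
        assert rejected == {"c1": "too_far"}

    def test_distance_exactly_3500_kept(self):
        ci = make_contig(
            gene_spans=((0, 500), (1000, 2000), (5700, 6000), (6100, 6400), (7000, 7400)),
            orit=(5500, 5600),
        )
        passing, rejected = qc_filter_contigs([ci])
        assert len(passing) == 1

    def test_orit_inside_relaxase_rejected(self):
        ci = make_contig(orit=(1200, 1300))
        _, rejected = qc_filter_contigs([ci])
        assert rejected == {"c1": "orit_inside_relaxase"}

    def test_partial_overlap_retained(self):
        ci = make_contig(orit=(1900, 2100))
        passing, rejected = qc_filter_contigs([ci])
        assert len(passing) == 1

    def test_relaxase_at_contig_edge_rejected(self):
        ci = make_contig(relaxase=("c1_g0",))
        _, rejected = qc_filter_contigs([ci])
        assert rejected == {"c1": "edge_placement"}

    def test_orit_beyond_last_gene_rejected(self):
        ci = make_contig(orit=(4100, 4200))
        _, rejected = qc_filter_contigs([ci])
        assert rejected == {"c1": "edge_placement"}

    def test_missing_inputs_reported(self):
        no_orit = make_contig(orit=None)
        no_relax = make_contig(cid="c2", relaxase=())
        _, rejected = qc_filter_contigs([no_orit, no_relax])
        assert rejected == {"c1": "no_orit", "c2": "no_relaxase"}


class TestRelativePositions:
    def test_forced_example(self):
        # relaxase [1000,2000), oriT [2100,2200), gene midpoints 2400, 2800, 600
        genes = [
            GeneRecord("c1", 2300, 2500, "-", "gA", 2),
            GeneRecord("c1", 2700, 2900, "-", "gB", 3),
            GeneRecord("c1", 500, 700, "+", "gC", 0),
            GeneRecord("c1", 1000, 2000, "+", "relax", 1),
        ]
        ci = ContigInput("c1", genes, ["relax"], [orit_hit(2100, 2200)])
        passing, _ = qc_filter_contigs([ci])
        geo = assign_relative_positions(*([passing[0][0].genes, passing[0][1]]))
        assert geo.leading_direction == 1
        assert geo.relative_position == {"gA": 0, "gB": 1, "relax": -1, "gC": -2}

    def test_gene_midpoint_at_orit_midpoint_is_position_zero(self):
        genes = [
            GeneRecord("c1", 2100, 2200, "+", "gMid", 2),  # midpoint == oriT midpoint
            GeneRecord("c1", 200, 500, "-", "gLag", 0),
            GeneRecord("c1", 1000, 2000, "+", "relax", 1),
            GeneRecord("c1", 2400, 2600, "-", "gA", 3),
        ]
        ci = ContigInput("c1", genes, ["relax"], [orit_hit(2100, 2200)])
        passing, _ = qc_filter_contigs([ci])
        geo = assign_relative_positions(passing[0][0].genes, passing[0][1])
        assert geo.relative_position["gMid"] == 0

    def test_degenerate_geometry_raises(self):
        genes = [GeneRecord("c1", 1000, 2000, "+", "relax", 0)]
        ci = ContigInput("c1", genes, ["relax"], [orit_hit(1400, 1600)])
        from leadscan.geometry import _resolve_orit

        assignment, reason = _resolve_orit(ci, 3500)
        assert reason == "orit_inside_relaxase"  # full containment caught in QC
        # a partially overlapping oriT with coinciding midpoints is degenerate
        genes = [GeneRecord("c1", 1000, 2000, "+", "relax", 0)]
        ci = ContigInput("c1", genes, ["relax"], [orit_hit(900, 2100)])
        assignment, reason = _resolve_orit(ci, 3500)
        with pytest.raises(DegenerateGeometryError):
            assign_relative_positions(genes, assignment)

    def test_relaxase_always_negative(self, small_dataset):
        from leadscan.geometry import qc_filter_contigs

        passing, _ = qc_filter_contigs(small_dataset.contig_inputs())
        for ci, assignment in passing:
            geo = assign_relative_positions(ci.genes, assignment)
            assert geo.relative_position[assignment.relaxase_gene_id] < 0

    def test_positions_partition_all_genes(self, small_dataset):
        passing, _ = qc_filter_contigs(small_dataset.contig_inputs())
        for ci, assignment in passing:
            geo = assign_relative_positions(ci.genes, assignment)
            positions = sorted(geo.relative_position.values())
            lead = [p for p in positions if p >= 0]
            lag = [p for p in positions if p < 0]
            assert lead == list(range(len(lead)))
            assert lag == list(range(-len(lag), 0))


class TestTStrandConvention:
    @pytest.mark.parametrize(
        "direction,strand,expected",
        [(1, "-", True), (1, "+", False), (-1, "-", False), (-1, "+", True)],
    )
    def test_toward_orit_convention(self, direction, strand, expected):
        g = GeneRecord("c", 0, 10, strand, "g", 0)
        assert t_strand_expressible(g, direction, "toward_oriT") is expected

    def test_away_convention_is_the_mirror(self):
        g = GeneRecord("c", 0, 10, "-", "g", 0)
        assert t_strand_expressible(g, 1, "away_from_oriT") is False


class TestReverseComplementInvariance:
    def test_mirror_preserves_geometry(self, small_dataset):
        inputs = small_dataset.contig_inputs()[:10]
        passing, _ = qc_filter_contigs(inputs)
        for ci, assignment in passing:
            geo = assign_relative_positions(ci.genes, assignment)
            mirrored = mirror_contig_input(ci)
            mp, mrej = qc_filter_contigs([mirrored])
            assert not mrej
            mgeo = assign_relative_positions(mp[0][0].genes, mp[0][1])
            assert mgeo.relative_position == geo.relative_position
            assert mgeo.t_strand_expressible == geo.t_strand_expressible
            assert mgeo.leading_direction == -geo.leading_direction
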