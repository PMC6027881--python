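"""The 0-360 projection: coordinates, y indices, vectors, color scale."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from blastxy.model import BlastHit, GeneFeature, Replicon
from blastxy.projection import (
    DARK_BLUE,
    YELLOW,
    ColorScale,
    assign_replicon_indices,
    bitscore_to_color,
    project_hit,
    project_hit_genome,
    project_hits,
    relative_coordinate,
)


def make_hit(**kw):
    base = dict(
        query_id="q", subject_id="s", pct_identity=99.0, aln_length=100,
        mismatches=1, gap_opens=0, q_start=1, q_end=100, s_start=1,
        s_end=100, evalue=1e-30, bitscore=200.0,
    )
    base.update(kw)
    return BlastHit(**base)


class TestRelativeCoordinate:
    @pytest.mark.parametrize("L", [1, 5, 1_234_567, 4_641_652])
    def test_final_base_end_is_exactly_360(self, L):
        assert relative_coordinate(L, L, "end") == 360.0

    @pytest.mark.parametrize("L", [1, 5, 1_234_567, 4_641_652])
    def test_first_base_start_is_exactly_zero(self, L):
        assert relative_coordinate(1, L, "start") == 0.0

    def test_midpoint(self):
        assert relative_coordinate(2_000_000, 4_000_000, "end") == 180.0

    def test_wrap_normalized_positions_reduce_modulo_length(self):
        # a wrap-normalized coordinate L+k maps like position k
        assert relative_coordinate(5200, 5000, "end") == (
            relative_coordinate(200, 5000, "end")
        )

    @pytest.mark.parametrize("pos,L", [(0, 10), (1, 0), (-3, 10)])
    def test_invalid_inputs_raise(self, pos, L):
        with pytest.raises(ValueError):
            relative_coordinate(pos, L, "start")

    @settings(max_examples=200, deadline=None)
    @given(st.integers(2, 10**7), st.data())
    def test_monotone_and_strict_across_bases(self, L, data):
        """Non-decreasing in position; strictly increasing across distinct
        bases at the same boundary."""
        a = data.draw(st.integers(1, L - 1))
        b = data.draw(st.integers(a + 1, L))
        for boundary in ("start", "end"):
            assert relative_coordinate(a, L, boundary) < (
                relative_coordinate(b, L, boundary)
            )
        assert relative_coordinate(a, L, "start") < (
            relative_coordinate(a, L, "end")
        )

    def test_degree_length_conservation(self):
        """Non-overlapping features tiling a replicon sum to 360 degrees."""
        L = 97_013
        bounds = [1, 20_000, 20_001, 55_000, 55_001, L]
        total = sum(
            relative_coordinate(e, L, "end") - relative_coordinate(s, L, "start")
            for s, e in zip(bounds[0::2], bounds[1::2])
        )
        assert total == pytest.approx(360.0, abs=1e-6)


class TestAssignIndices:
    def test_single_replicon_gets_index_one(self):
        (r,) = assign_replicon_indices(
            [Replicon("chr", 1000, organism="Solo")]
        )
        assert r.replicon_index == 1

    def test_indices_are_one_to_n_without_gaps(self):
        reps = assign_replicon_indices(
            [Replicon(f"r{i}", 1000 + i) for i in range(3)]
        )
        assert sorted(r.replicon_index for r in reps) == [1, 2, 3]

    def test_canonical_order_chromosome_before_plasmid(self):
        # organisms alphabetical; within one, longest (chromosome) first
        reps = assign_replicon_indices([
            Replicon("b_plasmid", 50_000, organism="OrgB"),
            Replicon("a_plasmid", 60_000, organism="OrgA"),
            Replicon("b_chr", 4_000_000, organism="OrgB"),
            Replicon("a_chr", 3_000_000, organism="OrgA"),
        ])
        order = [r.replicon_id for r in reps]
        assert order == ["a_chr", "a_plasmid", "b_chr", "b_plasmid"]
        assert [r.replicon_index for r in reps] == [1, 2, 3, 4]

    def test_stable_across_input_permutations(self):
        pool = [Replicon(f"r{i}", 1000 * (i + 1), organism="X")
                for i in range(5)]
        a = assign_replicon_indices(pool)
        b = assign_replicon_indices(list(reversed(pool)))
        assert [(r.replicon_id, r.replicon_index) for r in a] == (
            [(r.replicon_id, r.replicon_index) for r in b]
        )

    def test_duplicate_id_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_replicon_indices(
                [Replicon("r", 10), Replicon("r", 20)]
            )


class TestProjectHit:
    REP = Replicon("rep", 360_000, organism="Org", replicon_index=2)
    SCALE = ColorScale(0.0, 400.0)

    def test_plus_strand_vector_and_segment(self):
        feature = GeneFeature("rep", "g", 1, 1000, "+")
        hit = make_hit(s_start=101, s_end=600)
        r = project_hit(hit, feature, self.REP, self.SCALE)
        assert abs(r.vector_deg) == pytest.approx(1.0, rel=1e-9)
        assert r.vector_deg > 0
        assert r.seg_offset_deg == pytest.approx(0.1, rel=1e-9)
        assert r.seg_len_deg == pytest.approx(0.5, rel=1e-9)
        assert r.x == 0.0
        assert r.y == 2

    def test_minus_strand_dot_at_upper_boundary(self):
        feature = GeneFeature("rep", "g", 1, 1000, "-")
        hit = make_hit(s_start=101, s_end=600)
        r = project_hit(hit, feature, self.REP, self.SCALE)
        assert r.vector_deg == pytest.approx(-1.0, rel=1e-9)
        assert r.x == pytest.approx(
            relative_coordinate(1000, 360_000, "end"), rel=1e-12
        )

    def test_full_span_alignment_covers_vector(self):
        feature = GeneFeature("rep", "g", 5000, 5999, "+")
        hit = make_hit(s_start=1, s_end=1000)
        r = project_hit(hit, feature, self.REP, self.SCALE)
        assert r.seg_offset_deg == 0.0
        assert r.seg_len_deg == pytest.approx(abs(r.vector_deg), rel=1e-9)

    def test_reversed_subject_coordinates_accepted(self):
        feature = GeneFeature("rep", "g", 1, 1000, "+")
        hit = make_hit(s_start=600, s_end=101)  # minus-strand alignment
        r = project_hit(hit, feature, self.REP, self.SCALE)
        assert r.seg_offset_deg == pytest.approx(0.1, rel=1e-9)
        assert r.seg_len_deg == pytest.approx(0.5, rel=1e-9)

    def test_subject_coordinates_outside_length_raise(self):
        feature = GeneFeature("rep", "g", 1, 1000, "+")
        with pytest.raises(ValueError, match="outside subject length"):
            project_hit(make_hit(s_start=1, s_end=1001), feature,
                        self.REP, self.SCALE)

    def test_protein_subject_uses_residue_fraction(self):
        # 900 bp gene -> 300 residues; residues 1..150 = first half
        feature = GeneFeature("rep", "g", 1, 900, "+")
        hit = make_hit(s_start=1, s_end=150, unit="protein")
        r = project_hit(hit, feature, self.REP, self.SCALE)
        assert r.seg_offset_deg == 0.0
        assert r.seg_len_deg == pytest.approx(abs(r.vector_deg) / 2, rel=1e-9)

    def test_vector_magnitude_matches_gene_fraction(self):
        feature = GeneFeature("rep", "g", 100, 3699, "+")  # 3600 bp
        r = project_hit(make_hit(s_start=1, s_end=100), feature,
                        self.REP, self.SCALE)
        assert abs(r.vector_deg) == pytest.approx(
            360.0 * 3600 / 360_000, rel=1e-9
        )

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_segment_agrees_with_bruteforce(self, data):
        """Independent integer-arithmetic recomputation of the segment
        boundaries agrees with project_hit to 1e-9 relative tolerance."""
        L = data.draw(st.integers(10_000, 5_000_000))
        glen = data.draw(st.integers(90, min(L, 9000)))
        gstart = data.draw(st.integers(1, L - glen + 1))
        strand = data.draw(st.sampled_from("+-"))
        s_lo = data.draw(st.integers(1, glen))
        s_hi = data.draw(st.integers(s_lo, glen))
        feature = GeneFeature("rep", "g", gstart, gstart + glen - 1, strand)
        rep = Replicon("rep", L, replicon_index=1)
        hit = make_hit(s_start=s_lo, s_end=s_hi, aln_length=s_hi - s_lo + 1)
        r = project_hit(hit, feature, rep, self.SCALE)
        # oracle: integer bp arithmetic then one division
        vec = 360.0 * glen / L
        assert abs(r.vector_deg) == pytest.approx(vec, rel=1e-9)
        assert r.seg_offset_deg == pytest.approx(
            360.0 * ((s_lo - 1) * glen / glen) / L, rel=1e-9
        )
        assert r.seg_len_deg == pytest.approx(
            360.0 * (s_hi - s_lo + 1) / L, rel=1e-9
        )
        assert r.seg_offset_deg + r.seg_len_deg <= abs(r.vector_deg) + 1e-9


class TestGenomeMode:
    def test_whole_replicon_subject(self):
        rep = Replicon("chr", 1_000_000, organism="Org", replicon_index=3)
        scale = ColorScale(0, 400)
        r = project_hit_genome(
            make_hit(s_start=250_001, s_end=500_000), rep, scale
        )
        assert r.x == pytest.approx(90.0, rel=1e-12)
        assert r.vector_deg == pytest.approx(90.0, rel=1e-9)
        assert r.seg_offset_deg == 0.0
        assert r.seg_len_deg == pytest.approx(90.0, rel=1e-9)

    def test_minus_orientation_from_coordinates(self):
        rep = Replicon("chr", 1_000_000, replicon_index=1)
        r = project_hit_genome(
            make_hit(s_start=500_000, s_end=250_001), rep, ColorScale(0, 400)
        )
        assert r.strand == "-" and r.vector_deg < 0
        assert r.x == pytest.approx(180.0, rel=1e-12)


class TestColorScale:
    SCALE = ColorScale(50.0, 250.0)

    def test_max_is_dark_blue(self):
        v, rgb = bitscore_to_color(250.0, self.SCALE)
        assert v == 1.0 and rgb == DARK_BLUE

    def test_min_is_yellow(self):
        v, rgb = bitscore_to_color(50.0, self.SCALE)
        assert v == 0.0 and rgb == YELLOW

    def test_degenerate_scale_is_dark_blue(self):
        v, rgb = bitscore_to_color(100.0, ColorScale(100.0, 100.0))
        assert v == 1.0 and rgb == DARK_BLUE

    def test_out_of_range_clipped(self):
        assert bitscore_to_color(500.0, self.SCALE)[0] == 1.0
        assert bitscore_to_color(0.0, self.SCALE)[0] == 0.0

    def test_non_finite_bitscore_raises(self):
        with pytest.raises(ValueError):
            bitscore_to_color(math.nan, self.SCALE)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 400, allow_nan=False),
           st.floats(0, 400, allow_nan=False))
    def test_monotone(self, b1, b2):
        v1 = self.SCALE.color_value(b1)
        v2 = self.SCALE.color_value(b2)
        if b1 >= b2:
            assert v1 >= v2

    def test_idempotent_under_rescaling(self):
        for b in (50.0, 137.5, 250.0):
            v = self.SCALE.color_value(b)
            again = ColorScale(self.SCALE.min_bitscore,
                               self.SCALE.max_bitscore).color_value(b)
            assert v == again


class TestProjectHits:
    def test_every_resolvable_hit_yields_one_result(self, projected):
        n_in = len(projected["hits"])
        assert len(projected["rows"]) + len(projected["unresolved"]) == n_in

    def test_simulated_subjects_all_resolve(self, projected):
        assert projected["unresolved"] == []

    def test_locus_tag_fallback(self):
        reps = assign_replicon_indices([Replicon("rep", 100_000)])
        feats = [GeneFeature("rep", "gene1", 1, 999, "+", locus_tag="LT_0001")]
        hits = [make_hit(subject_id="LT_0001", s_start=1, s_end=999)]
        rows, unresolved = project_hits(hits, feats, reps)
        assert len(rows) == 1 and unresolved == []

    def test_unresolvable_counted_not_dropped(self):
        reps = assign_replicon_indices([Replicon("rep", 100_000)])
        feats = [GeneFeature("rep", "gene1", 1, 999, "+")]
        hits = [make_hit(subject_id="nope", s_start=1, s_end=10)]
        rows, unresolved = project_hits(hits, feats, reps)
        assert rows == [] and len(unresolved) == 1
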