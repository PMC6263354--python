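"""Promoter library design: backbones, insertion, screening, oligos."""

import dataclasses

import pytest

from fermlogic.promoters import (
    DEFAULT_TAILS,
    OPERATORS,

    DesignSpec,
    LibraryMember,
    Operator,
    apply_filters,
    build_library,
    dual_insert,
    finalize_oligo,
    generate_backbones,
    has_bsai,
    has_repeat,
    library_hash,
    scan_insert,
    spurious_promoter_pairs,
)

CRP = Operator("CRP", OPERATORS["CRP"])
FNR = Operator("FNR", OPERATORS["FNR"])
FRUR = Operator("FruR", OPERATORS["FruR"])


@pytest.fixture(scope="module")
def backbones():
    return generate_backbones(seed=7)


@pytest.fixture(scope="module")
def small_spec(backbones):
    """Two backbones, reduced dual grid: fast but fully representative."""
    return DesignSpec(
        backbones=tuple(backbones[:2]),
        operators=(CRP, FNR, FRUR),
        dual_site_shifts=(0,),
    )


class TestBackboneGeneration:
    def test_twelve_backbones_from_four_cores(self, backbones):
        assert len(backbones) == 12
        assert len({b.core_name for b in backbones}) == 4
        assert all(len(b) == 150 for b in backbones)

    def test_deterministic_for_fixed_seed(self, backbones):
        again = generate_backbones(seed=7)
        assert [b.sequence for b in again] == [b.sequence for b in backbones]
        different = generate_backbones(seed=8)
        assert [b.sequence for b in different] != [b.sequence for b in backbones]

    def test_single_spacer_gives_four(self):
        assert len(generate_backbones(n_spacers=1, seed=1)) == 4

    def test_backbones_are_screen_clean(self, backbones):
        for b in backbones:
            assert apply_filters(b.sequence, whitelist=(b.minus35, b.minus10)) == ()

    def test_element_coordinates_consistent(self, backbones):
        b = backbones[0]
        assert b.minus35[0] == 25 and b.minus10[0] == 48
        assert b.plus1 == 60 and b.core_span == (25, 60)


class TestScanInsert:
    def test_full_span_candidate_count(self, backbones):
        # 150 bp backbone, 14 bp operator, replace: 150 - 14 + 1
        assert len(scan_insert(backbones[0], FNR)) == 137

    def test_position_zero_starts_with_operator(self, backbones):
        first = scan_insert(backbones[0], CRP)[0]
        assert first.sequence.startswith(CRP.sequence)
        assert first.positions == (0,)

    def test_operator_present_at_recorded_offset(self, backbones):
        for m in scan_insert(backbones[1], FRUR):
            p = m.positions[0]
            assert m.sequence[p : p + len(FRUR)] == FRUR.sequence
            assert len(m.sequence) == 150  # replace preserves length

    def test_insert_mode_grows_sequence(self, backbones):
        m = scan_insert(backbones[0], FNR, mode="insert", positions=[10])[0]
        assert len(m.sequence) == 150 + 14
        assert m.sequence[10:24] == FNR.sequence


class TestDualInsert:
    def test_thirteen_spacings_per_site(self, backbones):
        got = dual_insert(backbones[0], CRP, FNR, "plus1")
        assert len(got) == 13

    def test_both_operators_present_verbatim(self, backbones):
        for m in dual_insert(backbones[0], FNR, FRUR, "minus10_minus35_spacer"):
            (pa, pb) = m.positions
            assert m.sequence[pa : pa + len(FNR)] == FNR.sequence
            assert m.sequence[pb : pb + len(FRUR)] == FRUR.sequence

    def test_zero_offset_reproduces_nominal_geometry(self, backbones):
        b = backbones[0]
        m = next(
            x for x in dual_insert(b, CRP, FNR, "plus1") if
            x.positions[1] - (x.positions[0] + len(CRP)) == 6
        )
        assert m.positions[0] == b.plus1

    def test_infeasible_geometry_skipped(self, backbones):
        # a CRP+FNR pair cannot fit upstream of the -35 in 25 bp
        got = dual_insert(backbones[0], CRP, FNR, "upstream_minus35")
        assert got == []


class TestFilters:
    def test_bsai_both_strands(self):
        assert has_bsai("AAAGGTCTCAAA")
        assert has_bsai("AAAGAGACCAAA")  # reverse-complement site
        carrier = "ATCGGATTCAAGCTTGCAGGTCTCTTGGCCAATGC"  # repeat-free
        assert apply_filters(carrier) == ("bsai",)

    def test_direct_repeat_of_six(self):
        seq = "ACGTAACTGCATGCCTGAACGTAA"  # ACGTAA twice
        assert has_repeat(seq)
        assert "repeat" in apply_filters(seq)

    def test_intended_core_whitelisted(self, backbones):
        b = backbones[0]
        assert spurious_promoter_pairs(b.sequence, (b.minus35, b.minus10)) == []
        # without the whitelist the core's own -35/-10 pair is flagged
        assert spurious_promoter_pairs(b.sequence) != []

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            apply_filters("ACGTN")


class TestFinalize:
    def test_oligo_is_design_plus_forty(self, small_spec):
        members, _ = build_library(small_spec)
        oligo = finalize_oligo(members[0], small_spec)
        assert len(oligo) == 190
        assert oligo.startswith(DEFAULT_TAILS[0])
        assert oligo.endswith(DEFAULT_TAILS[1])

    def test_unscreened_member_rejected(self, backbones):
        m = scan_insert(backbones[0], CRP)[0]  # filter_status is None
        with pytest.raises(ValueError):
            finalize_oligo(m, DesignSpec(backbones=tuple(backbones[:1]),
                                         operators=(CRP,)))

    def test_junction_bsai_rejected(self, small_spec):
        member = LibraryMember(
            sequence="A" * 145 + "GGTCT",  # + tail 'C...' makes GGTCTC
            backbone="x", operators=("CRP",), positions=(0,),
            mode="replace", filter_status=(),
        )
        with pytest.raises(ValueError, match="junction"):
            finalize_oligo(member, small_spec)


class TestBuildLibrary:
    def test_members_clean_unique_uniform(self, small_spec):
        members, summary = build_library(small_spec)
        seqs = [m.sequence for m in members]
        assert len(seqs) == len(set(seqs))
        assert all(len(s) == 150 for s in seqs)
        for m in members:
            assert not has_bsai(m.sequence)
            assert not has_repeat(m.sequence)
            for op, p in zip(m.operators, m.positions):
                assert m.sequence[p : p + len(OPERATORS[op])] == OPERATORS[op]
        assert summary.n_pass == len(members)
        assert summary.n_raw > summary.n_pass

    def test_removing_a_filter_never_shrinks_the_library(self, small_spec):
        full, _ = build_library(small_spec)
        relaxed, _ = build_library(
            dataclasses.replace(small_spec, filters=frozenset({"bsai", "sigma70"}))
        )
        assert len(relaxed) >= len(full)

    def test_deterministic_hash(self, small_spec):
        a, _ = build_library(small_spec)
        b, _ = build_library(small_spec)
        assert library_hash(a) == library_hash(b)

    def test_spec_validation(self, backbones):
        with pytest.raises(ValueError):
            DesignSpec(backbones=tuple(backbones[:1]), operators=(CRP,),
                       dual_spacings=(0, 9))
        with pytest.raises(ValueError):
            DesignSpec(backbones=tuple(backbones[:1]), operators=(CRP,),
                       amplification_tails=("ACGT", "ACGT"))
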