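import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from repeatlens.errors import FormatError, MappingError, ParameterError
from repeatlens.synthgen import toy_structure_atoms
from repeatlens.xlinkseq import (
    ChainAssignment,
    CrosslinkRecord,
    StructureMap,
    consensus_profile,
    count_pairs,
    filter_by_score,
    find_motif,
    flag_consistency,
    highlight,
    load_structure,
    map_distance,
    read_crosslinks,
    span_length,
)

TOY_MAP = StructureMap(
    structure_id="TOY",
    chains={"A": ChainAssignment("FAN1"), "B": ChainAssignment("MLH1")},
)


def rec(pa, ra, pb, rb, score=25.0, la=None, lb=None):
    return CrosslinkRecord(
        protein_a=pa, res_a=ra, protein_b=pb, res_b=rb, score=score,
        residue_letter_a=la, residue_letter_b=lb,
    )


class TestRecords:
    def test_intra_kind(self):
        assert rec("FAN1", 539, "FAN1", 646).kind == "intra"

    def test_inter_kind(self):
        assert rec("FAN1", 100, "MLH1", 200).kind == "inter"

    def test_nonlinkable_letter_warns(self):
        r = rec("FAN1", 50, "MLH1", 60, la="G", lb="K")
        assert len(r.linkability_warnings()) == 1

    def test_n_terminus_is_linkable(self):
        r = rec("FAN1", 1, "MLH1", 60, la="M", lb="K")
        assert r.linkability_warnings() == []

    def test_positions_one_based(self):
        with pytest.raises(ValueError):
            rec("A", 0, "B", 5)


class TestReadCrosslinks:
    def test_fixture_reads_with_kinds(self, xlink_fixture):
        records = read_crosslinks(xlink_fixture.links_path)
        assert len(records) == len(xlink_fixture.records)
        kinds = {r.kind for r in records}
        assert kinds == {"inter", "intra"}

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("protein1\tresidue1\n")
        with pytest.raises(FormatError):
            read_crosslinks(p)

    def test_linkability_warnings_collected(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text(
            "protein1\tresidue1\taa1\tprotein2\tresidue2\taa2\tscore\n"
            "A\t5\tG\tB\t6\tK\t30\n"
        )
        warn: list[str] = []
        read_crosslinks(p, warn=warn)
        assert len(warn) == 1


class TestFilterByScore:
    def test_strictly_above_cutoff(self):
        records = [rec("A", 1, "B", 2, score=s) for s in (19.9, 20.0, 20.1)]
        kept = filter_by_score(records, min_score=20)
        assert [r.score for r in kept] == [20.1]

    def test_empty_input(self):
        assert filter_by_score([]) == []

    def test_minus_infinity_is_identity(self):
        records = [rec("A", 1, "B", 2, score=s) for s in (0.0, 50.0)]
        assert filter_by_score(records, min_score=float("-inf")) == records

    def test_idempotent(self):
        records = [rec("A", i, "B", i + 1, score=10.0 + i) for i in range(1, 20)]
        once = filter_by_score(records, 20)
        assert filter_by_score(once, 20) == once


class TestCountPairs:
    def test_fixture_counts(self, xlink_fixture):
        records = filter_by_score(read_crosslinks(xlink_fixture.links_path), 20)
        counts = count_pairs(records)
        assert counts[("FAN1", "MLH1")] == 3
        assert counts[("FAN1", "PMS2")] == 6

    def test_duplicate_does_not_change_count(self):
        base = [rec("A", 1, "B", 2), rec("A", 3, "B", 4)]
        assert count_pairs(base + [rec("A", 1, "B", 2, score=99.0)]) == count_pairs(base)

    def test_swapped_sides_count_once(self):
        assert count_pairs([rec("A", 1, "B", 2), rec("B", 2, "A", 1)]) == {
            ("A", "B"): 1
        }

    @settings(max_examples=50, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=10),
                st.integers(min_value=1, max_value=10),
            ),
            min_size=1,
            max_size=20,
        ),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_order_and_orientation_invariance(self, pairs, seed):
        records = [rec("P", a, "Q", b) for a, b in pairs]
        rng = np.random.default_rng(seed)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        flipped = [
            rec(r.protein_b, r.res_b, r.protein_a, r.res_a) for r in shuffled
        ]
        assert count_pairs(records) == count_pairs(shuffled) == count_pairs(flipped)


class TestMapDistance:
    def test_toy_three_four_five(self):
        d = map_distance(rec("FAN1", 10, "FAN1", 20), toy_structure_atoms(), TOY_MAP)
        assert d == pytest.approx(5.0, abs=1e-12)

    def test_symmetric_in_residue_order(self):
        atoms = toy_structure_atoms()
        a = map_distance(rec("FAN1", 10, "MLH1", 5), atoms, TOY_MAP)
        b = map_distance(rec("MLH1", 5, "FAN1", 10), atoms, TOY_MAP)
        assert a == pytest.approx(b)

    def test_unresolved_residue_returns_none(self):
        d = map_distance(rec("FAN1", 999, "FAN1", 10), toy_structure_atoms(), TOY_MAP)
        assert d is None

    def test_unmapped_protein_raises(self):
        with pytest.raises(MappingError):
            map_distance(rec("PMS2", 10, "FAN1", 20), toy_structure_atoms(), TOY_MAP)

    def test_offset_bridges_numbering(self):
        smap = StructureMap(
            structure_id="TOY",
            chains={"A": ChainAssignment("FAN1", offset=5)},
        )
        d = map_distance(rec("FAN1", 5, "FAN1", 15), toy_structure_atoms(), smap)
        assert d == pytest.approx(5.0)

    def test_rigid_body_invariance_exact(self):
        """Sign-permutation rotations and integer shifts are exactly
        representable in the structure's float32 coordinates, so the
        distance is preserved to 1e-9."""
        atoms = toy_structure_atoms()
        record = rec("FAN1", 10, "MLH1", 50)
        base = map_distance(record, atoms, TOY_MAP)
        rot_z90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        rot_x90 = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        rng = np.random.default_rng(7)
        for rot in (rot_z90, rot_x90, rot_z90 @ rot_z90):
            shift = rng.integers(-100, 100, size=3).astype(float)
            moved = atoms.copy()
            moved.coord = atoms.coord @ rot.T + shift
            assert map_distance(record, moved, TOY_MAP) == pytest.approx(
                base, abs=1e-9
            )

    def test_rigid_body_invariance_random(self):
        """Arbitrary rotations/translations preserve the distance to within
        float32 coordinate precision."""
        atoms = toy_structure_atoms()
        record = rec("FAN1", 10, "MLH1", 50)
        base = map_distance(record, atoms, TOY_MAP)
        rng = np.random.default_rng(7)
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0, 50, size=3)
            moved = atoms.copy()
            moved.coord = atoms.coord @ rot.T + shift
            assert map_distance(record, moved, TOY_MAP) == pytest.approx(
                base, abs=1e-3
            )

    def test_structure_file_round_trip(self, xlink_fixture):
        atoms = load_structure(xlink_fixture.structure_path)
        smap = StructureMap.from_yaml(xlink_fixture.map_path)
        d = map_distance(rec("FAN1", 10, "FAN1", 20), atoms, smap)
        assert d == pytest.approx(5.0, abs=1e-3)  # PDB coords to 3 decimals


class TestFlagConsistency:
    def test_twenty_seven_consistent(self):
        assert flag_consistency(27.0) is True

    def test_boundary_inclusive(self):
        assert flag_consistency(30.0) is True

    def test_beyond_span(self):
        assert flag_consistency(45.0) is False

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            flag_consistency(-1.0)


def write_alignment(tmp_path, rows):
    p = tmp_path / "aln.fasta"
    p.write_text("".join(f">s{i}\n{r}\n" for i, r in enumerate(rows)))
    return p


class TestConsensus:
    def test_unanimous_column_highlighted(self, tmp_path):
        p = write_alignment(tmp_path, ["YA", "YC", "YG"])
        prof = consensus_profile(p)
        assert prof.residues[0] == "Y"
        assert prof.fractions[0] == 1.0
        assert highlight(prof) == [1]

    def test_exactly_eighty_percent_not_highlighted(self, tmp_path):
        p = write_alignment(tmp_path, ["S", "S", "S", "S", "T"])
        prof = consensus_profile(p)
        assert prof.fractions[0] == pytest.approx(0.8)
        assert highlight(prof) == []  # strict > 80%

    def test_all_gap_column(self, tmp_path):
        p = write_alignment(tmp_path, ["-A", "-A", "-A"])
        prof = consensus_profile(p)
        assert prof.residues[0] is None
        assert highlight(prof) == [2]

    def test_gaps_excluded_from_denominator(self, tmp_path):
        # 2 of 5 rows gapped; 3/3 non-gap rows agree -> fraction 1.0
        p = write_alignment(tmp_path, ["F", "F", "F", "-", "-"])
        prof = consensus_profile(p)
        assert prof.fractions[0] == 1.0

    def test_ragged_alignment_rejected(self, tmp_path):
        p = write_alignment(tmp_path, ["AB", "A"])
        with pytest.raises(FormatError):
            consensus_profile(p)


class TestFindMotif:
    def test_known_position(self):
        seq = "M" + "A" * 124 + "SPYF" + "Q" * 10
        assert find_motif(seq, "SPYF") == [126]

    def test_absent(self):
        assert find_motif("AAAA", "SPYF") == []

    def test_at_position_one(self):
        assert find_motif("SPYFAA", "SPYF") == [1]

    def test_overlapping_matches(self):
        assert find_motif("AAAA", "AA") == [1, 2, 3]

    def test_empty_motif_rejected(self):
        with pytest.raises(ParameterError):
            find_motif("AAAA", "")


class TestSpanLength:
    def test_sixty_mer(self):
        assert span_length(118, 177) == 60

    def test_spyf_span(self):
        assert span_length(126, 129) == 4

    def test_single_residue(self):
        assert span_length(7, 7) == 1

    def test_inverted_span_rejected(self):
        with pytest.raises(ParameterError):
            span_length(10, 9)


class TestFixtureContracts:
    def test_boundary_score_record_present(self, xlink_fixture):
        assert any(r.score == 20.0 for r in xlink_fixture.records)

    def test_all_residue_letters_linkable_or_terminal(self, xlink_fixture):
        for r in xlink_fixture.records:
            assert r.linkability_warnings() == []
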