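"""Residue frequency profiling, position calling, trimming, mutations."""

import numpy as np
import pytest

import paraspec as ps
from paraspec.errors import InvalidArgumentError, WildTypeMismatchError


@pytest.fixture
def toy_alignment():
    # 10 sequences; column 2: 9x R + 1x Q; column 4 has gaps
    rows = []
    for i in range(10):
        c2 = "Q" if i == 9 else "R"
        c4 = "-" if i < 2 else "K"
        rows.append((f"s{i}", f"A{c2}N{c4}C"))
    return ps.Alignment(rows)


class TestPositionFrequencies:
    def test_counting(self, toy_alignment):
        table = ps.position_frequencies(toy_alignment, toy_alignment.ids, [2])
        assert table.frequency(2, "R") == pytest.approx(0.9)
        assert table.frequency(2, "Q") == pytest.approx(0.1)
        assert int(table.n_sequences[2]) == 10

    def test_gaps_excluded_from_numerator_and_denominator(self, toy_alignment):
        table = ps.position_frequencies(toy_alignment, toy_alignment.ids, [4])
        assert int(table.n_sequences[4]) == 8
        assert table.frequency(4, "K") == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, toy_alignment):
        table = ps.position_frequencies(toy_alignment, toy_alignment.ids)
        sums = table.frequencies.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_subset_order_is_irrelevant(self, toy_alignment):
        ids = toy_alignment.ids
        a = ps.position_frequencies(toy_alignment, ids)
        b = ps.position_frequencies(toy_alignment, ids[::-1])
        assert a.frequencies.equals(b.frequencies)

    def test_empty_subset_rejected(self, toy_alignment):
        with pytest.raises(InvalidArgumentError):
            ps.position_frequencies(toy_alignment, [])


def freq_table(position_rows):
    """Build a FrequencyTable-bearing alignment-free fixture via a tiny aln."""
    n = len(next(iter(position_rows.values())))
    seqs = ["".join(position_rows[p][i] for p in sorted(position_rows))
            for i in range(n)]
    aln = ps.Alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
    return ps.position_frequencies(aln, aln.ids)


class TestParalogSpecificPositions:
    def test_planted_diagnostic_position(self):
        f1 = freq_table({1: "R" * 20 + "Q"})   # 20/21 R
        f2 = freq_table({1: "Q" * 21})
        calls = ps.paralog_specific_positions(f1, f2)
        assert calls[0].is_specific
        assert calls[0].feature == "R"
        assert calls[0].direction == 1

    def test_class_sum_rule_for_acidic_residues(self):
        f1 = freq_table({1: "E" * 10 + "D" * 9 + "A"})  # E 0.5, D 0.45
        f2 = freq_table({1: "A" * 10 + "G" * 10})  # no single residue fixed
        calls = ps.paralog_specific_positions(f1, f2)
        assert calls[0].is_specific
        assert calls[0].feature == "acidic"

    def test_modest_difference_not_called(self):
        f1 = freq_table({1: "R" * 12 + "Q" * 8})  # 0.6
        f2 = freq_table({1: "R" * 8 + "Q" * 12})  # 0.4
        calls = ps.paralog_specific_positions(f1, f2)
        assert not calls[0].is_specific

    def test_mismatched_positions_rejected(self, toy_alignment):
        f1 = ps.position_frequencies(toy_alignment, toy_alignment.ids, [1, 2])
        f2 = ps.position_frequencies(toy_alignment, toy_alignment.ids, [1, 3])
        with pytest.raises(InvalidArgumentError):
            ps.paralog_specific_positions(f1, f2)


class TestTrimAlignment:
    def test_low_occupancy_column_removed(self):
        aln = ps.Alignment(
            [("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "AK")]
        )
        trimmed, kept = ps.trim_alignment(aln)
        assert kept == [1]
        assert trimmed.n_columns == 1

    def test_conservation_exactly_at_threshold_kept(self):
        # A/C/D/E: top frequency 0.25, not strictly below 0.25
        aln = ps.Alignment([("a", "A"), ("b", "C"), ("c", "D"), ("d", "E")])
        _, kept = ps.trim_alignment(aln, min_conservation=0.25)
        assert kept == [1]

    def test_identity_alignment_passes_through(self):
        aln = ps.Alignment([("a", "AAAA"), ("b", "AAAA")])
        trimmed, kept = ps.trim_alignment(aln)
        assert kept == [1, 2, 3, 4]
        assert trimmed == aln

    def test_idempotent(self):
        aln = ps.Alignment(
            [("a", "AR--ND"), ("b", "ARK-ND"), ("c", "-RKAND"), ("d", "CRK-WD")]
        )
        once, kept1 = ps.trim_alignment(aln)
        twice, kept2 = ps.trim_alignment(once)
        assert twice == once
        assert kept2 == list(range(1, once.n_columns + 1))

    def test_removing_everything_warns(self):
        aln = ps.Alignment([("a", "A-"), ("b", "-A")])
        with pytest.warns(UserWarning):
            trimmed, kept = ps.trim_alignment(aln, min_occupancy=0.9)
        assert kept == []
        assert trimmed.n_columns == 0

    def test_invalid_thresholds_rejected(self):
        aln = ps.Alignment([("a", "A")])
        with pytest.raises(InvalidArgumentError):
            ps.trim_alignment(aln, min_occupancy=0.0)


def test_frequency_logo_plot_written(tmp_path):
    from paraspec.profiles import plot_frequency_logo

    aln = ps.Alignment([(f"s{i}", "RQ" if i < 8 else "QA") for i in range(10)])
    t1 = ps.position_frequencies(aln, [f"s{i}" for i in range(8)])
    t2 = ps.position_frequencies(aln, [f"s{i}" for i in range(8, 10)])
    out = tmp_path / "logo.png"
    plot_frequency_logo({"EnvZ1": t1, "EnvZ2": t2}, [1, 2], out)
    assert out.stat().st_size > 0


class TestCoordinateMap:
    def test_ungapped_reference_is_identity(self):
        aln = ps.Alignment([("ref", "ARND"), ("o", "ARNE")])
        cmap = ps.map_reference_position(aln, "ref")
        assert all(cmap.column(k) == k for k in range(1, 5))

    def test_leading_gap_shifts_columns(self):
        aln = ps.Alignment([("ref", "-MK"), ("o", "AMK")])
        cmap = ps.map_reference_position(aln, "ref")
        assert cmap.column(1) == 2
        assert cmap.reference_position(3) == 2

    def test_position_beyond_reference_rejected(self):
        aln = ps.Alignment([("ref", "AR")])
        with pytest.raises(InvalidArgumentError):
            ps.map_reference_position(aln, "ref", [3])


class TestApplySubstitutions:
    @pytest.fixture
    def anc_hk(self):
        # toy pre-duplication kinase fragment carrying R at reference
        # position 27 and E at 29, the residues replaced in the derived
        # paralog (R27Q / E29A)
        seq = "M" + "A" * 24 + "LRSE" + "A" * 11  # R at 27, E at 29
        aln = ps.Alignment([("ancHK", seq)])
        return aln, ps.map_reference_position(aln, "ancHK")

    def test_double_substitution(self, anc_hk):
        aln, cmap = anc_hk
        new_seq, applied = ps.apply_substitutions(
            aln.sequence("ancHK"), ["R27Q", "E29A"], cmap
        )
        assert new_seq[26] == "Q"
        assert new_seq[28] == "A"
        assert [a.mutation for a in applied] == ["R27Q", "E29A"]

    def test_wild_type_mismatch_rejected(self, anc_hk):
        aln, cmap = anc_hk
        with pytest.raises(WildTypeMismatchError, match="27"):
            ps.apply_substitutions(aln.sequence("ancHK"), ["K27Q"], cmap)

    def test_empty_mutation_list_is_identity(self, anc_hk):
        aln, cmap = anc_hk
        seq, applied = ps.apply_substitutions(aln.sequence("ancHK"), [], cmap)
        assert seq == aln.sequence("ancHK")
        assert applied == []

    def test_apply_then_reverse_restores_sequence(self, anc_hk):
        aln, cmap = anc_hk
        forward, _ = ps.apply_substitutions(
            aln.sequence("ancHK"), ["R27Q", "E29A"], cmap
        )
        back, _ = ps.apply_substitutions(forward, ["Q27R", "A29E"], cmap)
        assert back == aln.sequence("ancHK")

    def test_unparseable_mutation_rejected(self, anc_hk):
        aln, cmap = anc_hk
        with pytest.raises(InvalidArgumentError):
            ps.apply_substitutions(aln.sequence("ancHK"), ["R27"], cmap)
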