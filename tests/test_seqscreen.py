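"""Moiety scans against brute-force oracles; scale lookups; hydrophobic moment."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from discbind.seqscreen import (
    DE4_QR7,
    DE4_R7_KR10_KR11,
    MoietyPattern,
    ResidueScale,
    hydrophobic_moment,
    load_packaged_sequence,
    load_scale,
    mean_helical_penalty,
    mean_hydrophilicity,
    scan_fragments,
    scan_pairs,
    screen_proteome,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=60)


def oracle_fragment_starts(seq, window=22):
    """Regex re-implementation of the DE4-QR7 window scan (overlapping)."""
    rx = re.compile(r"(?=(.{3}[DE].{2}[QR].{" + str(window - 7) + r"}))")
    return [m.start() + 1 for m in rx.finditer(seq)]


def oracle_pair_positions(seq, acids="DE", partners="QR", offset=3):
    out = []
    for j in range(1, len(seq) + 1):
        if j + offset <= len(seq) and seq[j - 1] in acids \
                and seq[j - 1 + offset] in partners:
            out.append(j)
    return out


class TestScanFragments:
    def test_sequence_shorter_than_window_has_no_hits(self):
        assert scan_fragments("A" * 21) == []

    def test_mimetic_peptide_hits_at_start_one(self):
        seq = load_packaged_sequence("peptide_22a")
        assert [h.start for h in scan_fragments(seq)] == [1]
        assert seq[3] == "D" and seq[6] == "R"  # the D4/R7 anchor pair

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        letters = np.array(list(AA))
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=int(rng.integers(1, 80))))
            got = [h.start for h in scan_fragments(seq)]
            assert got == oracle_fragment_starts(seq)

    def test_x_never_satisfies_a_constraint(self):
        seq = "AAAXAAQAA" + "A" * 13  # X at position 4
        assert scan_fragments(seq) == []
        seq2 = "AAADAAQAA" + "A" * 13
        assert [h.start for h in scan_fragments(seq2)] == [1]

    def test_generalized_pattern_is_disjunctive(self):
        base = list("A" * 22)
        base[3] = "D"
        assert scan_fragments("".join(base), DE4_R7_KR10_KR11) == []
        for pos, letter in ((7, "R"), (10, "K"), (11, "R")):
            s = list(base)
            s[pos - 1] = letter
            assert [h.start for h in scan_fragments("".join(s), DE4_R7_KR10_KR11)] == [1]
        # Q at 7 satisfies the plain pattern but not the generalized one
        s = list(base)
        s[6] = "Q"
        assert scan_fragments("".join(s), DE4_R7_KR10_KR11) == []

    def test_every_window_hit_implies_a_pair_hit(self, rng):
        letters = np.array(list(AA))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=60))
            for h in scan_fragments(seq):
                assert h.start + 3 in scan_pairs(seq)

    def test_pattern_validation(self):
        with pytest.raises(ValueError, match="outside window"):
            MoietyPattern(window=5, constraints=((7, frozenset("D")),))
        with pytest.raises(ValueError, match="empty"):
            MoietyPattern(constraints=((4, frozenset()),))


class TestScanPairs:
    def test_helix6_region_of_apoa1_has_three_moieties(self):
        apo = load_packaged_sequence("apoa1_mature")
        assert scan_pairs(apo, region=(143, 164)) == [146, 150, 157]

    def test_empty_acid_set_gives_empty_result(self):
        assert scan_pairs("DDDDQQQQ", acid_set=frozenset()) == []

    def test_region_out_of_bounds_is_error(self):
        with pytest.raises(ValueError, match="out of bounds"):
            scan_pairs("DAAQ", region=(1, 10))

    def test_matches_double_loop_oracle(self, rng):
        letters = np.array(list(AA))
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=int(rng.integers(4, 50))))
            assert scan_pairs(seq) == oracle_pair_positions(seq)


class TestScales:
    def test_polyarginine_mean_is_the_published_arginine_value(self):
        assert mean_hydrophilicity("R" * 22) == pytest.approx(3.0)

    def test_polyalanine_has_zero_helical_penalty(self):
        assert mean_helical_penalty("A" * 22) == pytest.approx(0.0)

    @pytest.mark.parametrize("aa", list(AA))
    def test_homopolymer_mean_identity(self, aa):
        hw = load_scale("hopp_woods")
        ps = load_scale("pace_scholtz")
        assert mean_hydrophilicity(aa * 7) == pytest.approx(hw.values[aa])
        assert mean_helical_penalty(aa * 7) == pytest.approx(ps.values[aa])

    def test_fifty_fifty_sequence_hits_the_midpoint(self):
        hw = load_scale("hopp_woods")
        mid = 0.5 * (hw.values["R"] + hw.values["W"])
        assert mean_hydrophilicity("RW" * 11) == pytest.approx(mid)

    def test_mixed_sequence_matches_hand_summed_mean(self):
        ps = load_scale("pace_scholtz")
        seq = "GPAW"
        hand = sum(ps.values[a] for a in seq) / 4
        assert mean_helical_penalty(seq) == pytest.approx(hand)

    def test_unknown_residue_error_names_it(self):
        with pytest.raises(ValueError, match="X"):
            mean_hydrophilicity("AAXA")

    def test_all_scales_cover_twenty_residues(self):
        for name in ("hopp_woods", "pace_scholtz", "fauchere_pliska", "eisenberg"):
            assert set(load_scale(name).values) == set(AA)


class TestHydrophobicMoment:
    def test_zero_scale_gives_zero_moment(self):
        zero = ResidueScale("zero", {a: 0.0 for a in AA})
        assert hydrophobic_moment("ADKLRW", zero) == 0.0

    def test_single_residue_moment_is_absolute_value(self):
        fp = load_scale("fauchere_pliska")
        assert hydrophobic_moment("R") == pytest.approx(abs(fp.values["R"]))
        assert hydrophobic_moment("W") == pytest.approx(abs(fp.values["W"]))

    def test_matches_bruteforce_trigonometric_sum(self, rng):
        fp = load_scale("fauchere_pliska")
        letters = np.array(list(AA))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=22))
            s = c = 0.0
            for i, a in enumerate(seq):
                s += fp.values[a] * math.sin(math.radians(100.0) * i)
                c += fp.values[a] * math.cos(math.radians(100.0) * i)
            expect = math.hypot(s, c) / len(seq)
            assert hydrophobic_moment(seq) == pytest.approx(expect, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(seq_strategy)
    def test_moment_bounds(self, seq):
        fp = load_scale("fauchere_pliska")
        mu = hydrophobic_moment(seq, fp)
        assert 0.0 <= mu <= max(abs(fp.values[a]) for a in seq) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(seq_strategy)
    def test_reversal_with_angle_negation_preserves_moment(self, seq):
        # reversing the residue order while negating the wheel angle walks
        # the same set of wheel positions up to a global rotation
        assert hydrophobic_moment(seq[::-1], delta_deg=-100.0) == pytest.approx(
            hydrophobic_moment(seq), abs=1e-9)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            hydrophobic_moment("")


class TestScreenProteome:
    def test_planted_synthetic_record_yields_one_hit(self, tmp_path):
        from discbind.synthetic import make_sequence_set, write_fasta

        # composition without D/E/Q/R: plants are the only possible hits
        comp = {a: 1.0 for a in AA if a not in "DEQR"}
        records, truth = make_sequence_set(3, length=40, planted=[(1, 9)],
                                           background_composition=comp, seed=2)
        assert truth == [("synth_0001", 9)]
        fasta = tmp_path / "s.fa"
        write_fasta(records, fasta)
        report = screen_proteome(fasta)
        assert [(h.protein_id, h.start) for h in report.hits] == [("synth_0001", 9)]
        assert all(h.hydrophobic_moment is not None for h in report.hits)

    def test_empty_input_gives_empty_report(self):
        report = screen_proteome([])
        assert report.hits == [] and report.to_dataframe().empty

    def test_duplicate_record_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            screen_proteome([("p1", "A" * 22), ("p1", "C" * 22)])

    def test_overlapping_hits_all_reported(self):
        apo = load_packaged_sequence("apoa1_mature")
        report = screen_proteome([("apoa1", apo)])
        starts = {h.start for h in report.hits}
        # the three helix-6 moieties give overlapping windows at 143/147/154
        assert {143, 147, 154} <= starts

    def test_scores_are_pure_functions(self):
        apo = load_packaged_sequence("apoa1_mature")
        a = screen_proteome([("apoa1", apo)]).to_dataframe()
        b = screen_proteome([("apoa1", apo)]).to_dataframe()
        assert a.equals(b)
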