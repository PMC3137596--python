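"""Feature encoders: one-hot, PWM, composition, ASA, AAindex, motifs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from snopred.encoding import (
    AAindexEntry,
    EncodingError,
    MotifPattern,
    WindowVectorizer,
    asa_profile,
    build_pwm,
    composition_bias,
    concat_features,
    encode_aa20d,
    encode_aac,
    encode_asa,
    encode_motifs,
    encode_physicochemical,
    encode_pwm,
    parse_aaindex,
    parse_motif_patterns,
)
from snopred.sequence_io import ALPHABET, AMINO_ACIDS, SequenceWindow


def _window(residues: str, label="positive", asa=None) -> SequenceWindow:
    return SequenceWindow(
        residues=residues,
        center_index=len(residues) // 2,
        source=("P", 1),
        label=label,
        asa=asa,
    )


window_strategy = st.builds(
    lambda left, right: _window(left + "C" + right),
    st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=3),
    st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=3),
)


class TestOneHot:
    def test_one_hot_count_equals_window_length(self):
        vec = encode_aa20d(_window("ACA"))
        assert vec.values.sum() == 3
        assert len(vec.values) == 21 * 3

    def test_pad_symbol_occupies_pad_slot(self):
        vec = encode_aa20d(_window("-C-"))
        pad_slot = ALPHABET.index("-")
        assert vec.values[pad_slot] == 1
        assert vec.values[2 * 21 + pad_slot] == 1

    def test_unknown_residue_is_all_zero(self):
        vec = encode_aa20d(_window("XCX"))
        assert vec.values.sum() == 1  # only the center C

    @given(a=window_strategy, b=window_strategy)
    @settings(max_examples=30, deadline=None)
    def test_injective_on_distinct_windows(self, a, b):
        va, vb = encode_aa20d(a), encode_aa20d(b)
        if a.residues != b.residues:
            assert not np.array_equal(va.values, vb.values)
        else:
            assert np.array_equal(va.values, vb.values)


class TestPWM:
    def test_single_window_gives_one_hot_columns(self):
        pwm = build_pwm([_window("ACD")])
        assert (pwm.values.max(axis=0) == 1).all()
        np.testing.assert_allclose(pwm.values.sum(axis=0), 1.0)

    def test_direct_count(self):
        windows = [_window(s) for s in ["KCA", "KCA", "KCD", "ACD"]]
        pwm = build_pwm(windows)
        assert pwm.frequency("K", 0) == 0.75
        assert pwm.frequency("A", 0) == 0.25
        assert pwm.frequency("C", 1) == 1.0
        assert pwm.frequency("D", 2) == 0.5

    @given(windows=st.lists(window_strategy, min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_column_sums_one_for_any_input(self, windows):
        pwm = build_pwm(windows)
        np.testing.assert_allclose(pwm.values.sum(axis=0), 1.0, atol=1e-9)
        assert ((pwm.values >= 0) & (pwm.values <= 1)).all()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(EncodingError, match="mixed"):
            build_pwm([_window("ACD"), _window("AACDD")])

    def test_encode_training_window_of_singleton_pwm_is_all_ones(self):
        w = _window("KACDE")
        pwm = build_pwm([w])
        np.testing.assert_array_equal(encode_pwm(w, pwm).values, 1.0)

    def test_encode_disjoint_window_is_all_zeros(self):
        pwm = build_pwm([_window("KCD")])
        vec = encode_pwm(_window("ACA"), pwm)
        assert vec.values[0] == 0 and vec.values[2] == 0
        assert vec.values[1] == 1  # the shared center C

    def test_hand_counted_three_window_fixture(self):
        windows = [_window(s) for s in ["KCD", "KCE", "RCD"]]
        pwm = build_pwm(windows)
        query = _window("KCE")
        # K at -1 appears in 2/3 windows; E at +1 in 1/3; C center 3/3
        np.testing.assert_allclose(
            encode_pwm(query, pwm).values, [2 / 3, 1.0, 1 / 3]
        )


class TestAAC:
    def test_direct_composition(self):
        vec = encode_aac(_window("AAAAACAAAAA"))
        comp = dict(zip(AMINO_ACIDS, vec.values))
        assert comp["A"] == pytest.approx(10 / 11)
        assert comp["C"] == pytest.approx(1 / 11)

    def test_pads_excluded_from_denominator(self):
        vec = encode_aac(_window("----C----"))
        comp = dict(zip(AMINO_ACIDS, vec.values))
        assert comp["C"] == 1.0
        assert vec.values.sum() == pytest.approx(1.0)

    @given(w=window_strategy)
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant_and_normalised(self, w):
        shuffled = _window(w.residues[::-1][:3] + "C" + w.residues[:3])
        flat = sorted(w.residues)
        if sorted(shuffled.residues) == flat:
            np.testing.assert_allclose(
                encode_aac(w).values, encode_aac(shuffled).values
            )
        assert encode_aac(w).values.sum() == pytest.approx(1.0)

    def test_law_of_large_numbers_matches_generator(self):
        rng = np.random.default_rng(0)
        letters = [a for a in AMINO_ACIDS if a != "C"]
        windows = []
        for _ in range(2000):
            flank = rng.choice(letters, size=10)
            windows.append(
                _window("".join(flank[:5]) + "C" + "".join(flank[5:]))
            )
        mean_comp = np.mean([encode_aac(w).values for w in windows], axis=0)
        comp = dict(zip(AMINO_ACIDS, mean_comp))
        # uniform over 19 letters on 10 of 11 slots; C fills the 11th
        for aa in letters:
            assert comp[aa] == pytest.approx(10 / 11 / 19, abs=0.01)
        assert comp["C"] == pytest.approx(1 / 11, abs=0.01)


class TestASA:
    def test_encode_requires_asa(self):
        with pytest.raises(EncodingError, match="ASA"):
            encode_asa(_window("ACA"))

    def test_values_passthrough(self):
        vec = encode_asa(_window("ACA", asa=[0.1, 0.2, 0.3]))
        np.testing.assert_allclose(vec.values, [0.1, 0.2, 0.3])

    def test_profile_separates_classes(self):
        pos = [_window("ACA", asa=[0.8, 0.1, 0.2]) for _ in range(5)]
        neg = [_window("ACA", asa=[0.2, 0.1, 0.2]) for _ in range(5)]
        table = asa_profile(pos, neg)
        row = table[table.position == -1].iloc[0]
        assert row.mean_asa_positive > row.mean_asa_negative


AAINDEX_FIXTURE = """\
H SYNT000101
D Synthetic hydropathy-like scale (synthetic fixture, not a published index)
R
A Nobody A.
T Synthetic entry for parser tests
J None
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
    3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H SYNT000102
D Synthetic scale with missing values (synthetic fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.000  NA      0.500   0.200   0.100   0.300   0.400   0.600   0.700   0.800
    0.900  0.200   0.100   0.000   0.500   0.300   0.200   0.400   0.600   0.100
//
"""


class TestAAindex:
    def test_parse_two_records(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(AAINDEX_FIXTURE)
        entries = parse_aaindex(path)
        assert [e.id for e in entries] == ["SYNT000101", "SYNT000102"]
        # row order: first row A R N D C Q E G H I, second L K M F P S T W Y V
        assert entries[0].values["A"] == 1.8
        assert entries[0].values["L"] == 3.8
        assert entries[0].values["V"] == 4.2
        assert entries[0].has_na is False

    def test_na_record_flagged(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(AAINDEX_FIXTURE)
        entries = parse_aaindex(path)
        assert entries[1].has_na is True
        assert entries[1].values["R"] == 0.0

    def test_truncated_record_is_error(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(AAINDEX_FIXTURE.rsplit("//", 1)[0])
        with pytest.raises(EncodingError, match="SYNT000102"):
            parse_aaindex(path)

    def test_encoding_is_minmax_scaled(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(AAINDEX_FIXTURE)
        entry = parse_aaindex(path)[0]
        vec = encode_physicochemical(_window("ICR"), entry)
        # I has the max raw value (4.5) -> 1.0; R the min (-4.5) -> 0.0
        assert vec.values[0] == pytest.approx(1.0)
        assert vec.values[2] == pytest.approx(0.0)
        assert 0.0 <= vec.values[1] <= 1.0

    def test_pads_and_unknowns_encode_zero(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(AAINDEX_FIXTURE)
        entry = parse_aaindex(path)[0]
        vec = encode_physicochemical(_window("-CX"), entry)
        assert vec.values[0] == 0.0 and vec.values[2] == 0.0


class TestMotifs:
    def patterns(self):
        return [
            MotifPattern("any", frozenset()),
            MotifPattern(
                "k_plus1", frozenset({(1, frozenset("K"))})
            ),
            MotifPattern(
                "basic_m2_acid_p1",
                frozenset(
                    {(-2, frozenset("KRH")), (1, frozenset("DE"))}
                ),
            ),
        ]

    def test_empty_constraints_match_everything(self):
        vec = encode_motifs(_window("ACDEF"[:2] + "C" + "FG"), self.patterns())
        assert vec.values[0] == 1

    def test_mismatched_constraint_gives_zero(self):
        w = _window("AACRF")  # R at +1, not K
        vec = encode_motifs(w, self.patterns())
        assert vec.values[1] == 0

    def test_exact_match_count(self):
        w = _window("KACDE")  # K at -2, D at +1
        vec = encode_motifs(w, self.patterns())
        assert vec.values.tolist() == [1.0, 0.0, 1.0]

    def test_pattern_file_roundtrip(self, tmp_path):
        path = tmp_path / "motifs.tsv"
        path.write_text(
            "any\t\nk_plus1\t1:K\nbasic_m2_acid_p1\t-2:KRH,1:DE\n"
        )
        parsed = parse_motif_patterns(path)
        assert parsed == self.patterns()

    def test_center_constraint_must_be_cysteine(self):
        with pytest.raises(EncodingError):
            MotifPattern("bad", frozenset({(0, frozenset("K"))}))


class TestConcatAndVectorizer:
    def test_concat_preserves_blocks(self):
        w = _window("KCD")
        merged = concat_features(encode_aac(w), encode_aa20d(w))
        assert [b[0] for b in merged.blocks] == ["AAC", "AA_20D"]
        np.testing.assert_array_equal(merged.block("AAC"), encode_aac(w).values)

    def test_vectorizer_fits_pwm_on_positives_only(self):
        pos = [_window("KCD"), _window("KCE")]
        neg = [_window("ACA"), _window("GCG")]
        vec = WindowVectorizer(features=("AA_PWM", "AAC"))
        vec.fit(pos + neg, [1, 1, 0, 0])
        assert vec.pwm_.frequency("K", 0) == 1.0
        X = vec.transform(pos + neg)
        assert X.shape == (4, 3 + 20)

    def test_deterministic(self):
        w = _window("KCD")
        vec = WindowVectorizer(features=("AA_PWM", "AAC")).fit([w], [1])
        np.testing.assert_array_equal(
            vec.transform([w]), vec.transform([w])
        )


class TestCompositionBias:
    def test_identical_classes_flag_nothing(self):
        windows = [_window("KCDEF"[:2] + "C" + "DE") for _ in range(20)]
        table = composition_bias(windows, list(windows))
        assert (table.flag == "").all()

    def test_planted_enrichment_flagged_and_confirmed_by_fisher(self):
        rng = np.random.default_rng(1)
        letters = [a for a in AMINO_ACIDS if a not in "CK"]

        def rand_window(k_at_m2: bool):
            flank = list(rng.choice(letters, size=10))
            if k_at_m2:
                flank[3] = "K"  # offset -2
            return _window("".join(flank[:5]) + "C" + "".join(flank[5:]))

        pos = [rand_window(rng.random() < 0.8) for _ in range(500)]
        neg = [rand_window(rng.random() < 0.05) for _ in range(500)]
        table = composition_bias(pos, neg)
        row = table[(table.position == -2) & (table.residue == "K")].iloc[0]
        assert row.flag == "enriched"
        # independent confirmation by exact test on the same counts
        cpos = int(round(row.freq_positive * 500))
        cneg = int(round(row.freq_negative * 500))
        _, p = fisher_exact([[cpos, 500 - cpos], [cneg, 500 - cneg]])
        assert p < 0.05

    def test_swapping_classes_flips_flags(self):
        rng = np.random.default_rng(2)
        letters = [a for a in AMINO_ACIDS if a != "C"]

        def rand_window(enrich):
            flank = list(rng.choice(letters, size=4))
            if enrich:
                flank[0] = "R"
            return _window("".join(flank[:2]) + "C" + "".join(flank[2:]))

        pos = [rand_window(True) for _ in range(100)]
        neg = [rand_window(False) for _ in range(100)]
        fwd = composition_bias(pos, neg)
        rev = composition_bias(neg, pos)
        f = fwd[(fwd.position == -2) & (fwd.residue == "R")].iloc[0]
        r = rev[(rev.position == -2) & (rev.residue == "R")].iloc[0]
        assert f.flag == "enriched" and r.flag == "depleted"
        assert f.p_value == pytest.approx(r.p_value)
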