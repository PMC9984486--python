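import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from dtikit.io_formats import ALPHABET, STANDARD_AA, ProteinRecord
from dtikit.protein_encoders import (
    EncoderConfig,
    FeatureBlock,
    SEQUENCE_ENCODERS,
    encode,
    encode_bina,
    encode_dde,
    encode_eaac,
    encode_egaac,
    encode_kgram,
    encode_num,
    encode_pseaac,
    encode_tfidf,
    encoder_dimensions,
    fit_tfidf,
    normalize_sequence,
)

CFG = EncoderConfig()

seq_strategy = st.text(alphabet=STANDARD_AA, min_size=10, max_size=160)


class TestNormalize:
    def test_truncates(self):
        seq = "A" * 120
        assert normalize_sequence(seq, 100) == "A" * 100

    def test_pads(self):
        assert normalize_sequence("ACD", 5) == "ACDOO"

    def test_identity(self):
        seq = "AC" * 50
        assert normalize_sequence(seq, 100) == seq

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            normalize_sequence("", 100)


class TestEaacEgaac:
    def test_homopolymer(self):
        block = encode_eaac("A" * 100, CFG)
        a_components = [v for v, n in zip(block.values, block.feature_names) if n.endswith("_A")]
        assert a_components == [1.0] * 5
        assert block.values.sum() == 5.0

    def test_hand_count_window1(self):
        seq = "A" * 10 + "C" * 10 + "G" * 80
        block = encode_eaac(seq, CFG)
        names = list(block.feature_names)
        assert block.values[names.index("EAAC_w1_A")] == 0.5
        assert block.values[names.index("EAAC_w1_C")] == 0.5

    def test_padded_window_all_zero(self):
        block = encode_eaac(normalize_sequence("A" * 20, 100), CFG)
        assert (block.values[20:] == 0).all()  # windows 2-5 fully padded

    def test_egaac_glycine_aliphatic(self):
        block = encode_egaac("G" * 100, CFG)
        ali = [v for v, n in zip(block.values, block.feature_names) if "aliphatic" in n]
        assert ali == [1.0] * 5

    def test_egaac_negative_group(self):
        block = encode_egaac("D" * 100, CFG)
        neg = [v for v, n in zip(block.values, block.feature_names) if "negative" in n]
        assert neg == [1.0] * 5

    def test_egaac_hand_count(self):
        seq = "K" * 10 + "S" * 10 + "A" * 80
        block = encode_egaac(seq, CFG)
        names = list(block.feature_names)
        assert block.values[names.index("EGAAC_w1_positive")] == 0.5
        assert block.values[names.index("EGAAC_w1_uncharged")] == 0.5

    @settings(max_examples=40, derandomize=True)
    @given(seq_strategy)
    def test_window_sums(self, seq):
        seq_norm = normalize_sequence(seq, 100)
        block = encode_eaac(seq_norm, CFG)
        for w in range(5):
            window = seq_norm[w * 20 : (w + 1) * 20]
            total = block.values[w * 20 : (w + 1) * 20].sum()
            expected = sum(1 for c in window if c != "O") / 20
            assert math.isclose(total, expected)


class TestDde:
    def test_aaa_value(self):
        block = encode_dde("AAA")
        names = list(block.feature_names)
        assert abs(block.values[names.index("DDE_AA")] - 21.52) < 0.01

    def test_absent_dipeptide_negative(self):
        block = encode_dde("AAA")
        names = list(block.feature_names)
        assert block.values[names.index("DDE_CC")] < 0

    def test_dimension(self):
        assert len(encode_dde("ACDEFG")) == 400

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_dde("A")


class TestTfidf:
    def test_ubiquitous_residue_idf_zero(self):
        corpus = [ProteinRecord("P1", "AC"), ProteinRecord("P2", "AG")]
        model = fit_tfidf(corpus, CFG)
        assert model.idf["A"] == 0.0

    def test_idf_log10_2(self):
        corpus = [ProteinRecord("P1", "AC"), ProteinRecord("P2", "AG")]
        model = fit_tfidf(corpus, CFG)
        assert math.isclose(model.idf["C"], math.log10(2), rel_tol=1e-12)

    def test_twenty_idf_values(self):
        model = fit_tfidf([ProteinRecord("P1", "ACDE")], CFG)
        assert len(model) == 20

    def test_aacc_example(self):
        corpus = [ProteinRecord("P1", "AACC"), ProteinRecord("P2", "AG")]
        model = fit_tfidf(corpus, CFG)
        block = encode_tfidf("AACC", model)
        names = list(block.feature_names)
        assert block.values[names.index("TFIDF_A")] == 0.0
        assert math.isclose(block.values[names.index("TFIDF_C")], 0.5 * math.log10(2))

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            fit_tfidf([], CFG)

    def test_unfitted_model_errors(self):
        with pytest.raises(ValueError):
            encode_tfidf("ACDE", None)


class TestKgram:
    def test_1gram_homopolymer(self):
        block = encode_kgram("AAAA", 1)
        assert block.values[0] == 1.0
        assert block.values[1:].sum() == 0.0

    def test_2gram_acac(self):
        block = encode_kgram("ACAC", 2)
        names = list(block.feature_names)
        assert math.isclose(block.values[names.index("2GRAM_AC")], 2 / 3)
        assert math.isclose(block.values[names.index("2GRAM_CA")], 1 / 3)
        assert math.isclose(block.values.sum(), 1.0)

    def test_unsupported_k(self):
        with pytest.raises(ValueError):
            encode_kgram("ACDE", 3)

    @settings(max_examples=40, derandomize=True)
    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=120))
    def test_1gram_sums_to_one(self, seq):
        assert math.isclose(encode_kgram(seq, 1).values.sum(), 1.0)


class TestNumBina:
    def test_num_first_letter(self):
        assert encode_num("A" * 100, CFG).values[0] == 1

    def test_num_dummy_21(self):
        seq = normalize_sequence("ACD", 100)
        values = encode_num(seq, CFG).values
        assert values[:3].tolist() == [1, 2, 3]
        assert (values[3:] == 21).all()

    def test_bina_one_hot(self):
        block = encode_bina("A" * 100, CFG)
        first = block.values[:21]
        assert first[0] == 1.0 and first[1:].sum() == 0.0

    def test_bina_dummy_last_slot(self):
        seq = normalize_sequence("A", 100)
        block = encode_bina(seq, CFG)
        second = block.values[21:42]
        assert second[-1] == 1.0 and second[:-1].sum() == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(seq_strategy)
    def test_bina_blocks_sum_to_one(self, seq):
        block = encode_bina(normalize_sequence(seq, 100), CFG)
        sums = block.values.reshape(100, 21).sum(axis=1)
        assert (sums == 1.0).all()


class TestPseaac:
    def test_homopolymer(self):
        block = encode_pseaac("A" * 50, CFG)
        assert math.isclose(block.values[0], 1.0)
        assert (block.values[20:] == 0).all()

    def test_dimension_28(self):
        assert len(encode_pseaac("ACDEFGHIKL" * 3, CFG)) == 28

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_pseaac("ACDEFGHI", CFG)  # exactly lambda residues

    def test_alternating_matches_oracle(self):
        seq = "AC" * 20
        block = encode_pseaac(seq, CFG)
        expected = oracles.pseaac(seq, CFG.pseaac_lambda, CFG.pseaac_weight)
        assert np.allclose(block.values, expected, atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.text(alphabet=STANDARD_AA, min_size=9, max_size=120))
    def test_sums_to_one(self, seq):
        block = encode_pseaac(seq, CFG)
        assert (block.values >= 0).all()
        assert math.isclose(block.values.sum(), 1.0)


class TestRegistry:
    def test_declared_dimensions(self):
        dims = encoder_dimensions(CFG)
        assert dims == {
            "EAAC": 100, "EGAAC": 25, "DDE": 400, "TFIDF": 20, "1GRAM": 21,
            "2GRAM": 400, "NUM": 100, "BINA": 2100, "PSEAAC": 28,
        }

    def test_every_encoder_matches_declared_dimension(self):
        rng = np.random.default_rng(11)
        record = ProteinRecord(
            "P1", "".join(STANDARD_AA[c] for c in rng.integers(0, 20, size=77))
        )
        model = fit_tfidf([record], CFG)
        dims = encoder_dimensions(CFG)
        for name in SEQUENCE_ENCODERS:
            block = encode(name, record, CFG, model)
            assert isinstance(block, FeatureBlock)
            assert len(block) == dims[name], name

    def test_unknown_encoder(self):
        with pytest.raises(KeyError):
            encode("WAVELET", ProteinRecord("P1", "ACDEFGHIKL"), CFG)
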