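"""Encoder arithmetic, dimensionalities and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfenpred.aaindex import AAindexTable, load_aaindex_table, parse_aaindex_table
from sulfenpred.alphabet import AMINO_ACIDS, MOTIF_ALPHABET
from sulfenpred.encoders import (
    EncoderConfig,
    EncodingError,
    MinMaxParams,
    assemble_feature_matrix,
    blosum62_matrix,
    encode_aac,
    encode_aaindex,
    encode_binary,
    encode_blosum62,
    encode_cksaap,
    encode_disorder,
    encode_pssm,
    encode_secondary_structure,
    encode_surface_accessibility_raw,
    min_max_apply,
    min_max_fit,
)
from sulfenpred.motif_io import Motif
from sulfenpred.structural import mock_provider

from conftest import make_motif

motif_strategy = st.text(alphabet=AMINO_ACIDS + "X", min_size=10, max_size=10).flatmap(
    lambda left: st.text(alphabet=AMINO_ACIDS + "X", min_size=10, max_size=10).map(
        lambda right: make_motif(left + "C" + right)
    )
)


def cksaap_oracle(seq: str, k_max: int) -> np.ndarray:
    """Exhaustive pair enumeration, independent of the encoder."""
    w = len(seq)
    out = np.zeros((k_max + 1) * 400)
    for k in range(k_max + 1):
        for i in range(w):
            j = i + k + 1
            if j >= w:
                continue
            a, b = seq[i], seq[j]
            if a == "X" or b == "X":
                continue
            idx = k * 400 + AMINO_ACIDS.index(a) * 20 + AMINO_ACIDS.index(b)
            out[idx] += 1.0 / (w - k - 1)
    return out


class TestAAC:
    def test_poly_a_counts(self, poly_a_motif):
        v = encode_aac(poly_a_motif)
        assert v[AMINO_ACIDS.index("A")] == pytest.approx(20 / 21)
        assert v[AMINO_ACIDS.index("C")] == pytest.approx(1 / 21)
        assert np.count_nonzero(v) == 2

    def test_padding_contributes_nothing(self, padded_motif):
        v = encode_aac(padded_motif)
        assert v[AMINO_ACIDS.index("C")] == pytest.approx(1 / 21)
        assert v.sum() == pytest.approx(1 / 21)

    @given(motif_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_sum_conservation(self, motif):
        v = encode_aac(motif)
        n_x = motif.sequence.count("X")
        assert v.sum() == pytest.approx((21 - n_x) / 21)


class TestCKSAAP:
    def test_poly_a_k0_hand_count(self, poly_a_motif):
        v = encode_cksaap(poly_a_motif, k_max=0)
        aa = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("A")
        ac = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")
        ca = AMINO_ACIDS.index("C") * 20 + AMINO_ACIDS.index("A")
        assert v[aa] == pytest.approx(18 / 20)
        assert v[ac] == pytest.approx(1 / 20)
        assert v[ca] == pytest.approx(1 / 20)
        assert np.count_nonzero(v) == 3

    def test_default_dimension(self, poly_a_motif):
        assert encode_cksaap(poly_a_motif).shape == (2400,)

    def test_all_padded_motif_is_zero(self, padded_motif):
        # The single non-X residue forms no X-free pair at any spacing.
        assert not encode_cksaap(padded_motif).any()

    def test_k_max_too_large(self, poly_a_motif):
        with pytest.raises(EncodingError):
            encode_cksaap(poly_a_motif, k_max=20)

    @given(motif_strategy, st.integers(min_value=0, max_value=5))
    @settings(max_examples=40, derandomize=True)
    def test_matches_exhaustive_oracle(self, motif, k_max):
        v = encode_cksaap(motif, k_max=k_max)
        assert np.allclose(v, cksaap_oracle(motif.sequence, k_max))
        assert v.min() >= 0.0 and v.max() <= 1.0

    @given(st.text(alphabet=AMINO_ACIDS, min_size=10, max_size=10),
           st.text(alphabet=AMINO_ACIDS, min_size=10, max_size=10))
    @settings(max_examples=30, derandomize=True)
    def test_x_free_motif_k_blocks_sum_to_one(self, left, right):
        v = encode_cksaap(make_motif(left + "C" + right))
        for k in range(6):
            assert v[k * 400:(k + 1) * 400].sum() == pytest.approx(1.0)


class TestBinary:
    def test_cysteine_one_hot_row(self):
        m = make_motif("A" * 10 + "C" + "A" * 10)
        v = encode_binary(m)
        centre = v[10 * 21:11 * 21]
        expected = np.zeros(21)
        expected[MOTIF_ALPHABET.index("C")] = 1  # second alphabet slot
        assert np.array_equal(centre, expected)
        assert MOTIF_ALPHABET.index("C") == 1

    def test_x_uses_last_slot(self, padded_motif):
        v = encode_binary(padded_motif)
        assert v[0 * 21 + 20] == 1.0

    @given(motif_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_exactly_21_ones(self, motif):
        v = encode_binary(motif)
        assert v.shape == (441,)
        assert np.count_nonzero(v) == 21
        assert set(np.unique(v)) <= {0.0, 1.0}


class TestBlosum62:
    def test_cc_score_is_nine(self):
        m = make_motif("A" * 10 + "C" + "A" * 10)
        v = encode_blosum62(m)
        centre = v[10 * 21:11 * 21]
        assert centre[AMINO_ACIDS.index("C")] == 9.0

    def test_dimension_and_symmetry(self, poly_a_motif):
        assert encode_blosum62(poly_a_motif).shape == (441,)
        mat = blosum62_matrix()
        sub = mat.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy()
        assert np.array_equal(sub, sub.T)

    def test_locality(self):
        m1 = make_motif("A" * 10 + "C" + "A" * 10)
        m2 = make_motif("W" + "A" * 9 + "C" + "A" * 10)
        d = encode_blosum62(m1) != encode_blosum62(m2)
        assert d[:21].any() and not d[21:].any()


class TestPSSM:
    @pytest.fixture
    def profile(self):
        _, prof = mock_provider("P1", "A" * 30, seed=0)
        return prof

    def test_default_dimension_441(self, profile):
        m = Motif("P1", 15, "A" * 10 + "C" + "A" * 10)
        assert encode_pssm(m, profile).shape == (441,)

    def test_width_20_gives_420(self, profile):
        m = Motif("P1", 15, "A" * 10 + "C" + "A" * 10)
        assert encode_pssm(m, profile, width=20).shape == (420,)

    def test_table2_variant_gives_400(self, profile):
        m = Motif("P1", 15, "A" * 10 + "C" + "A" * 10)
        assert encode_pssm(m, profile, width=20, drop_terminal=True).shape == (400,)

    def test_padded_positions_zero_rows(self, profile):
        m = Motif("P1", 1, "X" * 10 + "C" + "A" * 10)  # N-terminal window
        v = encode_pssm(m, profile).reshape(21, 21)
        assert not v[:10].any()
        assert v[10:].any()


class TestAAindex:
    def test_default_table_shape(self):
        table = load_aaindex_table()
        assert len(table) == 64
        assert len(set(table.clusters)) == 8

    def test_dimension_1344(self, poly_a_motif):
        assert encode_aaindex(poly_a_motif, load_aaindex_table()).shape == (1344,)

    def test_x_value_is_mean(self):
        table = load_aaindex_table()
        for i in range(len(table)):
            assert table.values[i, 20] == pytest.approx(table.values[i, :20].mean())

    def test_constant_index_propagates(self, padded_motif):
        table = parse_aaindex_table(
            "CONST demo " + " ".join(["7"] * 20) + "\n", "inline"
        )
        v = encode_aaindex(padded_motif, table)
        assert np.allclose(v, 7.0)

    def test_missing_residue_rejected_at_load(self):
        with pytest.raises(Exception, match="20 values"):
            parse_aaindex_table("BAD demo 1 2 3\n", "inline")


class TestStructuralEncoders:
    @pytest.fixture
    def annotation(self):
        ann, _ = mock_provider("P1", "A" * 30, seed=0)
        return ann

    def test_disorder_dimension_and_centre_excluded(self, annotation):
        m = Motif("P1", 15, "A" * 10 + "C" + "A" * 10)
        v = encode_disorder(m, annotation)
        assert v.shape == (20,)
        expected = np.r_[annotation.disorder[4:14], annotation.disorder[15:25]]
        assert np.allclose(v, expected)

    def test_disorder_padded_flanks_zero(self, annotation):
        m = Motif("P1", 1, "X" * 10 + "C" + "A" * 10)
        v = encode_disorder(m, annotation)
        assert not v[:10].any()

    def test_ss_dimension_and_padding(self, annotation):
        m = Motif("P1", 1, "X" * 10 + "C" + "A" * 10)
        v = encode_secondary_structure(m, annotation)
        assert v.shape == (84,)
        assert not v[:40].any()  # ten padded positions x 4 scores

    def test_missing_annotation_is_error(self):
        m = Motif("P1", 15, "A" * 10 + "C" + "A" * 10)
        with pytest.raises(EncodingError, match="P1"):
            encode_disorder(m, None)

    def test_acc_raw_nan_padding(self, annotation):
        m = Motif("P1", 1, "X" * 10 + "C" + "A" * 10)
        v = encode_surface_accessibility_raw(m, annotation)
        assert v.shape == (147,)
        assert np.isnan(v[:70]).all()
        assert np.isfinite(v[70:]).all()


class TestMinMax:
    def test_fit_apply_midpoint(self):
        vals = np.array([[0.0], [10.0]])
        params = min_max_fit(vals, ["s"])
        out = min_max_apply(np.array([[5.0]]), params, ["s"])
        assert out[0, 0] == pytest.approx(0.5)

    def test_endpoints_exact(self):
        vals = np.array([[1.0], [3.0], [5.0]])
        params = min_max_fit(vals, ["s"])
        out = min_max_apply(vals, params, ["s"])
        assert np.allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        vals = np.full((4, 1), 2.5)
        with pytest.warns(UserWarning, match="constant"):
            params = min_max_fit(vals, ["s"])
        assert not min_max_apply(vals, params, ["s"]).any()

    def test_apply_without_fit_is_error(self):
        with pytest.raises(EncodingError, match="not fitted"):
            min_max_apply(np.zeros((1, 1)), None, ["s"])

    def test_clip_at_prediction_time(self):
        params = min_max_fit(np.array([[0.0], [1.0]]), ["s"])
        out = min_max_apply(np.array([[2.0]]), params, ["s"], clip=True)
        assert out[0, 0] == 1.0


class TestAssembly:
    def test_table2_configuration_totals_5297(self, small_strong_data):
        dataset, store, _ = small_strong_data
        fm = assemble_feature_matrix(
            dataset, providers=store, config=EncoderConfig().table2()
        )
        dims = {b.cluster_name: b.dimension for b in fm.blocks}
        assert dims == {
            "AAC": 20, "CKSAAP": 2400, "BLOSUM62": 441, "PSSM": 400,
            "AAindex": 1344, "BINARY": 441, "DISOPRED": 20, "PSIPRED": 84,
            "ACC": 147,
        }
        assert fm.n_features == 5297

    def test_default_pssm_width_totals_5338(self, small_strong_data):
        dataset, store, _ = small_strong_data
        fm = assemble_feature_matrix(dataset, providers=store)
        assert fm.n_features == 5338

    def test_sequence_only_blocks(self, small_strong_data):
        dataset, _, _ = small_strong_data
        fm = assemble_feature_matrix(
            dataset, blocks=["AAC", "CKSAAP", "BLOSUM62", "AAindex", "BINARY"]
        )
        assert fm.n_features == 20 + 2400 + 441 + 1344 + 441

    def test_deterministic_re_encoding(self, small_strong_data):
        dataset, store, _ = small_strong_data
        cfg = EncoderConfig().table2()
        a = assemble_feature_matrix(dataset, providers=store, config=cfg)
        b = assemble_feature_matrix(dataset, providers=store, config=cfg,
                                    acc_norm=a.acc_norm)
        assert np.array_equal(a.values, b.values)
        assert a.feature_names == b.feature_names

    def test_structural_without_provider_is_error(self, small_strong_data):
        dataset, _, _ = small_strong_data
        with pytest.raises(EncodingError, match="provider"):
            assemble_feature_matrix(dataset, blocks=["DISOPRED"])

    def test_unique_prefixed_column_names(self, small_strong_matrix):
        fm, _ = small_strong_matrix
        names = fm.feature_names
        assert len(names) == len(set(names))
        for b in fm.blocks:
            assert all(n.startswith(b.cluster_name + ".")
                       for n in b.feature_names)
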