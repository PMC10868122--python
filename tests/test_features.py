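"""Feature groups vs. independent brute-force constructions.

PRIM oracle: explicit enumeration of ordered occurrence pairs (p < q) with
their forward distance q - p.  Frequency/position oracles: naive substring
scans over the window string.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m1apred.features import (
    FEATURE_LENGTH,
    GROUP_SLICES,
    KMER_LEVELS,
    KmerTokenStream,
    aapiv,
    assemble,
    code_kmer,
    feature_names,
    feature_table,
    frequency_vector,
    kmer_code,
    prim,
    raapiv,
    rprim,
    sequence_matrix,
    tokenize,
)
from m1apred.seqio import validate_window
from tests.conftest import random_window


def stream_of(seq: str, k: int) -> KmerTokenStream:
    toks = tuple(kmer_code(seq[i : i + k]) for i in range(len(seq) - k + 1))
    return KmerTokenStream(k=k, tokens=toks)


def prim_oracle(seq: str, k: int) -> np.ndarray:
    toks = [kmer_code(seq[i : i + k]) for i in range(len(seq) - k + 1)]
    V = np.zeros((4**k, 4**k))
    for p in range(len(toks)):
        for q in range(p + 1, len(toks)):
            V[toks[p] - 1, toks[q] - 1] += q - p
    return V


windows_st = st.builds(
    lambda flanks: validate_window(flanks[: len(flanks) // 2] + "A" + flanks[len(flanks) // 2 :],
                                   len(flanks) + 1),
    st.text(alphabet="ACGU", min_size=10, max_size=30).filter(lambda s: len(s) % 2 == 0),
)


class TestTokenize:
    def test_overlap_definition(self):
        w = validate_window("ACGUUUUUAUUUUUUUU", 17)
        s = tokenize(w, 2)
        assert len(s) == 16
        assert s.tokens[:3] == (kmer_code("AC"), kmer_code("CG"), kmer_code("GU"))

    def test_token_count_41mer(self, rng):
        w = random_window(rng)
        assert len(tokenize(w, 3)) == 39

    @pytest.mark.parametrize("k", KMER_LEVELS)
    def test_poly_a_code_is_one(self, k):
        assert kmer_code("A" * k) == 1
        assert code_kmer(1, k) == "A" * k

    @pytest.mark.parametrize("k", KMER_LEVELS)
    def test_codes_match_string_tokenization(self, rng, k):
        w = random_window(rng)
        assert tokenize(w, k).tokens == stream_of(w.bases, k).tokens

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            tokenize(random_window(rng), 4)


class TestSequenceMatrix:
    def test_41_tokens_pack_into_7x7(self, rng):
        M = sequence_matrix(tokenize(random_window(rng), 1))
        assert M.shape == (7, 7)
        assert (M.reshape(-1)[41:] == 0).all()

    def test_four_tokens_no_padding(self):
        M = sequence_matrix(KmerTokenStream(k=1, tokens=(1, 2, 3, 4)))
        assert M.shape == (2, 2) and (M.reshape(-1) == [1, 2, 3, 4]).all()

    def test_first_cell_holds_first_token(self, rng):
        w = random_window(rng)
        s = tokenize(w, 2)
        assert sequence_matrix(s)[0, 0] == s.tokens[0]


class TestPrim:
    def test_two_token_stream(self):
        V = prim(stream_of("AC", 1))
        expected = np.zeros((4, 4))
        expected[0, 1] = 1.0  # A -> C at distance 1
        assert (V == expected).all()

    def test_identical_tokens_accumulate_distances(self):
        V = prim(stream_of("AAA", 1))
        assert V[0, 0] == 4.0  # (2-1) + (3-1) + (3-2)
        assert V.sum() == 4.0

    def test_single_token_gives_zero_matrix(self):
        assert not prim(KmerTokenStream(k=1, tokens=(3,))).any()

    @pytest.mark.parametrize("k", KMER_LEVELS)
    def test_matches_pair_enumeration_oracle(self, rng, k):
        w = random_window(rng)
        assert prim(tokenize(w, k)) == pytest.approx(prim_oracle(w.bases, k))

    @pytest.mark.parametrize("k,side", [(1, 4), (2, 16), (3, 64)])
    def test_matrix_sides(self, rng, k, side):
        assert prim(tokenize(random_window(rng), k)).shape == (side, side)


class TestRprim:
    def test_reversed_two_tokens(self):
        # reversing "AC" gives "CA": the only pair is C -> A at distance 1
        V = prim_oracle("AC"[::-1], 1)
        expected = np.zeros((4, 4))
        expected[kmer_code("C") - 1, kmer_code("A") - 1] = 1.0
        assert (V == expected).all()

    @pytest.mark.parametrize("k", KMER_LEVELS)
    def test_equals_prim_of_reversed_string(self, rng, k):
        w = random_window(rng)
        assert rprim(w, k) == pytest.approx(prim_oracle(w.bases[::-1], k))

    def test_palindromic_window_fixed_point(self):
        w = validate_window("UGCAAAAACGU", 11)
        for k in KMER_LEVELS:
            assert rprim(w, k) == pytest.approx(prim(tokenize(w, k)))


class TestFrequencyVector:
    def test_poly_a_degenerate_composition(self):
        fv = frequency_vector(validate_window("A" * 41, 41))
        nonzero = {i: v for i, v in enumerate(fv) if v}
        assert nonzero == {0: 41.0, 4: 40.0, 20: 39.0}  # A, AA, AAA slots

    def test_level_sums(self, rng):
        fv = frequency_vector(random_window(rng))
        assert fv[:4].sum() == 41
        assert fv[4:20].sum() == 40
        assert fv[20:].sum() == 39

    def test_matches_substring_count_oracle(self, rng):
        w = random_window(rng)
        fv = frequency_vector(w)
        off = {1: 0, 2: 4, 3: 20}
        for k in KMER_LEVELS:
            for code in range(1, 4**k + 1):
                kmer = code_kmer(code, k)
                expected = sum(w.bases[i : i + k] == kmer for i in range(len(w.bases) - k + 1))
                assert fv[off[k] + code - 1] == expected


class TestPositionVectors:
    def test_mono_position_sums_small_example(self):
        # "ACGA" as the leading tokens of a window is awkward; check the rule
        # directly on the mono stream of a 5-mer window UCAGU -> positions:
        w = validate_window("UCAGU", 5)
        v = aapiv(w)[:4]
        assert v[kmer_code("A") - 1] == 3
        assert v[kmer_code("C") - 1] == 2
        assert v[kmer_code("G") - 1] == 4
        assert v[kmer_code("U") - 1] == 1 + 5

    def test_mono_partition_identity(self, rng):
        L = 41
        w = random_window(rng, L)
        assert aapiv(w)[:4].sum() == L * (L + 1) / 2
        assert raapiv(w)[:4].sum() == L * (L + 1) / 2

    def test_di_level_matches_bruteforce(self, rng):
        w = random_window(rng)
        v = aapiv(w)[4:20]
        for code in range(1, 17):
            kmer = code_kmer(code, 2)
            expected = sum(i + 1 for i in range(40) if w.bases[i : i + 2] == kmer)
            assert v[code - 1] == expected

    def test_raapiv_mirror_identity(self, rng):
        # mono level: reversed-position sum for base b equals sum of (L+1-p)
        w = random_window(rng)
        L = len(w.bases)
        rv = raapiv(w)[:4]
        for code, base in enumerate("ACGU", start=1):
            expected = sum(L + 1 - (i + 1) for i, b in enumerate(w.bases) if b == base)
            assert rv[code - 1] == expected

    def test_raapiv_palindrome_fixed_point(self):
        w = validate_window("UGCAAAAACGU", 11)
        assert raapiv(w) == pytest.approx(aapiv(w))


class TestAssemble:
    def test_length_and_group_sizes(self, rng):
        fv = assemble(random_window(rng))
        assert len(fv.values) == FEATURE_LENGTH == 522
        sizes = {g: s.stop - s.start for g, s in GROUP_SLICES.items()}
        assert sizes == {"PRIM": 90, "RPRIM": 90, "FV": 84, "AAPIV": 84, "RAAPIV": 84, "SEQMAT": 90}

    def test_determinism(self, rng):
        w = random_window(rng)
        assert assemble(w).values == pytest.approx(assemble(w).values)

    def test_all_u_except_center_fv_block(self):
        w = validate_window("U" * 20 + "A" + "U" * 20, 41)
        fv = assemble(w).group("FV")
        # forced nonzero cells: U, A, and the k-mers straddling the center
        expected = {"A": 1, "U": 40, "UA": 1, "AU": 1, "UU": 38,
                    "UUA": 1, "UAU": 1, "AUU": 1, "UUU": 36}
        off = {1: 0, 2: 4, 3: 20}
        got = {}
        for k in KMER_LEVELS:
            for code in range(1, 4**k + 1):
                val = fv[off[k] + code - 1]
                if val:
                    got[code_kmer(code, k)] = int(val)
        assert got == expected

    def test_group_slices_consistent_with_direct_builders(self, rng):
        w = random_window(rng)
        full = assemble(w)
        assert full.group("FV") == pytest.approx(frequency_vector(w))
        assert full.group("AAPIV") == pytest.approx(aapiv(w))
        assert full.group("RAAPIV") == pytest.approx(raapiv(w))

    def test_feature_names_unique_and_sized(self):
        names = feature_names()
        assert len(names) == FEATURE_LENGTH and len(set(names)) == FEATURE_LENGTH

    def test_feature_table_layout(self, windows_small):
        df = feature_table(windows_small[:3])
        assert df.shape == (3, FEATURE_LENGTH + 2)
        assert list(df.columns[:1]) == ["id"] and df.columns[-1] == "label"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(windows_st)
    def test_partition_identities_hold_for_arbitrary_windows(self, w):
        L = len(w.bases)
        assert aapiv(w)[:4].sum() == L * (L + 1) / 2
        assert raapiv(w)[:4].sum() == L * (L + 1) / 2
        fv = frequency_vector(w)
        assert fv[:4].sum() == L and fv[4:20].sum() == L - 1 and fv[20:].sum() == L - 2

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(windows_st)
    def test_assemble_length_for_arbitrary_windows(self, w):
        assert len(assemble(w).values) == FEATURE_LENGTH
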