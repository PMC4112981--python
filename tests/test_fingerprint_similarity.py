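"""Structural-key fingerprints and Tanimoto similarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit.Chem import MACCSkeys

from steroidxr import (
    FingerprintError,
    KeyDictionary,
    StructuralKeyFingerprint,
    compute_fingerprint,
    similarity_panel,
    tanimoto,
)
from steroidxr.compound_library import read_smiles_file, standardize


def fp(bits):
    return StructuralKeyFingerprint(dictionary_version="public-166-v1", bits=np.array(bits))


def make_bits(on, n=166):
    bits = np.zeros(n, dtype=np.uint8)
    bits[list(on)] = 1
    return bits


class TestDictionary:
    def test_packaged_dictionary_has_166_dense_keys(self, dictionary):
        assert len(dictionary) == 166
        assert [k.index for k in dictionary.keys] == list(range(1, 167))

    def test_every_pattern_compiles(self, dictionary):
        # construction would have raised otherwise; spot-check query storage
        assert sum(q is not None for q in dictionary._queries) == 163  # 3 specials

    def test_unknown_version_rejected(self):
        with pytest.raises(FingerprintError, match="unknown dictionary"):
            KeyDictionary.load("no-such-version")


class TestComputeFingerprint:
    def test_requires_standardized_compound(self, tmp_path, dictionary):
        path = tmp_path / "x.smi"
        path.write_text("CCO ethanol\n")
        (raw,) = read_smiles_file(path)
        with pytest.raises(FingerprintError, match="standardized"):
            compute_fingerprint(raw, dictionary)

    def test_methane_sets_no_ring_or_heteroatom_keys(self, tmp_path, dictionary):
        path = tmp_path / "m.smi"
        path.write_text("C methane\n")
        (methane,) = [standardize(c) for c in read_smiles_file(path)]
        bits = compute_fingerprint(methane, dictionary)
        # ring keys (165: any ring, 163: 6-ring, 96: 5-ring), oxygen (164), N (161), S (88)
        for key_index in (88, 96, 161, 163, 164, 165):
            assert key_index not in bits.on_bits()

    def test_cortisol_sets_carbonyl_and_hydroxyl_keys(self, library, dictionary):
        bits = compute_fingerprint(library["cortisol"], dictionary).on_bits()
        assert 154 in bits  # C=O
        assert 139 in bits  # O-H

    def test_stereoisomers_identical_fingerprints(self, library, dictionary):
        a = compute_fingerprint(library["pregnanolone"], dictionary)
        b = compute_fingerprint(library["allopregnanolone"], dictionary)
        assert np.array_equal(a.bits, b.bits)
        assert tanimoto(a, b) == 1.0

    def test_agrees_with_established_public_keys_implementation(self, library, dictionary):
        """>= 95% per-bit agreement with RDKit's MACCS generator on the panel."""
        agree = total = 0
        for compound in library.values():
            mine = compute_fingerprint(compound, dictionary)
            reference = MACCSkeys.GenMACCSKeys(compound.structure)  # bit 0 unused
            for k in range(1, 167):
                total += 1
                agree += int(mine.bits[k - 1]) == int(reference.GetBit(k))
        assert agree / total >= 0.95

    def test_hex_round_trip(self, library, dictionary):
        original = compute_fingerprint(library["estradiol"], dictionary)
        restored = StructuralKeyFingerprint.from_hex(
            original.to_hex(), original.dictionary_version
        )
        assert np.array_equal(original.bits, restored.bits)


class TestTanimoto:
    def test_identity_is_one(self):
        a = fp(make_bits([0, 5, 100]))
        assert tanimoto(a, a) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        assert tanimoto(fp(make_bits([0, 1])), fp(make_bits([10, 11]))) == 0.0

    def test_hand_counted_overlap(self):
        a = fp(make_bits(range(5)))  # |a| = 5
        b = fp(make_bits([0, 1, 2, 9]))  # |b| = 4, shared = 3
        assert tanimoto(a, b) == pytest.approx(3 / 6)

    def test_empty_conventions(self):
        empty = fp(make_bits([]))
        assert tanimoto(empty, fp(make_bits([]))) == 1.0
        assert tanimoto(empty, fp(make_bits([3]))) == 0.0

    def test_dictionary_version_mismatch_rejected(self):
        other = StructuralKeyFingerprint(dictionary_version="other", bits=make_bits([1]))
        with pytest.raises(FingerprintError, match="mismatch"):
            tanimoto(fp(make_bits([1])), other)

    def test_oracle_equivalence_on_random_bit_vectors(self):
        """Exact match with a brute-force set-intersection oracle, 1000 pairs."""
        rng = np.random.default_rng(20140714)
        for _ in range(1000):
            a_bits = rng.integers(0, 2, 166).astype(np.uint8)
            b_bits = rng.integers(0, 2, 166).astype(np.uint8)
            a_set = {i for i, bit in enumerate(a_bits) if bit}
            b_set = {i for i, bit in enumerate(b_bits) if bit}
            union = len(a_set | b_set)
            expected = len(a_set & b_set) / union if union else 1.0
            assert tanimoto(fp(a_bits), fp(b_bits)) == pytest.approx(expected)

    @given(
        a=st.sets(st.integers(0, 165), max_size=166),
        b=st.sets(st.integers(0, 165), max_size=166),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        x, y = fp(make_bits(a)), fp(make_bits(b))
        forward = tanimoto(x, y)
        assert forward == tanimoto(y, x)
        assert 0.0 <= forward <= 1.0

    def test_symmetric_on_all_panel_pairs(self, library, dictionary):
        fps = [compute_fingerprint(c, dictionary) for c in library.values()]
        for a, b in itertools.combinations(fps, 2):
            assert tanimoto(a, b) == tanimoto(b, a)
            assert 0.0 <= tanimoto(a, b) <= 1.0


class TestSimilarityPanel:
    def test_cardinality_and_order(self, library, dictionary):
        targets = [library["estradiol"]]
        candidates = [library[n] for n in ("estrone", "estriol", "letrozole")]
        scores = similarity_panel(targets, candidates, dictionary)
        assert [s.query_name for s in scores] == ["estrone", "estriol", "letrozole"]

    def test_candidate_equal_to_target_scores_one(self, library, dictionary):
        (score,) = similarity_panel([library["cortisol"]], [library["cortisol"]], dictionary)
        assert score.tanimoto == 1.0

    def test_empty_candidates_empty_result(self, library, dictionary):
        assert similarity_panel([library["cortisol"]], [], dictionary) == []

    def test_nonsteroid_scores_low_against_steroid_target(self, library, dictionary):
        (score,) = similarity_panel([library["estradiol"]], [library["letrozole"]], dictionary)
        assert score.tanimoto < 0.6
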