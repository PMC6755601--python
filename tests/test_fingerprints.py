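"""Fingerprint family: MHFP, SECFP, MHECFP and the Jaccard comparators."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from shinglefp import (
    BinaryFingerprint,
    EmptyInputError,
    MinHashVector,
    ParameterMismatchError,
    fold_hashes,
    fold_to_32bit,
    generate_permutations,
    generate_planted_pair,
    hash_string_32,
    hash_strings_32,
    jaccard_distance,
    jaccard_estimated,
    jaccard_exact,
    mhecfp_from_hashes,
    minhash,
    mhfp_from_smiles,
    read_minhash_file,
    read_secfp_file,
    secfp_from_smiles,
    shingling_from_smiles,
    write_minhash_file,
    write_secfp_file,
)


class TestJaccardExact:
    @pytest.mark.parametrize(
        "A,B,expected",
        [
            ({1, 2, 3}, {2, 3, 4}, 0.5),
            ({1, 2}, {1, 2}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1}, set(), 0.0),
        ],
    )
    def test_values(self, A, B, expected):
        assert jaccard_exact(A, B) == expected
        assert jaccard_distance(A, B) == 1.0 - expected

    def test_both_empty_undefined(self):
        with pytest.raises(EmptyInputError):
            jaccard_exact(set(), set())


class TestJaccardEstimated:
    def test_self_similarity_is_one(self, params128):
        fp = minhash([1, 2, 3], params128)
        assert jaccard_estimated(fp, fp) == 1.0

    def test_fraction_of_equal_components(self):
        u = MinHashVector(np.array([1, 2, 3, 4]), "fam")
        v = MinHashVector(np.array([1, 2, 9, 9]), "fam")
        assert jaccard_estimated(u, v) == 0.5

    def test_mismatched_families_rejected(self, params128):
        other = generate_permutations(128, seed=99)
        u = minhash([1, 2], params128)
        v = minhash([1, 2], other)
        with pytest.raises(ParameterMismatchError):
            jaccard_estimated(u, v)

    def test_estimate_tracks_exact_jaccard(self, params2048):
        """Estimator lands within 3 sigma of a planted exact Jaccard."""
        A, B, J = generate_planted_pair(60, 10, 10, seed=5)  # J = 0.75
        est = jaccard_estimated(minhash(A, params2048), minhash(B, params2048))
        sigma = math.sqrt(J * (1 - J) / params2048.k)
        assert abs(est - J) <= 3 * sigma


class TestMHFP:
    def test_spelling_invariance(self, params128):
        a = mhfp_from_smiles("CCO", params=params128)
        b = mhfp_from_smiles("OCC", params=params128)
        assert a == b

    @pytest.mark.parametrize("k", [128, 1024, 2048, 4096])
    def test_output_length(self, k):
        params = generate_permutations(k, seed=42)
        fp = mhfp_from_smiles("CCO", params=params, k=k)
        assert fp.k == k

    def test_composition_identity(self, params128):
        """mhfp == minhash o sha1_32 o shingling, stage by stage."""
        smiles = "Cc1ccccc1"
        shingles = shingling_from_smiles(smiles, radius=3)
        staged = minhash(hash_strings_32(shingles), params128)
        assert mhfp_from_smiles(smiles, params=params128, radius=3) == staged

    def test_purity(self, params128):
        assert mhfp_from_smiles("c1ccncc1", params=params128) == mhfp_from_smiles(
            "c1ccncc1", params=params128
        )


class TestSECFP:
    def test_fold_is_modulo(self):
        fp = fold_hashes({5, 2053}, D=2048)
        assert fp.set_bits == (5,)  # 2053 mod 2048 == 5

    def test_bits_bounded_by_shingles(self):
        smiles = "CC(=O)Oc1ccccc1C(=O)O"
        fp = secfp_from_smiles(smiles, D=2048, radius=3)
        assert len(fp.set_bits) <= len(shingling_from_smiles(smiles, radius=3))

    def test_definitional_identity(self):
        smiles = "c1ccc2ccccc2c1"
        shingles = shingling_from_smiles(smiles, radius=3)
        expected = {hash_string_32(s) % 2048 for s in shingles}
        assert set(secfp_from_smiles(smiles).set_bits) == expected

    def test_defaults(self):
        fp = secfp_from_smiles("CCO")
        assert fp.length == 2048

    def test_identical_molecules_identical_bits(self):
        assert secfp_from_smiles("OCC") == secfp_from_smiles("CCO")

    def test_hex_round_trip(self):
        fp = secfp_from_smiles("Cc1ccccc1")
        assert BinaryFingerprint.from_hex(fp.to_hex(), fp.length) == fp


class TestMHECFP:
    def test_alias_of_minhash(self, params128):
        hashes = {10, 20, 30}
        assert mhecfp_from_hashes(hashes, params128) == minhash(hashes, params128)

    def test_estimated_matches_exact_jaccard_of_hash_sets(self, params2048):
        A, B, J = generate_planted_pair(50, 25, 25, seed=11)  # J = 0.5
        est = jaccard_estimated(
            mhecfp_from_hashes(A, params2048), mhecfp_from_hashes(B, params2048)
        )
        assert abs(est - J) <= 3 * math.sqrt(J * (1 - J) / params2048.k)

    def test_with_toolkit_ecfp_hashes(self, params128):
        """End-to-end control route: unfolded Morgan identifiers -> MinHash."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
        def ecfp_hashes(smiles):
            mol = Chem.MolFromSmiles(smiles)
            return fold_to_32bit(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
        fp1 = mhecfp_from_hashes(ecfp_hashes("CCO"), params128)
        fp2 = mhecfp_from_hashes(ecfp_hashes("OCC"), params128)
        assert fp1 == fp2


class TestFingerprintIO:
    def test_minhash_file_round_trip(self, tmp_path, params128):
        records = [
            ("ethanol", mhfp_from_smiles("CCO", params=params128)),
            ("benzene", mhfp_from_smiles("c1ccccc1", params=params128)),
        ]
        path = tmp_path / "fps.tsv"
        write_minhash_file(path, records, params128, config={"radius": 3})
        loaded, params, config = read_minhash_file(path)
        assert config == {"radius": 3}
        assert params.digest == params128.digest
        assert loaded == records

    def test_secfp_file_round_trip(self, tmp_path):
        records = [
            ("ethanol", secfp_from_smiles("CCO")),
            ("toluene", secfp_from_smiles("Cc1ccccc1")),
        ]
        path = tmp_path / "secfp.tsv"
        write_secfp_file(path, records)
        loaded, _ = read_secfp_file(path)
        assert loaded == records
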