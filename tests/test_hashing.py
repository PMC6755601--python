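"""32-bit hashing, collision estimate and the MinHash family."""

import hashlib
import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shinglefp import (
    EmptyInputError,
    MAX_HASH,
    MERSENNE_PRIME,
    PermutationParams,
    estimate_collisions,
    generate_permutations,
    hash_string_32,
    hash_strings_32,
    minhash,
)


class TestHashString32:
    def test_matches_sha1_prefix(self):
        for s in ("CC", "C1=CC=CC=C1", "C(C)O", "ünïcode"):
            expected = int.from_bytes(
                hashlib.sha1(s.encode("utf-8")).digest()[:4], "big"
            )
            assert hash_string_32(s) == expected

    def test_frozen_value(self):
        # first 4 big-endian bytes of SHA-1("CC")
        assert hash_string_32("CC") == 0xC5A976DE

    def test_range_and_determinism(self):
        vals = [hash_string_32(s) for s in ("a", "b", "CCO", "x" * 100)]
        assert all(0 <= v <= MAX_HASH for v in vals)
        assert hash_string_32("CCO") == hash_string_32("CCO")

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            hash_string_32("")

    def test_hash_strings_dedupes(self):
        out = hash_strings_32(["CC", "CC", "CCO"])
        assert out.shape == (2,)


def _collisions_decimal(m: int, N: int) -> float:
    """High-precision oracle: c(m, N) = m - N(1 - ((N-1)/N)^m) via Decimal."""
    getcontext().prec = 60
    ratio = (Decimal(N) - 1) / Decimal(N)
    return float(Decimal(m) - Decimal(N) * (1 - ratio**m))


class TestEstimateCollisions:
    @pytest.mark.parametrize("m", [2, 100, 197_604, 2_022_448, 50_000_000])
    def test_agrees_with_high_precision_oracle(self, m):
        N = 2**32 - 1
        oracle = _collisions_decimal(m, N)
        assert estimate_collisions(m, N) == pytest.approx(oracle, rel=1e-9)

    def test_one_item_cannot_collide(self):
        assert estimate_collisions(1, 10) == pytest.approx(0.0)
        assert estimate_collisions(0, 10) == 0.0

    def test_monotone_and_bounded(self):
        N = 2**32 - 1
        ms = [10, 10**3, 10**5, 10**7, 10**9]
        vals = [estimate_collisions(m, N) for m in ms]
        assert all(0 <= c < m for c, m in zip(vals, ms))
        assert vals == sorted(vals)

    def test_saturates_to_m_minus_N(self):
        # as m -> inf every slot fills: c -> m - N
        N = 1000
        m = 10**9
        assert estimate_collisions(m, N) == pytest.approx(m - N, rel=1e-6)

    def test_small_case_against_exact_expectation(self):
        # two items, N slots: collision probability exactly 1/N
        N = 17
        assert estimate_collisions(2, N) == pytest.approx(1 / N)


class TestGeneratePermutations:
    def test_lengths_distinctness_and_range(self):
        params = generate_permutations(128, seed=42)
        assert params.a.shape == params.b.shape == (128,)
        assert len(set(params.a.tolist())) == 128
        assert len(set(params.b.tolist())) == 128
        assert int(params.a.min()) >= 1  # zero multiplier is degenerate
        assert int(params.a.max()) <= MAX_HASH
        assert int(params.b.min()) >= 0
        assert params.p == MERSENNE_PRIME == 2**61 - 1

    def test_reproducible_by_seed(self):
        p1 = generate_permutations(64, seed=42)
        p2 = generate_permutations(64, seed=42)
        assert np.array_equal(p1.a, p2.a) and np.array_equal(p1.b, p2.b)
        assert p1.digest == p2.digest

    def test_different_seeds_differ(self):
        p1 = generate_permutations(64, seed=1)
        p2 = generate_permutations(64, seed=2)
        assert not np.array_equal(p1.a, p2.a)
        assert p1.digest != p2.digest

    def test_json_round_trip(self, tmp_path):
        p1 = generate_permutations(32, seed=7)
        path = tmp_path / "params.json"
        p1.save(path)
        p2 = PermutationParams.load(path)
        assert p2.digest == p1.digest
        assert np.array_equal(p2.a, p1.a)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            generate_permutations(0)


class TestMinHash:
    def test_singleton_set_formula(self, params128):
        """Min over one element is that element's hash, computed exactly."""
        v = 123_456_789
        fp = minhash([v], params128)
        for i in range(params128.k):
            expected = (
                (int(params128.a[i]) * v + int(params128.b[i])) % MERSENNE_PRIME
            ) % MAX_HASH
            assert int(fp.components[i]) == expected

    def test_empty_set_rejected(self, params128):
        with pytest.raises(EmptyInputError):
            minhash([], params128)

    def test_values_out_of_range_rejected(self, params128):
        with pytest.raises(ValueError):
            minhash([2**32], params128)

    def test_identical_sets_identical_vectors(self, params128):
        a = minhash([1, 5, 9], params128)
        b = minhash([9, 1, 5, 5], params128)
        assert a == b

    def test_components_within_range(self, params128):
        rng = np.random.default_rng(0)
        fp = minhash(rng.integers(0, 2**32, 100, dtype=np.uint64), params128)
        assert fp.components.max() <= MAX_HASH - 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        A=st.sets(st.integers(0, MAX_HASH), min_size=1, max_size=50),
        B=st.sets(st.integers(0, MAX_HASH), min_size=1, max_size=50),
    )
    def test_union_min_identity(self, A, B, params128):
        """minhash(A | B) is the componentwise minimum of the parts."""
        u = minhash(A | B, params128)
        expected = np.minimum(
            minhash(A, params128).components, minhash(B, params128).components
        )
        assert np.array_equal(u.components, expected)

    def test_exact_arithmetic_at_extremes(self, params128):
        """No overflow for the largest admissible inputs."""
        v = MAX_HASH
        fp = minhash([v], params128)
        for i in (0, params128.k - 1):
            expected = (
                (int(params128.a[i]) * v + int(params128.b[i])) % MERSENNE_PRIME
            ) % MAX_HASH
            assert int(fp.components[i]) == expected
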