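"""32-bit string hashing, MinHash function family, and collision estimation.

Shingle strings are mapped to 32-bit unsigned integers by truncating their
SHA-1 digest.  A MinHash signature of a hash set is then the componentwise
minimum of k universal hash functions

    h_i(v) = ((a_i * v + b_i) mod p) mod (2^32 - 1),   p = 2^61 - 1,

with a_i, b_i drawn once, reproducibly, from {0, ..., 2^32 - 1} (a_i != 0).
Because a_i and v are both below 2^32, the product a_i * v + b_i stays below
2^64, so plain unsigned 64-bit arithmetic is exact.

The expected number of collisions when hashing m distinct strings uniformly
into N slots follows from a generalisation of the birthday problem:

    c(m, N) = m - N * (1 - ((N - 1) / N)^m)

evaluated here in log space (``expm1``/``log1p``) so the tiny per-string
collision probability survives at N = 2^32 - 1.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import EmptyInputError, ParameterMismatchError

__all__ = [
    "MERSENNE_PRIME",
    "MAX_HASH",
    "PermutationParams",
    "MinHashVector",
    "hash_string_32",
    "hash_strings_32",
    "estimate_collisions",
    "generate_permutations",
    "minhash",
]

#: Modulus of the universal hash family: the Mersenne prime 2^61 - 1.
MERSENNE_PRIME = (1 << 61) - 1
#: Output range of the 32-bit string hash: {0, ..., 2^32 - 1}.
MAX_HASH = (1 << 32) - 1

DEFAULT_SEED = 42


def hash_string_32(s: str) -> int:
    """Hash a non-empty string to a 32-bit unsigned integer.

    The value is the first 4 bytes of the SHA-1 digest of the UTF-8 encoded
    string, read big-endian — a fixed, platform-independent choice.
    """
    if not s:
        raise ValueError("cannot hash the empty string")
    return int.from_bytes(hashlib.sha1(s.encode("utf-8")).digest()[:4], "big")


def hash_strings_32(strings) -> np.ndarray:
    """Hash an iterable of strings; returns sorted unique uint32 values."""
    values = {hash_string_32(s) for s in strings}
    return np.fromiter(sorted(values), dtype=np.uint64, count=len(values))


def estimate_collisions(m: int, N: int) -> float:
    """Expected number of colliding insertions of m uniform hashes into N slots.

    Uses ``c(m, N) = m - N * (1 - ((N-1)/N)^m)`` computed as
    ``m + N * expm1(m * log1p(-1/N))``, which is exact to double precision
    even when ``m / N`` is tiny (naive powering of (N-1)/N returns exactly m
    collisions ... minus m, i.e. garbage, once the ratio rounds to 1.0).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    if m == 0:
        return 0.0
    # N * (1 - ((N-1)/N)^m) = -N * expm1(m * log1p(-1/N))
    return m + N * math.expm1(m * math.log1p(-1.0 / N))


@dataclass(frozen=True)
class PermutationParams:
    """The k (a_i, b_i) pairs defining a MinHash function family.

    Regeneration with the same ``(k, seed)`` is bit-identical; the entries
    of ``a`` are pairwise distinct and nonzero (a zero multiplier would
    collapse its hash function to the constant b_i), the entries of ``b``
    pairwise distinct.  ``digest`` identifies the family so that vectors
    hashed under different families are never compared.
    """

    a: np.ndarray
    b: np.ndarray
    k: int
    seed: int
    p: int = MERSENNE_PRIME

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=np.uint64))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=np.uint64))
        if self.a.shape != (self.k,) or self.b.shape != (self.k,):
            raise ValueError("a and b must both have length k")

    @property
    def digest(self) -> str:
        """Short hex digest identifying this hash family."""
        h = hashlib.sha1()
        h.update(f"{self.k}:{self.seed}:{self.p}:".encode())
        h.update(self.a.tobytes())
        h.update(self.b.tobytes())
        return h.hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "p": self.p,
                "a": self.a.tolist(),
                "b": self.b.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PermutationParams":
        doc = json.loads(text)
        params = cls(
            a=np.asarray(doc["a"], dtype=np.uint64),
            b=np.asarray(doc["b"], dtype=np.uint64),
            k=int(doc["k"]),
            seed=int(doc["seed"]),
            p=int(doc["p"]),
        )
        return params

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PermutationParams":
        return cls.from_json(Path(path).read_text())


def _sample_distinct(rng: np.random.Generator, k: int, low: int) -> np.ndarray:
    """Draw k pairwise-distinct uint32 values in [low, 2^32 - 1] by rejection."""
    seen: list[int] = []
    have: set[int] = set()
    while len(seen) < k:
        draw = rng.integers(low, 1 << 32, size=k - len(seen), dtype=np.uint64)
        for v in draw.tolist():
            if v not in have:
                have.add(v)
                seen.append(v)
    return np.asarray(seen, dtype=np.uint64)


def generate_permutations(k: int, seed: int = DEFAULT_SEED) -> PermutationParams:
    """Generate the reproducible MinHash family for a given (k, seed).

    ``a`` entries are distinct and drawn from [1, 2^32 - 1]; ``b`` entries
    are distinct and drawn from [0, 2^32 - 1].  A value may appear in both
    vectors; uniqueness is enforced within each.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    a = _sample_distinct(rng, k, low=1)
    b = _sample_distinct(rng, k, low=0)
    return PermutationParams(a=a, b=b, k=k, seed=seed)


@dataclass(frozen=True)
class MinHashVector:
    """A k-dimensional MinHash signature.

    ``components[i]`` is the minimum of hash function i over the input set;
    each lies in [0, 2^32 - 2].  Signatures are comparable only when they
    share ``params_fingerprint`` (same hash family).
    """

    components: np.ndarray
    params_fingerprint: str

    def __post_init__(self):
        comp = np.asarray(self.components, dtype=np.uint32)
        comp.setflags(write=False)
        object.__setattr__(self, "components", comp)

    @property
    def k(self) -> int:
        return int(self.components.shape[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, MinHashVector):
            return NotImplemented
        return (
            self.params_fingerprint == other.params_fingerprint
            and np.array_equal(self.components, other.components)
        )

    def __hash__(self):
        return hash((self.params_fingerprint, self.components.tobytes()))


def minhash(values, params: PermutationParams) -> MinHashVector:
    """MinHash signature of a set of 32-bit hash values.

    ``component[i] = min over v of ((a_i * v + b_i) mod p) mod (2^32 - 1)``.
    All arithmetic runs in uint64, which is exact here: a_i, v < 2^32 so
    a_i * v + b_i < 2^64.

    Raises
    ------
    EmptyInputError
        If the value set is empty (MinHash of the empty set is undefined).
    """
    if isinstance(values, np.ndarray):
        v = np.unique(values).astype(np.uint64)
    else:
        v = np.fromiter(sorted({int(x) for x in values}), dtype=np.uint64)
    if v.size == 0:
        raise EmptyInputError("MinHash of the empty set is undefined")
    if np.any(v > MAX_HASH):
        raise ValueError("hash values must be 32-bit unsigned integers")
    # (k, m) table of universal hash values; exact in uint64 (see module doc)
    table = (params.a[:, None] * v[None, :] + params.b[:, None]) % np.uint64(
        params.p
    ) % np.uint64(MAX_HASH)
    comp = table.min(axis=1).astype(np.uint32)
    return MinHashVector(components=comp, params_fingerprint=params.digest)


def check_compatible(u: MinHashVector, v: MinHashVector) -> None:
    """Raise unless two signatures come from the same hash family."""
    if u.params_fingerprint != v.params_fingerprint or u.k != v.k:
        raise ParameterMismatchError(
            "MinHash vectors built from different hash families (or different "
            "k) cannot be compared"
        )
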