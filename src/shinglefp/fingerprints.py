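"""The user-facing fingerprint family and Jaccard comparators.

Three fingerprints share one pipeline (shingling -> 32-bit hashing ->
reduction):

* **MHFP** — MinHash of the hashed molecular shingling.  MHFP4/6/8 denote
  maximum substructure *diameters* 4/6/8, i.e. radii 2/3/4; the default is
  MHFP6 (radius 3) at k = 2048, the variant that performs best overall.
* **SECFP** — the "SMILES extended connectivity fingerprint": the same
  hashed shingling folded into a D-bit binary vector by ``h mod D``, the
  folding used for classic circular fingerprints.  Default D = 2048,
  radius 3 (SECFP6).
* **MHECFP** — the control: MinHash applied to an externally supplied set
  of unfolded circular-fingerprint (ECFP) identifiers, so shingling and
  minhashing effects can be separated.  Identifiers wider than 32 bits are
  reduced modulo 2^32 by the caller (or via :func:`fold_to_32bit`).

Similarity is Jaccard (Tanimoto), J(A, B) = |A n B| / |A u B|; the distance
1 - J is a metric.  ``jaccard_estimated`` on MinHash signatures is an
unbiased estimator of the exact Jaccard of the underlying hash sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EmptyInputError, ParameterMismatchError
from .hashing import (
    MinHashVector,
    PermutationParams,
    check_compatible,
    generate_permutations,
    hash_string_32,
    hash_strings_32,
    minhash,
)
from .shingling import DEFAULT_RADIUS, shingling_from_smiles

__all__ = [
    "BinaryFingerprint",
    "jaccard_exact",
    "jaccard_distance",
    "jaccard_estimated",
    "mhfp_from_smiles",
    "secfp_from_smiles",
    "mhecfp_from_hashes",
    "fold_hashes",
    "fold_to_32bit",
    "write_minhash_file",
    "read_minhash_file",
    "write_secfp_file",
    "read_secfp_file",
    "DEFAULT_K",
    "DEFAULT_D",
]

DEFAULT_K = 2048
DEFAULT_D = 2048


@dataclass(frozen=True)
class BinaryFingerprint:
    """A folded binary fingerprint: D bits, stored as the sorted set bits."""

    length: int
    set_bits: tuple[int, ...]

    def __post_init__(self):
        bits = tuple(sorted(set(int(b) for b in self.set_bits)))
        if bits and (bits[0] < 0 or bits[-1] >= self.length):
            raise ValueError("bit index out of range")
        object.__setattr__(self, "set_bits", bits)

    def to_dense(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        arr[list(self.set_bits)] = 1
        return arr

    def to_hex(self) -> str:
        """Hex string of the bit vector (bit i = bit i of the D-bit integer)."""
        value = 0
        for b in self.set_bits:
            value |= 1 << b
        width = (self.length + 3) // 4
        return format(value, f"0{width}x")

    @classmethod
    def from_hex(cls, text: str, length: int) -> "BinaryFingerprint":
        value = int(text, 16)
        bits = [i for i in range(length) if (value >> i) & 1]
        return cls(length=length, set_bits=tuple(bits))


def jaccard_exact(A: Iterable, B: Iterable) -> float:
    """Exact Jaccard similarity |A n B| / |A u B| of two sets."""
    sa, sb = set(A), set(B)
    union = sa | sb
    if not union:
        raise EmptyInputError("Jaccard of two empty sets is undefined (0/0)")
    return len(sa & sb) / len(union)


def jaccard_distance(A: Iterable, B: Iterable) -> float:
    """Jaccard distance 1 - J(A, B); a metric on sets."""
    return 1.0 - jaccard_exact(A, B)


def jaccard_estimated(u: MinHashVector, v: MinHashVector) -> float:
    """MinHash estimate of Jaccard similarity: the fraction of equal components.

    Both signatures must come from the same hash family (identical
    ``params_fingerprint``); estimates across families are meaningless.
    """
    check_compatible(u, v)
    return float(np.count_nonzero(u.components == v.components)) / u.k


def mhfp_from_smiles(
    smiles: str,
    params: PermutationParams | None = None,
    k: int = DEFAULT_K,
    radius: int = DEFAULT_RADIUS,
    include_rings: bool = True,
    min_radius: int = 1,
    seed: int = 42,
) -> MinHashVector:
    """MHFP fingerprint of a molecule: MinHash of its hashed shingling.

    Defaults give MHFP6 (radius 3, k = 2048).  Equals, definitionally,
    ``minhash({sha1_32(s) for s in shingling(smiles, radius)}, params)``.
    """
    if params is None:
        params = generate_permutations(k, seed)
    elif params.k != k and k != DEFAULT_K:
        raise ParameterMismatchError("explicit k disagrees with params.k")
    shingling = shingling_from_smiles(
        smiles, radius=radius, include_rings=include_rings, min_radius=min_radius
    )
    return minhash(hash_strings_32(shingling), params)


def fold_hashes(hashes: Iterable[int], D: int) -> BinaryFingerprint:
    """Fold a set of hash values into a D-bit binary fingerprint via h mod D."""
    if D < 1:
        raise ValueError("fingerprint length D must be >= 1")
    return BinaryFingerprint(length=D, set_bits=tuple({int(h) % D for h in hashes}))


def secfp_from_smiles(
    smiles: str,
    D: int = DEFAULT_D,
    radius: int = DEFAULT_RADIUS,
    include_rings: bool = True,
    min_radius: int = 1,
) -> BinaryFingerprint:
    """SECFP fingerprint: the hashed shingling folded modulo D.

    Defaults give SECFP6 (radius 3, D = 2048).
    """
    shingling = shingling_from_smiles(
        smiles, radius=radius, include_rings=include_rings, min_radius=min_radius
    )
    return fold_hashes((hash_string_32(s) for s in shingling), D)


def fold_to_32bit(hashes: Iterable[int]) -> set[int]:
    """Reduce arbitrary-width hash identifiers into the 32-bit universe."""
    return {int(h) % (1 << 32) for h in hashes}


def mhecfp_from_hashes(hashes, params: PermutationParams) -> MinHashVector:
    """MHECFP fingerprint: MinHash of a set of unfolded ECFP identifiers.

    A named alias of :func:`shinglefp.hashing.minhash` — the caller obtains
    the unfolded circular-fingerprint identifiers from a chemistry toolkit
    (reduced to 32 bits if wider) and this entry point minhashes them.
    """
    return minhash(hashes, params)


# ---------------------------------------------------------------------------
# fingerprint file I/O: one record per line, identifier TAB payload, plus a
# JSON sidecar carrying the configuration needed to reproduce the vectors
# ---------------------------------------------------------------------------

def write_minhash_file(
    path: str | Path,
    records: Sequence[tuple[str, MinHashVector]],
    params: PermutationParams,
    config: dict | None = None,
) -> None:
    """Write MinHash vectors as 'identifier TAB comma-separated components'.

    A sidecar ``<path>.json`` stores the hash-family parameters and any
    extra configuration so the file is reproducible and comparable.
    """
    path = Path(path)
    with open(path, "w") as handle:
        for identifier, fp in records:
            if fp.params_fingerprint != params.digest:
                raise ParameterMismatchError(
                    f"record {identifier!r} was not built with the given params"
                )
            comps = ",".join(str(int(c)) for c in fp.components)
            handle.write(f"{identifier}\t{comps}\n")
    sidecar = {"params": json.loads(params.to_json()), "config": config or {}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_minhash_file(
    path: str | Path,
) -> tuple[list[tuple[str, MinHashVector]], PermutationParams, dict]:
    """Read a MinHash fingerprint file written by :func:`write_minhash_file`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = PermutationParams.from_json(json.dumps(sidecar["params"]))
    digest = params.digest
    records = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            identifier, comps = line.split("\t")
            vec = np.fromiter((int(c) for c in comps.split(",")), dtype=np.uint32)
            records.append(
                (identifier, MinHashVector(components=vec, params_fingerprint=digest))
            )
    return records, params, sidecar.get("config", {})


def write_secfp_file(
    path: str | Path,
    records: Sequence[tuple[str, BinaryFingerprint]],
    config: dict | None = None,
) -> None:
    """Write binary fingerprints as 'identifier TAB hex-bitstring'."""
    path = Path(path)
    lengths = {fp.length for _, fp in records}
    if len(lengths) > 1:
        raise ValueError("all fingerprints in one file must share length D")
    D = lengths.pop() if lengths else DEFAULT_D
    with open(path, "w") as handle:
        for identifier, fp in records:
            handle.write(f"{identifier}\t{fp.to_hex()}\n")
    sidecar = {"length": D, "config": config or {}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_secfp_file(path: str | Path) -> tuple[list[tuple[str, BinaryFingerprint]], dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    D = int(sidecar["length"])
    records = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            identifier, hexs = line.split("\t")
            records.append((identifier, BinaryFingerprint.from_hex(hexs, D)))
    return records, sidecar.get("config", {})
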