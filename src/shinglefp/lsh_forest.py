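"""LSH Forest index for MinHash signatures in Jaccard space.

The k components of every signature are split into l contiguous blocks of
``depth = k // l`` components; block t, byte-serialized, is the key of the
record in prefix tree t.  A query walks all l trees from the deepest prefix
of its own key, relaxing the prefix length one component at a time until
enough distinct candidates have been gathered (or the root is reached, at
which point every record is a candidate).  Candidates are then re-ranked by
their MinHash-estimated Jaccard distance to the query and the top k
returned — the k_c-fold oversampling ("search kc * k internally, linear-scan
re-rank, return top k") that trades recall against query time.

Each "prefix tree" is realised as a sorted array of fixed-width byte keys:
the records matching a prefix form a contiguous slice found by binary
search, which is contract-equivalent to walking an explicit trie.
"""

from __future__ import annotations

import bisect
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ParameterMismatchError, ShingleFPError
from .fingerprints import jaccard_estimated
from .hashing import MinHashVector

__all__ = ["LSHForestIndex", "recovery_rate", "brute_force_knn"]

DEFAULT_TREES = 32
DEFAULT_KC = 10


def _block_key(components: np.ndarray) -> bytes:
    """Big-endian 4-byte serialization: lexicographic byte order equals
    lexicographic component order, so byte prefixes are component prefixes."""
    return components.astype(">u4").tobytes()


class LSHForestIndex:
    """Approximate k-NN index over MinHash signatures.

    Parameters
    ----------
    k:
        Signature length; must be divisible by ``n_trees``.
    n_trees:
        Number of prefix trees l; each tree indexes ``k // n_trees``
        consecutive signature components.

    Records are added with :meth:`add` and become queryable only after
    :meth:`freeze`, which sorts the per-tree key arrays.
    """

    def __init__(self, k: int, n_trees: int = DEFAULT_TREES):
        if k < 1 or n_trees < 1:
            raise ValueError("k and n_trees must be >= 1")
        if k % n_trees:
            raise ValueError(f"n_trees={n_trees} must divide k={k}")
        self.k = k
        self.n_trees = n_trees
        self.depth = k // n_trees
        self.frozen = False
        self._ids: list[str] = []
        self._id_to_pos: dict[str, int] = {}
        self._components: list[np.ndarray] = []
        self._params_fingerprint: str | None = None
        # built at freeze time: per tree, keys sorted lexicographically and
        # the insertion positions in the same order
        self._tree_keys: list[list[bytes]] = []
        self._tree_pos: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._ids)

    @property
    def identifiers(self) -> list[str]:
        return list(self._ids)

    def add(self, identifier: str, fp: MinHashVector) -> None:
        """Add a record; rejected after :meth:`freeze` or on duplicate id."""
        if self.frozen:
            raise ShingleFPError("cannot add to a frozen index")
        if fp.k != self.k:
            raise ParameterMismatchError(
                f"fingerprint has k={fp.k}, index expects k={self.k}"
            )
        if self._params_fingerprint is None:
            self._params_fingerprint = fp.params_fingerprint
        elif fp.params_fingerprint != self._params_fingerprint:
            raise ParameterMismatchError(
                "all fingerprints in one index must share the same hash family"
            )
        if identifier in self._id_to_pos:
            raise ShingleFPError(f"duplicate identifier {identifier!r}")
        self._id_to_pos[identifier] = len(self._ids)
        self._ids.append(identifier)
        self._components.append(np.asarray(fp.components, dtype=np.uint32))

    def freeze(self) -> None:
        """Finalize the index: build the sorted key array of every tree."""
        if self.frozen:
            return
        n = len(self._ids)
        matrix = (
            np.vstack(self._components)
            if n
            else np.empty((0, self.k), dtype=np.uint32)
        )
        self._matrix = matrix
        self._tree_keys = []
        self._tree_pos = []
        for t in range(self.n_trees):
            block = matrix[:, t * self.depth : (t + 1) * self.depth]
            keys = [_block_key(block[i]) for i in range(n)]
            order = sorted(range(n), key=lambda i: keys[i])
            self._tree_keys.append([keys[i] for i in order])
            self._tree_pos.append(np.asarray(order, dtype=np.int64))
        self.frozen = True

    # -- candidate gathering ------------------------------------------------

    def _prefix_range(self, tree: int, prefix: bytes) -> tuple[int, int]:
        """Contiguous slice of tree keys sharing ``prefix`` (binary search)."""
        keys = self._tree_keys[tree]
        lo = bisect.bisect_left(keys, prefix)
        # pad with 0xff to one full key width: no valid key exceeds this
        hi = bisect.bisect_right(keys, prefix + b"\xff" * (4 * self.depth - len(prefix)))
        return lo, hi

    def _gather_candidates(self, fp: MinHashVector, n_wanted: int) -> list[int]:
        """Distinct record positions, walking all trees from the deepest
        matching prefix and relaxing until ``n_wanted`` found or depth 0."""
        query_keys = [
            _block_key(
                np.asarray(fp.components[t * self.depth : (t + 1) * self.depth])
            )
            for t in range(self.n_trees)
        ]
        seen: set[int] = set()
        for d in range(self.depth, 0, -1):
            for t in range(self.n_trees):
                lo, hi = self._prefix_range(t, query_keys[t][: 4 * d])
                for i in range(lo, hi):
                    seen.add(int(self._tree_pos[t][i]))
            if len(seen) >= n_wanted:
                break
        else:
            # depth relaxed to 0: the empty prefix matches every record
            seen = set(range(len(self._ids)))
        return sorted(seen)  # insertion order, for deterministic tie-breaks

    # -- queries ------------------------------------------------------------

    def query(
        self,
        fp: MinHashVector,
        k_neighbors: int,
        kc: int = DEFAULT_KC,
    ) -> list[tuple[str, float]]:
        """Approximate k-nearest neighbors of a query signature.

        Gathers at least ``kc * k_neighbors`` distinct candidates from the
        prefix trees, re-ranks them by estimated Jaccard distance, and
        returns the top ``k_neighbors`` as (identifier, distance) in
        nondecreasing distance, ties broken by insertion order.
        """
        if not self.frozen:
            raise ShingleFPError("freeze() the index before querying")
        if k_neighbors < 1 or kc < 1:
            raise ValueError("k_neighbors and kc must be >= 1")
        if not self._ids:
            return []
        if fp.k != self.k:
            raise ParameterMismatchError(
                f"query has k={fp.k}, index expects k={self.k}"
            )
        if fp.params_fingerprint != self._params_fingerprint:
            raise ParameterMismatchError(
                "query fingerprint uses a different hash family than the index"
            )
        candidates = self._gather_candidates(fp, kc * k_neighbors)
        q = np.asarray(fp.components, dtype=np.uint32)
        sub = self._matrix[candidates]
        dist = 1.0 - np.count_nonzero(sub == q[None, :], axis=1) / self.k
        order = np.argsort(dist, kind="stable")[:k_neighbors]
        return [(self._ids[candidates[i]], float(dist[i])) for i in order]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save the frozen index to a single ``.npz`` archive with a JSON
        header (l, depth, k, hash-family digest, n)."""
        if not self.frozen:
            raise ShingleFPError("freeze() the index before saving")
        header = json.dumps(
            {
                "k": self.k,
                "n_trees": self.n_trees,
                "depth": self.depth,
                "params_fingerprint": self._params_fingerprint,
                "n": len(self._ids),
            }
        )
        np.savez_compressed(
            path,
            header=np.frombuffer(header.encode(), dtype=np.uint8),
            identifiers=np.asarray(self._ids, dtype=object),
            components=self._matrix,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSHForestIndex":
        with np.load(path, allow_pickle=True) as archive:
            header = json.loads(archive["header"].tobytes().decode())
            ids = [str(x) for x in archive["identifiers"]]
            matrix = archive["components"]
        index = cls(k=int(header["k"]), n_trees=int(header["n_trees"]))
        index._params_fingerprint = header["params_fingerprint"]
        for identifier, row in zip(ids, matrix):
            index._id_to_pos[identifier] = len(index._ids)
            index._ids.append(identifier)
            index._components.append(np.asarray(row, dtype=np.uint32))
        index.freeze()
        return index


def brute_force_knn(
    database: Sequence[tuple[str, MinHashVector]],
    fp: MinHashVector,
    k_neighbors: int,
) -> list[tuple[str, float]]:
    """Exact k-NN by linear scan over estimated Jaccard distance.

    The ground truth the approximate index is judged against: same distance,
    same tie-break (insertion order), no pruning.
    """
    dists = [(1.0 - jaccard_estimated(fp, v), i) for i, (_, v) in enumerate(database)]
    dists.sort(key=lambda t: t)  # (distance, insertion order)
    return [(database[i][0], d) for d, i in dists[:k_neighbors]]


def recovery_rate(
    ann_result: Sequence[str], exact_result: Sequence[str], k_neighbors: int
) -> float:
    """Fraction of the true k nearest neighbors found by the approximate
    search: |top-k(ann) n top-k(exact)| / k."""
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    return len(set(ann_result[:k_neighbors]) & set(exact_result[:k_neighbors])) / k_neighbors
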