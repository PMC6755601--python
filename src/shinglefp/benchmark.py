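"""Synthetic fixtures and the scaled-down k-NN recovery benchmark.

The recovery benchmark mirrors the approximate-search evaluation protocol:
hold out a handful of query fingerprints, index the rest, and for every
(k, kc, l) cell compare the LSH Forest result against a brute-force linear
scan, averaging the recovery rate over the queries.  It is pure
vector-space evaluation — no chemistry is involved — so it runs on
synthetic integer sets standing in for hashed molecular shinglings.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hashing import MinHashVector, PermutationParams, minhash
from .lsh_forest import LSHForestIndex, brute_force_knn, recovery_rate

__all__ = [
    "BenchmarkConfig",
    "generate_fixture_sets",
    "generate_clustered_sets",
    "generate_planted_pair",
    "run_recovery_benchmark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid and sizes for the recovery benchmark.

    ``n_database`` vectors are indexed, ``n_queries`` held out as queries;
    every combination of neighbors ``k``, oversampling factor ``kc`` and
    tree count ``l`` becomes one row of the result table.
    """

    n_database: int = 10_000
    n_queries: int = 20
    k_list: tuple[int, ...] = (5, 10)
    kc_list: tuple[int, ...] = (1, 10, 20)
    l_list: tuple[int, ...] = (8, 32)
    seed: int = 42

    def __post_init__(self):
        if self.n_database < 1 or self.n_queries < 1:
            raise ValueError("n_database and n_queries must be >= 1")
        if any(k < 1 for k in self.k_list + self.kc_list + self.l_list):
            raise ValueError("k, kc and l values must all be >= 1")
        if max(self.k_list) > self.n_database:
            raise ValueError("cannot ask for more neighbors than database records")


def generate_fixture_sets(
    n: int,
    universe: int = 1000,
    size_range: tuple[int, int] = (30, 60),
    seed: int = 42,
) -> list[np.ndarray]:
    """Reproducible random integer sets standing in for hashed shinglings.

    Each set holds between ``size_range[0]`` and ``size_range[1]`` distinct
    values drawn uniformly from [0, universe).  A modest universe relative
    to the set sizes gives the sets non-trivial pairwise Jaccard overlap,
    which is what makes nearest-neighbor structure worth recovering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi <= universe:
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= universe")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n):
        size = int(rng.integers(lo, hi + 1))
        sets.append(np.sort(rng.choice(universe, size=size, replace=False)).astype(np.uint64))
    return sets


def generate_clustered_sets(
    n: int,
    universe: int = 4096,
    size_range: tuple[int, int] = (40, 80),
    swap_range: tuple[float, float] = (0.05, 0.35),
    cluster_size: int = 10,
    seed: int = 42,
) -> list[np.ndarray]:
    """Synthetic sets with compound-database-like neighbor structure.

    Real compound collections contain analogue series: groups of molecules
    sharing most of their substructure shingles.  Uniform random sets lack
    that structure — every record is almost equally far from every other,
    so there is nothing for a nearest-neighbor index to recover.  Here sets
    are generated in clusters: each cluster has a random "parent" set, and
    every member swaps a random fraction (``swap_range``) of the parent's
    elements for fresh ones.  Members of one cluster then have Jaccard
    similarity roughly ``(1 - f) / (1 + f)`` to the parent (about 0.5-0.9
    for the default swap fractions), mimicking the similarity of an
    analogue series, while members of different clusters are near-disjoint.
    The output order is shuffled so that any prefix of the list (e.g. the
    held-out queries of the recovery benchmark) spans many clusters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi <= universe:
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= universe")
    rng = np.random.default_rng(seed)
    sets: list[np.ndarray] = []
    while len(sets) < n:
        size = int(rng.integers(lo, hi + 1))
        parent = rng.choice(universe, size=size, replace=False)
        for _ in range(min(cluster_size, n - len(sets))):
            frac = rng.uniform(*swap_range)
            n_keep = size - int(round(frac * size))
            keep = rng.choice(size, size=n_keep, replace=False)
            member = set(parent[keep].tolist())
            while len(member) < size:
                member.add(int(rng.integers(0, universe)))
            sets.append(np.fromiter(sorted(member), dtype=np.uint64))
    order = rng.permutation(n)
    return [sets[i] for i in order]


def generate_planted_pair(
    n_shared: int,
    n_only_a: int,
    n_only_b: int,
    universe: int = 1 << 32,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two sets with exactly known Jaccard similarity.

    A and B share ``n_shared`` elements; A holds ``n_only_a`` and B
    ``n_only_b`` private elements, so by construction
    ``J = n_shared / (n_shared + n_only_a + n_only_b)`` — the swapped
    private elements are the knob that plants the similarity.  Returns
    (A, B, J).
    """
    total = n_shared + n_only_a + n_only_b
    if n_shared < 1 or total > universe:
        raise ValueError("need 1 <= n_shared and union size <= universe")
    rng = np.random.default_rng(seed)
    pool = rng.choice(universe, size=total, replace=False).astype(np.uint64)
    shared = pool[:n_shared]
    only_a = pool[n_shared : n_shared + n_only_a]
    only_b = pool[n_shared + n_only_a :]
    A = np.sort(np.concatenate([shared, only_a]))
    B = np.sort(np.concatenate([shared, only_b]))
    return A, B, n_shared / total


def minhash_all(
    sets: list[np.ndarray], params: PermutationParams
) -> list[MinHashVector]:
    """MinHash a list of integer sets under one hash family."""
    return [minhash(s, params) for s in sets]


def run_recovery_benchmark(
    config: BenchmarkConfig, fingerprints: list[MinHashVector]
) -> pd.DataFrame:
    """Run the recovery-rate grid and return a tidy table.

    ``fingerprints`` must hold at least ``n_database + n_queries`` vectors
    sharing one hash family; the first ``n_queries`` are held out as
    queries, the next ``n_database`` indexed.  For every (k, kc, l) cell an
    LSH Forest is queried and compared to the brute-force ranking; the
    output has columns ``k, kc, l, mean_recovery``.
    """
    needed = config.n_database + config.n_queries
    if len(fingerprints) < needed:
        raise ValueError(
            f"need {needed} fingerprints ({config.n_queries} queries + "
            f"{config.n_database} database), got {len(fingerprints)}"
        )
    digests = {fp.params_fingerprint for fp in fingerprints[:needed]}
    if len(digests) > 1:
        raise ValueError("all fingerprints must share one hash family")
    queries = fingerprints[: config.n_queries]
    database = [
        (str(i), fp)
        for i, fp in enumerate(fingerprints[config.n_queries : needed])
    ]
    k_sig = database[0][1].k

    # brute-force ground truth once per (query, k): compute to max k and slice
    k_max = max(config.k_list)
    t0 = time.perf_counter()
    exact = [brute_force_knn(database, q, k_max) for q in queries]
    logger.debug(
        "brute-force ground truth for %d queries over %d records: %.2fs",
        len(queries), len(database), time.perf_counter() - t0,
    )

    rows = []
    for l in config.l_list:
        index = LSHForestIndex(k=k_sig, n_trees=l)
        for identifier, fp in database:
            index.add(identifier, fp)
        index.freeze()
        for kc in config.kc_list:
            for k in config.k_list:
                recs = []
                for q, truth in zip(queries, exact):
                    ann = index.query(q, k_neighbors=k, kc=kc)
                    recs.append(
                        recovery_rate(
                            [i for i, _ in ann], [i for i, _ in truth], k
                        )
                    )
                rows.append(
                    {"k": k, "kc": kc, "l": l, "mean_recovery": float(np.mean(recs))}
                )
                logger.debug(
                    "cell k=%d kc=%d l=%d: mean recovery %.3f",
                    k, kc, l, rows[-1]["mean_recovery"],
                )
    return pd.DataFrame(rows, columns=["k", "kc", "l", "mean_recovery"])
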