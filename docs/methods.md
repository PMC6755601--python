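# Methods

## Molecular shingling

A molecule parsed from SMILES is stripped of stereochemistry, respelled
canonically, re-parsed and kekulized. The canonical respelling step is
load-bearing: kekulization assigns alternating single/double bonds
depending on atom order (a substituted benzene admits two valid
assignments), so without fixing the atom order first, two spellings of one
molecule can yield different substructure SMILES. After respelling, the
shingling is a graph invariant, and the test suite asserts bit-identical
fingerprints across spellings for ~50 fixture molecules.

For every heavy atom and every radius `min_radius..radius` (default
`1..3`), the subgraph of all bonds within that many bonds of the atom is
written as a canonical SMILES rooted at the centre atom; atoms whose
environment contains no bonds (isolated atoms, radii beyond the fragment)
contribute nothing. Each SSSR ring contributes one unrooted canonical
SMILES (a ring has no distinguished centre). Duplicates are removed. The
radius enumeration starts at 1 by default — radius-0 single-atom shingles
add little discrimination and are excluded from the standard fingerprints
— but `min_radius=0` enables them. A molecule with no bonds and no rings
(e.g. methane) has an empty shingling; because a MinHash over the empty
set is undefined, this raises by default (`allow_empty=True` returns the
empty set instead).

Multi-fragment (dot-separated) SMILES are shingled as-is, each fragment
contributing its atoms. Explicit hydrogens are folded into heavy-atom
valences by the parser. The canonical SMILES dialect is RDKit's; hash
values are therefore comparable only between fingerprints produced with
the same toolkit generation.

## Hashing and MinHash

Shingles are hashed to `{0, …, 2^32 − 1}` by truncating the SHA-1 digest
of their UTF-8 bytes to the first four bytes, read big-endian — a fixed,
documented choice; any fixed 32-bit slice would do. A 32-bit universe
keeps all MinHash arithmetic inside 64-bit words; the cost is a small
collision rate, quantified by the birthday-problem estimate
`c(m, N) = m − N(1 − ((N−1)/N)^m)`. This is evaluated as
`m + N·expm1(m·log1p(−1/N))`: at `N = 2^32 − 1` the ratio `(N−1)/N` rounds
to 1.0 in double precision, so naive powering returns 0 collisions for any
m; the log-space form agrees with a 60-digit Decimal oracle to nine
significant figures. At realistic corpus sizes (about 2·10^5 to 2·10^6
distinct shingles) the expectation is 4.5–476 collisions — negligible
against set sizes, so the MinHash estimate of shingling Jaccard is
unbiased for practical purposes.

The hash family `h_i(v) = ((a_i·v + b_i) mod p) mod (2^32 − 1)` uses the
Mersenne prime `p = 2^61 − 1`. The `a_i` are pairwise distinct and drawn
from `[1, 2^32 − 1]` (zero would collapse `h_i` to a constant), the `b_i`
pairwise distinct in `[0, 2^32 − 1]`; both are reproducible from `(k,
seed)` (default seed 42) and serializable to JSON so indexes remain
portable. Since `a_i, v < 2^32`, the product plus offset stays below
`2^64` and plain unsigned 64-bit arithmetic is exact — no wide-integer or
modular-multiplication tricks are needed, and the tests verify
componentwise equality with Python big-integer arithmetic at the extreme
admissible inputs. Signatures carry a digest of their hash family and
refuse comparison across families.

`k` trades estimator error (`sqrt(J(1−J)/k)`) against space and time;
supported sizes of interest are 128–4096, default 2048.

## Fingerprint variants

* **MHFP** — MinHash of the hashed shingling; radius 3, k = 2048 by
  default (diameter-6 naming: MHFP6).
* **SECFP** — the shingle hashes folded by `h mod D` into a D-bit binary
  vector (default D = 2048), the folding classic circular fingerprints
  use; for workflows that require a binary fingerprint.
* **MHECFP** — MinHash over a caller-supplied set of unfolded circular
  fingerprint (ECFP) identifiers, the control that isolates the effect of
  minhashing from the effect of SMILES shingling. Generating ECFP
  identifiers is delegated to the chemistry toolkit; identifiers wider
  than 32 bits are reduced modulo `2^32` (`fold_to_32bit`) before
  minhashing. The reduction choice is this package's, recorded here.

All constructors are pure: identical input and configuration give
bit-identical output.

## LSH Forest

Signatures are split into `l` contiguous blocks of `depth = k / l`
components (`l` must divide `k`); block `t`, serialized as big-endian
4-byte words so byte order equals component order, is the record's key in
tree `t`. Each "prefix tree" is a sorted array of keys: the records
matching a prefix form a contiguous slice located by binary search,
contract-equivalent to an explicit trie and cheaper to build. Queries
walk all trees from the full depth downward, accumulating distinct record
ids, and stop at the first depth where at least `kc·k_neighbors`
candidates have been gathered (at depth 0 every record matches).
Candidates are re-ranked by the MinHash-estimated Jaccard distance to the
query — the stored signatures are the ground truth the index serves, so
re-ranking does not return to the shinglings — and ties are broken by
insertion order, making result lists and recovery rates reproducible.
`kc` (default 10) is the recall/latency dial: `kc·k_neighbors ≥ n` makes
the query an exact linear scan.

The index is in-memory; persistence is a single `.npz` archive with a
JSON header. No multi-probe LSH, no cosine/Annoy-style indexing.

## Synthetic benchmark data

The recovery benchmark is pure vector-space evaluation and uses no
chemistry. Two generators supply its inputs:

* `generate_fixture_sets` — uniform random integer sets, for property
  tests (estimator unbiasedness, union-min identity, oracle equivalence).
* `generate_clustered_sets` — the database emulation: parent sets with
  members derived by swapping a random 5–35% of elements for fresh ones,
  giving within-cluster Jaccard of roughly 0.5–0.9 and near-disjoint
  cross-cluster pairs. This mimics the analogue series of real compound
  collections, where query molecules have genuinely close neighbors.
  Uniform random sets lack that structure — every record is nearly
  equidistant from every other — and in that regime deeper prefix matches
  carry no signal, so approximate-search recovery is flat or erratic in
  the index parameters. Defaults (universe 4096, set sizes 40–80,
  clusters of 10) were chosen once as a realistic shingling-sized regime.

Benchmark scale: the recovery-trend checks index 10,000 vectors and
average 20 held-out queries at `k = 10` over `kc ∈ {1, 10, 20}` and
`l ∈ {8, 32}` — sizes at which the monotone improvement of recovery with
oversampling and tree count is the package's own reproducible result.
What passing these tests does *not* show: recovery numbers on real
million-compound collections, where shingling statistics, set-size
distributions and cluster geometry differ.

## Numerical and degenerate-input choices

* Collision estimate in log space (see above); exact for `m = 0, 1`.
* MinHash of an empty set, Jaccard of two empty sets, and comparisons
  across hash families raise typed exceptions rather than returning
  sentinel values.
* Components are stored as uint32 (max value `2^32 − 2`).
* Tie-breaking everywhere is stable by insertion order.
* Hash-family generation uses rejection resampling for distinctness;
  a value may legitimately appear in both `a` and `b`.

## Known limitations

* In-memory index only; no incremental deletion, no index merging.
* Fingerprints are toolkit-dialect-bound: signatures computed with a
  different canonical SMILES writer will not match.
* SECFP similarity upper-bounds structural identity only in one
  direction: identical molecules give identical fingerprints, but
  identical fingerprints do not prove identical molecules.
* The estimator-error analysis assumes negligible string-hash collisions;
  at corpus sizes far beyond ~10^7 distinct shingles the 32-bit universe
  begins to saturate.
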