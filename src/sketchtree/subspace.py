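"""Deterministic k-mer substring subspace.

A sketch is built by keeping only the k-mers whose central length-``l``
substring falls in a pre-chosen *retained* subset of all ``4**l`` possible
substrings. Because the decision depends on the k-mer itself (not on a hash
of it), two genomes sketched with the same subspace sample exactly the same
region of k-mer space, so sketch intersections and unions are unbiased set
operations — the property minhash-style sketches lack due to hash collisions.

The retained set holds the first ``4**(l-r)`` entries of a seeded
permutation of ``range(4**l)``, i.e. a fraction ``4**-r`` of the substring
space. A subspace is fully determined by ``(k, l, r, seed)`` and is
serialized to a small versioned ``.shuf`` JSON container so every genome in
a study is sketched with the identical sampling rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SHUF_MAGIC = "SKETCHTREE_SHUF"
SHUF_VERSION = 1

#: PRNG behind the subspace permutation. numpy's PCG64 Generator performs a
#: Fisher-Yates shuffle with platform-independent 64-bit streams, so a
#: (k, l, r, seed) tuple denotes the same retained set on every machine.
PERMUTATION_PRNG = "numpy-PCG64-permutation-v1"

MAX_K = 31  # k-mer must fit 2 bits/base in a 64-bit word
MAX_L = 12  # 4**l substrings are materialized; 4**12 = 16.7M is the ceiling


@dataclass(frozen=True)
class KmerSubspace:
    """Retained-substring set deciding which canonical k-mers are sampled.

    Parameters
    ----------
    k : int
        k-mer length in bases, ``1 <= l <= k <= 31``.
    l : int
        Length of the decision substring.
    r : int
        Reduction exponent; a fraction ``4**-r`` of substrings is retained.
    seed : int
        Seed of the permutation PRNG.
    retained : numpy.ndarray
        Sorted unique substring codes in ``[0, 4**l)``, dtype uint64.
    """

    k: int
    l: int
    r: int
    seed: int
    retained: np.ndarray = field(repr=False)

    @property
    def offset(self) -> int:
        """Start of the decision substring within the k-mer: centered."""
        return (self.k - self.l) // 2

    @property
    def fraction(self) -> float:
        """Exact sampling fraction ``|retained| / 4**l``."""
        return self.retained.size / 4**self.l

    @property
    def params(self) -> tuple[int, int, int, int]:
        return (self.k, self.l, self.r, self.seed)

    @property
    def is_full(self) -> bool:
        return self.retained.size == 4**self.l

    def substring_codes(self, kmer_codes: np.ndarray) -> np.ndarray:
        """Extract the decision-substring code from each k-mer code."""
        shift = np.uint64(2 * (self.k - self.offset - self.l))
        mask = np.uint64(4**self.l - 1)
        return (np.asarray(kmer_codes, dtype=np.uint64) >> shift) & mask

    def contains_codes(self, kmer_codes: np.ndarray) -> np.ndarray:
        """Vectorized membership test for canonical k-mer codes."""
        codes = np.asarray(kmer_codes, dtype=np.uint64)
        if self.is_full:
            return np.ones(codes.shape, dtype=bool)
        if self.retained.size == 0:
            return np.zeros(codes.shape, dtype=bool)
        sub = self.substring_codes(codes)
        pos = np.searchsorted(self.retained, sub)
        pos[pos == self.retained.size] = 0
        return self.retained[pos] == sub

    def contains(self, kmer_code: int) -> bool:
        """Whether a single canonical k-mer code is sampled by this subspace."""
        return bool(self.contains_codes(np.asarray([kmer_code]))[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, KmerSubspace):
            return NotImplemented
        return self.params == other.params and np.array_equal(
            self.retained, other.retained
        )

    def __hash__(self):
        return hash(self.params)


def generate_subspace(k: int = 21, l: int = 11, r: int = 2, seed: int = 42) -> KmerSubspace:
    """Build the retained-substring set for ``(k, l, r, seed)``.

    The retained set is the first ``4**(l-r)`` elements of a seeded
    Fisher-Yates permutation of ``range(4**l)`` (PRNG: numpy PCG64), stored
    sorted. Regeneration with identical arguments is bit-for-bit identical.
    """
    if not 1 <= l <= k:
        raise ValueError(f"require 1 <= l <= k, got l={l}, k={k}")
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds maximum k={MAX_K} (64-bit 2-bit code)")
    if l > MAX_L:
        raise ValueError(f"l={l} exceeds maximum l={MAX_L} (4**l must be enumerable)")
    if not 0 <= r < l:
        raise ValueError(f"require 0 <= r < l, got r={r}, l={l}")
    space = 4**l
    count = 4 ** (l - r)
    if r == 0:
        retained = np.arange(space, dtype=np.uint64)
    else:
        rng = np.random.Generator(np.random.PCG64(seed))
        perm = rng.permutation(space)
        retained = np.sort(perm[:count]).astype(np.uint64)
    return KmerSubspace(k=k, l=l, r=r, seed=seed, retained=retained)


def write_subspace(subspace: KmerSubspace, path) -> None:
    """Serialize to the versioned ``.shuf`` JSON container."""
    doc = {
        "magic": SHUF_MAGIC,
        "version": SHUF_VERSION,
        "prng": PERMUTATION_PRNG,
        "k": subspace.k,
        "l": subspace.l,
        "r": subspace.r,
        "seed": subspace.seed,
        "count": int(subspace.retained.size),
    }
    # the full (r=0) set is implicit; everything else is stored explicitly
    if not subspace.is_full:
        doc["retained"] = [int(c) for c in subspace.retained]
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def read_subspace(path) -> KmerSubspace:
    """Read a ``.shuf`` container; rejects bad magic, version or payload."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"truncated or malformed .shuf file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("magic") != SHUF_MAGIC:
        raise ValueError(f"bad magic in {path}: expected {SHUF_MAGIC!r}")
    if doc.get("version") != SHUF_VERSION:
        raise ValueError(f"unsupported .shuf version {doc.get('version')!r} in {path}")
    try:
        k, l, r, seed = doc["k"], doc["l"], doc["r"], doc["seed"]
        count = doc["count"]
    except KeyError as exc:
        raise ValueError(f"missing field {exc} in .shuf file {path}") from exc
    if "retained" in doc:
        retained = np.asarray(doc["retained"], dtype=np.uint64)
    else:
        retained = np.arange(4**l, dtype=np.uint64)
    if retained.size != count:
        raise ValueError(
            f"payload mismatch in {path}: header count {count}, got {retained.size} codes"
        )
    if retained.size and (retained[-1] >= 4**l or np.any(np.diff(retained.view(np.int64)) <= 0)):
        raise ValueError(f"retained codes in {path} not sorted/unique/in-range for l={l}")
    return KmerSubspace(k=k, l=l, r=r, seed=seed, retained=retained)
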