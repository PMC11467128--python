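"""Genome sketching: canonical k-mer encoding, FASTA/FASTQ streaming, set algebra.

A sketch is the sorted set of canonical k-mer codes from one genome (assembly
or pooled reads) that pass the subspace filter and a minimum-multiplicity
threshold. Encoding is 2 bits per base (A=0, C=1, G=2, T=3, big-endian over
positions); a k-mer and its reverse complement collapse to the numerically
smaller code, so sketches are strand-invariant. Windows containing any
non-ACGT character are skipped.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .subspace import KmerSubspace

SKETCH_MAGIC = "SKETCHTREE_SKETCH"
SKETCH_VERSION = 1

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class Sketch:
    """Sorted unique canonical k-mer codes plus sketching provenance.

    ``params`` is the ``(k, l, r, seed)`` tuple of the subspace that produced
    the sketch; set operations are only defined between sketches sharing it.
    """

    name: str
    kmers: np.ndarray = field(repr=False)  # sorted unique uint64
    params: tuple[int, int, int, int]
    source_kind: str = "assembly"  # "assembly" | "reads"

    @property
    def k(self) -> int:
        return self.params[0]

    def __len__(self) -> int:
        return int(self.kmers.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.name == other.name
            and self.params == other.params
            and self.source_kind == other.source_kind
            and np.array_equal(self.kmers, other.kmers)
        )

    def __hash__(self):
        return hash((self.name, self.params))


# ---------------------------------------------------------------------------
# k-mer encoding


def encode_kmer(kmer: str, k: int | None = None) -> int | None:
    """2-bit code of a k-length DNA string, or None if any base is not ACGT."""
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(kmer)}")
    codes = _BASE_CODE[np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)]
    if codes.size == 0:
        raise ValueError("empty k-mer")
    if np.any(codes > 3):
        return None
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a valid code."""
    return "".join(_CODE_BASE[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement under the same encoding."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical(code: int, k: int) -> int:
    """min(code, revcomp code): strand-invariant representative."""
    return min(code, revcomp_code(code, k))


def canonical_kmer_codes(sequence: str | bytes, k: int) -> np.ndarray:
    """All canonical k-mer codes of a sequence, in window order.

    Windows containing non-ACGT characters are dropped. Not deduplicated —
    multiplicity is counted by the caller.
    """
    if isinstance(sequence, str):
        sequence = sequence.encode("ascii")
    b = _BASE_CODE[np.frombuffer(sequence, dtype=np.uint8)]
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    b64 = b.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        col = b64[j : j + n]
        fwd += (col & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        rev += ((np.uint64(3) - (col & np.uint64(3))) & np.uint64(3)) << np.uint64(2 * j)
    bad = (b > 3).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    return np.minimum(fwd[valid], rev[valid])


# ---------------------------------------------------------------------------
# sketch construction


def sketch_sequences(
    sequences,
    subspace: KmerSubspace,
    min_multiplicity: int = 1,
    name: str = "sketch",
    source_kind: str = "assembly",
) -> Sketch:
    """Sketch an iterable of sequences pooled as one genome.

    Canonical k-mers are counted across all sequences; those with multiplicity
    >= ``min_multiplicity`` that pass the subspace filter form the sketch.
    """
    if min_multiplicity < 1:
        raise ValueError(f"min_multiplicity must be >= 1, got {min_multiplicity}")
    chunks = [canonical_kmer_codes(s, subspace.k) for s in sequences]
    if chunks:
        codes = np.concatenate(chunks)
    else:
        codes = np.empty(0, dtype=np.uint64)
    if codes.size:
        uniq, counts = np.unique(codes, return_counts=True)
        uniq = uniq[counts >= min_multiplicity]
        uniq = uniq[subspace.contains_codes(uniq)]
    else:
        uniq = codes
    return Sketch(name=name, kmers=uniq, params=subspace.params, source_kind=source_kind)


def _open_maybe_gzip(path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(fh))
    return io.TextIOWrapper(fh)


def _sniff_format(text_handle) -> str:
    pos = text_handle.tell()
    offset = 0
    fmt = None
    while True:
        ch = text_handle.read(1)
        if ch == "":
            raise ValueError("empty sequence file")
        if not ch.isspace():
            if ch == ">":
                fmt = "fasta"
            elif ch == "@":
                fmt = "fastq"
            else:
                raise ValueError(
                    f"unknown sequence format: first non-whitespace byte {ch!r} "
                    f"at offset {offset} (expected '>' or '@')"
                )
            break
        offset += 1
    text_handle.seek(pos)
    return fmt


def sketch_sequence_file(
    path,
    subspace: KmerSubspace,
    min_multiplicity: int | None = None,
    name: str | None = None,
) -> Sketch:
    """Sketch a FASTA or FASTQ file (plain or gzip), all records pooled.

    Format is auto-detected from content and compression from magic bytes.
    ``min_multiplicity`` defaults to 1 for FASTA (assemblies) and 2 for FASTQ
    (suppresses k-mers created by sequencing error in raw reads).
    """
    path = str(path)
    with _open_maybe_gzip(path) as fh:
        fmt = _sniff_format(fh)
        seqs = (str(rec.seq) for rec in SeqIO.parse(fh, fmt))
        if min_multiplicity is None:
            min_multiplicity = 1 if fmt == "fasta" else 2
        if name is None:
            base = path.rsplit("/", 1)[-1]
            for suffix in (".gz", ".fasta", ".fa", ".fna", ".fastq", ".fq"):
                if base.endswith(suffix):
                    base = base[: -len(suffix)]
            name = base
        sketch = sketch_sequences(
            seqs,
            subspace,
            min_multiplicity=min_multiplicity,
            name=name,
            source_kind="assembly" if fmt == "fasta" else "reads",
        )
    return sketch


# ---------------------------------------------------------------------------
# set algebra


def _check_same_params(a: Sketch, b: Sketch) -> None:
    if a.params != b.params:
        raise ValueError(
            f"sketch parameter mismatch: {a.name} has (k,l,r,seed)={a.params}, "
            f"{b.name} has (k,l,r,seed)={b.params}"
        )


def union(a: Sketch, b: Sketch) -> Sketch:
    _check_same_params(a, b)
    return replace(a, kmers=np.union1d(a.kmers, b.kmers))


def intersection(a: Sketch, b: Sketch) -> Sketch:
    _check_same_params(a, b)
    return replace(a, kmers=np.intersect1d(a.kmers, b.kmers, assume_unique=True))


def subtract(a: Sketch, b: Sketch) -> Sketch:
    """k-mers of ``a`` absent from ``b`` (the reference-subtraction primitive)."""
    _check_same_params(a, b)
    return replace(a, kmers=np.setdiff1d(a.kmers, b.kmers, assume_unique=True))


# ---------------------------------------------------------------------------
# persistence


def write_sketch(sketch: Sketch, path) -> None:
    doc = {
        "magic": SKETCH_MAGIC,
        "version": SKETCH_VERSION,
        "name": sketch.name,
        "params": list(sketch.params),
        "source_kind": sketch.source_kind,
        "count": len(sketch),
        "kmers": [int(c) for c in sketch.kmers],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def read_sketch(path) -> Sketch:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt sketch file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("magic") != SKETCH_MAGIC:
        raise ValueError(f"bad magic in sketch file {path}")
    if doc.get("version") != SKETCH_VERSION:
        raise ValueError(f"unsupported sketch version {doc.get('version')!r} in {path}")
    kmers = np.asarray(doc["kmers"], dtype=np.uint64)
    if kmers.size != doc["count"]:
        raise ValueError(
            f"sketch payload mismatch in {path}: declared {doc['count']}, "
            f"found {kmers.size}"
        )
    if kmers.size > 1 and np.any(kmers[1:] <= kmers[:-1]):
        raise ValueError(f"sketch codes in {path} not sorted/unique")
    return Sketch(
        name=doc["name"],
        kmers=kmers,
        params=tuple(doc["params"]),
        source_kind=doc.get("source_kind", "assembly"),
    )
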