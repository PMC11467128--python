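"""Synthetic genomes, tree-structured evolution, and error-bearing reads.

Desk-scale fixture generator for the whole stack: i.i.d. random genomes,
substitution-only mutation at a per-site probability, independent evolution
of a root genome along the edges of a known tree (edge lengths read as
per-edge substitution probabilities), and uniformly placed single-end reads
with per-base errors. Substitutions are the only mutational process — they
are exactly what the Jaccard-to-distance conversion models, so recovering
the generating parameters from sketches is a meaningful end-to-end check.
Indels, rearrangements, GC bias and realistic quality strings are out of
scope and their absence means passing tests do not certify behavior on real
data with those features.

Every generator is deterministic given its seed; a JSON manifest recording
all parameters is written next to any file outputs.
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path

import numpy as np

from .treebuild import TreeNode

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def random_genome(length: int, seed: int) -> str:
    """i.i.d. uniform-ACGT sequence of the given length."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    codes = _rng(seed).integers(0, 4, size=length, dtype=np.uint8)
    return _BASES[codes].tobytes().decode("ascii")


def mutate(sequence: str, p: float, seed: int) -> str:
    """Substitute each site independently with probability ``p``.

    A substituted site receives one of the three other bases uniformly, so
    the expected observable mismatch fraction equals ``p`` exactly.
    """
    if not 0.0 <= p < 0.75:
        raise ValueError(f"substitution probability must be in [0, 0.75), got {p}")
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("sequence contains non-ACGT characters")
    rng = _rng(seed)
    hit = rng.random(codes.size) < p
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes = codes.copy()
    codes[hit] = (codes[hit] + shift) % 4
    return _BASES[codes].tobytes().decode("ascii")


def evolve_tree(
    root_length: int,
    tree: TreeNode,
    seed: int,
    outdir=None,
) -> dict[str, str]:
    """Evolve a random root genome along a tree; return leaf name -> sequence.

    Each edge applies an independent substitution process with probability
    equal to its branch length (lengths must lie in [0, 0.75)); lengths are
    *not* compounded into rates, a deliberate simplification. When
    ``outdir`` is given, one FASTA per leaf plus ``manifest.json`` are
    written there.
    """
    for node in tree.walk():
        if node.length is not None and not 0.0 <= node.length < 0.75:
            raise ValueError(
                f"branch length {node.length} outside [0, 0.75); cannot be read "
                "as a substitution probability"
            )
    seeds = np.random.SeedSequence(seed).generate_state(2 * sum(1 for _ in tree.walk()) + 1)
    seeds = [int(s) & 0x7FFFFFFF for s in seeds]
    root_seq = random_genome(root_length, seeds[0])
    out: dict[str, str] = {}
    counter = iter(range(1, len(seeds)))

    def descend(node: TreeNode, seq: str) -> None:
        for child in node.children:
            child_seq = mutate(seq, child.length or 0.0, seeds[next(counter)])
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                descend(child, child_seq)

    if tree.is_leaf:
        out[tree.name] = root_seq
    else:
        descend(tree, root_seq)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, seq in out.items():
            write_fasta(outdir / f"{name}.fasta", name, seq)
        manifest = {
            "generator": "evolve_tree",
            "root_length": root_length,
            "tree": tree.newick(),
            "seed": seed,
            "leaves": sorted(out),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def random_binary_tree(
    n_leaves: int,
    seed: int,
    min_edge: float = 0.1,
    max_edge: float = 1.0,
    names: list[str] | None = None,
) -> TreeNode:
    """Uniform random rooted binary topology with U(min_edge, max_edge) edges.

    Grown by attaching each new leaf to a uniformly chosen existing edge;
    useful both as a truth tree for simulation and as a source of additive
    distance matrices.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if names is None:
        names = [f"T{i + 1}" for i in range(n_leaves)]
    if len(names) != n_leaves:
        raise ValueError("names length must equal n_leaves")
    rng = _rng(seed)

    def edge_len() -> float:
        return float(rng.uniform(min_edge, max_edge))

    root = TreeNode(
        children=[
            TreeNode(name=names[0], length=edge_len()),
            TreeNode(name=names[1], length=edge_len()),
        ]
    )
    # parent pointers tracked locally while growing
    edges = [(root, root.children[0]), (root, root.children[1])]
    for leaf_idx in range(2, n_leaves):
        parent, child = edges[int(rng.integers(0, len(edges)))]
        half = (child.length or 0.0) / 2.0
        mid = TreeNode(length=half, children=[child])
        child.length = half
        new_leaf = TreeNode(name=names[leaf_idx], length=edge_len())
        mid.children.append(new_leaf)
        parent.children[parent.children.index(child)] = mid
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, new_leaf)])
    return root


def simulate_reads(
    sequence: str,
    read_length: int,
    coverage: float,
    error_rate: float,
    seed: int,
    path=None,
    name: str = "sim",
) -> list[str]:
    """Uniformly placed single-end reads from both strands.

    Emits enough reads for at least ``coverage`` x genome length bases; each
    base is substituted with probability ``error_rate``; quality is a fixed
    'I' (Q40) string. Returns the read sequences and optionally writes FASTQ
    (gzip if ``path`` ends in .gz) plus a manifest.
    """
    length = len(sequence)
    if read_length > length:
        raise ValueError(f"read_length {read_length} exceeds genome length {length}")
    if coverage <= 0:
        raise ValueError(f"coverage must be > 0, got {coverage}")
    if not 0.0 <= error_rate < 0.75:
        raise ValueError(f"error_rate must be in [0, 0.75), got {error_rate}")
    n_reads = math.ceil(coverage * length / read_length)
    rng = _rng(seed)
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    reads = []
    comp = np.uint8(3)
    for start, strand in zip(starts, strands):
        window = codes[start : start + read_length]
        if strand:
            window = (comp - window)[::-1]
        hit = rng.random(read_length) < error_rate
        if hit.any():
            window = window.copy()
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            window[hit] = (window[hit] + shift) % 4
        reads.append(_BASES[window].tobytes().decode("ascii"))
    if path is not None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        qual = "I" * read_length
        with opener(path, "wt") as fh:
            for i, read in enumerate(reads):
                fh.write(f"@{name}_{i}\n{read}\n+\n{qual}\n")
        manifest = {
            "generator": "simulate_reads",
            "genome_length": length,
            "read_length": read_length,
            "coverage": coverage,
            "error_rate": error_rate,
            "seed": seed,
            "n_reads": n_reads,
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
    return reads


def write_fasta(path, name: str, sequence: str, width: int = 80) -> None:
    """Write a single-record FASTA (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
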