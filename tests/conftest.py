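import numpy as np
import pytest

import sketchtree as st


@pytest.fixture(scope="session")
def full_subspace_k5():
    """k=5 subspace retaining everything (r=0): sketch == full canonical set."""
    return st.generate_subspace(k=5, l=3, r=0, seed=1)


@pytest.fixture(scope="session")
def default_subspace():
    """Package defaults: k=21, l=11, r=2 (1/16 of the substring space)."""
    return st.generate_subspace(21, 11, 2, 42)


@pytest.fixture(scope="session")
def r0_subspace_k21():
    return st.generate_subspace(21, 11, 0, 42)


def brute_force_canonical_set(sequence: str, k: int) -> set[int]:
    """String-level oracle: scan windows, skip non-ACGT, canonicalize by string."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k].upper()
        if any(c not in "ACGT" for c in window):
            continue
        rc = window.translate(comp)[::-1]
        out.add(min(st.encode_kmer(window), st.encode_kmer(rc)))
    return out


def make_sketch(codes, params, name="s"):
    return st.Sketch(
        name=name, kmers=np.asarray(sorted(codes), dtype=np.uint64), params=params
    )


def random_additive_case(n_leaves: int, seed: int):
    """A random binary tree and its exact patristic distance matrix."""
    tree = st.simdata.random_binary_tree(n_leaves, seed=seed, min_edge=0.1, max_edge=1.0)
    return tree, tree.leaf_distances()
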