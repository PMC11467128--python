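"""Jaccard estimation, Mash evolutionary distance, and PHYLIP matrix IO.

The Jaccard index between two sketches, J = |A ∩ B| / |A ∪ B|, estimates the
k-mer set similarity of the underlying genomes. Under a Poisson model of
independent per-site substitutions at rate D, a k-mer survives unmutated
with probability e^{-kD}, which leads to the Mash distance

    D = -(1/k) * ln( 2J / (1 + J) )

as an estimator of per-site divergence. J = 1 gives D = 0; as J -> 0 the
formula diverges, so D is capped at a configurable ``d_max`` (default 1.0),
keeping downstream neighbor-joining well-posed on disjoint sketches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sketcher import Sketch, _check_same_params

#: Sentinel distance for sketches sharing no k-mers (J = 0).
DEFAULT_D_MAX = 1.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise evolutionary distances with ordered taxon labels."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(labels)
        if len(set(labels)) != n:
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(values < 0):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(values, values.T, atol=1e-6, rtol=0):
            raise ValueError("distance matrix is not symmetric (tolerance 1e-6)")
        if np.any(np.abs(np.diag(values)) > 0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair):
        i, j = pair
        if isinstance(i, str):
            i = self.labels.index(i)
        if isinstance(j, str):
            j = self.labels.index(j)
        return float(self.values[i, j])


def jaccard(a: Sketch, b: Sketch) -> float:
    """Exact |A ∩ B| / |A ∪ B| over sketch k-mer codes."""
    _check_same_params(a, b)
    if len(a) == 0 and len(b) == 0:
        raise ValueError(
            f"Jaccard undefined: both sketches empty ({a.name!r}, {b.name!r})"
        )
    inter = np.intersect1d(a.kmers, b.kmers, assume_unique=True).size
    union = len(a) + len(b) - inter
    return inter / union


def mash_distance(j: float, k: int, d_max: float = DEFAULT_D_MAX) -> float:
    """Convert a Jaccard index to evolutionary distance.

    Returns min(-(1/k)·ln(2j/(1+j)), d_max); the cap makes the function total
    and monotone non-increasing on [0, 1] including j = 0.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must be in [0, 1], got {j}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if j == 0.0:
        return d_max
    if j == 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(d, d_max)


def pairwise_matrix(sketches, d_max: float = DEFAULT_D_MAX) -> DistanceMatrix:
    """All-pairs Mash distances for >= 2 sketches with shared parameters."""
    sketches = list(sketches)
    if len(sketches) < 2:
        raise ValueError(f"need at least 2 sketches, got {len(sketches)}")
    names = [s.name for s in sketches]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate sketch names: {dupes}")
    n = len(sketches)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sketches[i], sketches[j]
            if len(a) == 0 and len(b) == 0:
                raise ValueError(
                    f"cannot compute distance for pair ({a.name!r}, {b.name!r}): "
                    "both sketches empty"
                )
            d = mash_distance(jaccard(a, b), a.k, d_max=d_max)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(names), values=values)


# ---------------------------------------------------------------------------
# PHYLIP (square, relaxed names) serialization


def write_phylip(m: DistanceMatrix, path) -> None:
    """Write a square relaxed-PHYLIP distance matrix at 6 decimals.

    Relaxed: taxon names of any length, separated from the row by whitespace,
    hence names themselves must not contain whitespace.
    """
    for name in m.labels:
        if any(c.isspace() for c in name):
            raise ValueError(f"taxon name {name!r} contains whitespace; not "
                             "representable in PHYLIP rows")
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for i, name in enumerate(m.labels):
            row = " ".join(f"{v:.6f}" for v in m.values[i])
            fh.write(f"{name} {row}\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty PHYLIP file {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"bad PHYLIP header in {path}: {lines[0]!r}") from exc
    rows = lines[1:]
    if len(rows) != n:
        raise ValueError(f"{path} declares {n} taxa but contains {len(rows)} rows")
    labels, values = [], []
    for ln in rows:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"row for {parts[0] if parts else '?'!r} in {path} has "
                f"{len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        values.append([float(x) for x in parts[1:]])
    values = np.asarray(values)
    if not np.allclose(values, values.T, atol=1e-6, rtol=0):
        raise ValueError(f"matrix in {path} is not symmetric within 1e-6")
    # symmetrize away 6-decimal rounding; DistanceMatrix validates the rest
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=values)
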