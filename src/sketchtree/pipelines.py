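"""One-stop pipelines: routine, reference subtraction, and placement.

Each pipeline is an exact composition of the per-module operations — sketch,
pairwise distances, NJ/DNJ, Newick + text rendering — with all intermediate
artifacts written under one output directory and a run log recording input
counts, sketch sizes and elapsed time. Given fixed inputs the artifacts are
byte-identical across runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import distances, sketcher, treebuild
from .sketcher import Sketch
from .subspace import KmerSubspace

_METHODS = {"nj": treebuild.nj, "dnj": treebuild.dnj}

DEFAULT_NEIGHBORS = 10

logger = logging.getLogger("sketchtree")


@dataclass(frozen=True)
class RetrievalResult:
    """Ranked nearest neighbors of one query against a sketch database."""

    query: str
    neighbors: tuple[tuple[str, float], ...]  # (database name, distance), ascending


class SketchDatabase:
    """Directory of sketch files sharing one parameter tuple.

    The index maps each member name to its file path and sketch size;
    sketches are loaded lazily on retrieval.
    """

    def __init__(self, directory):
        self.directory = Path(directory)
        paths = sorted(self.directory.glob("*.sketch"))
        if not paths:
            raise ValueError(f"no .sketch files in database directory {directory}")
        self.index: dict[str, dict] = {}
        self.params = None
        for path in paths:
            sk = sketcher.read_sketch(path)
            if self.params is None:
                self.params = sk.params
            elif sk.params != self.params:
                raise ValueError(
                    f"database parameter mismatch: {path.name} has {sk.params}, "
                    f"expected {self.params}"
                )
            if sk.name in self.index:
                raise ValueError(f"duplicate sketch name {sk.name!r} in database")
            self.index[sk.name] = {"path": path, "size": len(sk)}

    def __len__(self) -> int:
        return len(self.index)

    @property
    def names(self) -> list[str]:
        return sorted(self.index)

    def load(self, name: str) -> Sketch:
        return sketcher.read_sketch(self.index[name]["path"])


def build_database(inputs, subspace: KmerSubspace, directory) -> SketchDatabase:
    """Sketch a collection of genome files into a database directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for path in inputs:
        sk = sketcher.sketch_sequence_file(path, subspace)
        sketcher.write_sketch(sk, directory / f"{sk.name}.sketch")
    return SketchDatabase(directory)


def _setup_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _tree_stage(sketches, method: str, outdir: Path) -> treebuild.TreeNode:
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    t0 = time.perf_counter()
    matrix = distances.pairwise_matrix(sketches)
    distances.write_phylip(matrix, outdir / "matrix.phy")
    logger.info("distance stage: %d taxa, %.2fs", matrix.n, time.perf_counter() - t0)
    t0 = time.perf_counter()
    tree = _METHODS[method](matrix)
    treebuild.write_newick(tree, outdir / "tree.nwk")
    (outdir / "tree.txt").write_text(treebuild.render_text(tree))
    logger.info("tree stage (%s): %.2fs", method, time.perf_counter() - t0)
    return tree


def _sketch_stage(inputs, subspace, outdir: Path, min_multiplicity=None) -> list[Sketch]:
    sketch_dir = outdir / "sketches"
    sketch_dir.mkdir(parents=True, exist_ok=True)
    sketches = []
    for path in inputs:
        try:
            sk = sketcher.sketch_sequence_file(path, subspace, min_multiplicity)
        except Exception as exc:
            raise RuntimeError(f"sketch stage failed on {path}: {exc}") from exc
        sketcher.write_sketch(sk, sketch_dir / f"{sk.name}.sketch")
        logger.info("sketched %s: %d k-mers", sk.name, len(sk))
        sketches.append(sk)
    return sketches


def routine(
    inputs,
    subspace: KmerSubspace,
    method: str = "nj",
    outdir="sketchtree_out",
    min_multiplicity: int | None = None,
) -> treebuild.TreeNode:
    """General-purpose pipeline: sketch -> distances -> tree -> artifacts.

    Writes per-genome sketches, a PHYLIP matrix, a Newick tree and a text
    rendering under ``outdir``; returns the tree.
    """
    inputs = [Path(p) for p in inputs]
    if len(inputs) < 3:
        raise ValueError(f"routine pipeline needs >= 3 inputs, got {len(inputs)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        logger.info("routine pipeline: %d inputs, method=%s", len(inputs), method)
        sketches = _sketch_stage(inputs, subspace, outdir, min_multiplicity)
        return _tree_stage(sketches, method, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def subtract_pipeline(
    reference,
    inputs,
    subspace: KmerSubspace,
    method: str = "nj",
    outdir="sketchtree_out",
    min_multiplicity: int | None = None,
) -> treebuild.TreeNode:
    """Intra-species pipeline: distances on reference-subtracted sketches.

    The reference sketch (e.g. a species-representative assembly) is removed
    from every individual's sketch, so the remaining differential k-mers —
    the phylogenetically informative minority within a species — dominate
    the distances instead of being swamped by the shared backbone.
    """
    inputs = [Path(p) for p in inputs]
    if len(inputs) < 3:
        raise ValueError(f"subtraction pipeline needs >= 3 inputs, got {len(inputs)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        ref_sketch = sketcher.sketch_sequence_file(reference, subspace)
        if len(ref_sketch) == 0:
            raise ValueError(f"reference sketch from {reference} is empty")
        logger.info("reference %s: %d k-mers", ref_sketch.name, len(ref_sketch))
        sketches = _sketch_stage(inputs, subspace, outdir, min_multiplicity)
        remainders = []
        for sk in sketches:
            rem = sketcher.subtract(sk, ref_sketch)
            if len(rem) == 0:
                raise ValueError(
                    f"no informative k-mers: sketch of {sk.name!r} is empty after "
                    "reference subtraction"
                )
            remainders.append(rem)
        rem_dir = outdir / "remainders"
        rem_dir.mkdir(exist_ok=True)
        for rem in remainders:
            sketcher.write_sketch(rem, rem_dir / f"{rem.name}.sketch")
        return _tree_stage(remainders, method, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def retrieve(query: Sketch, db: SketchDatabase, n: int = DEFAULT_NEIGHBORS) -> RetrievalResult:
    """Rank database members by distance to the query; keep the closest n."""
    if len(db) == 0:
        raise ValueError("sketch database is empty")
    if query.params != db.params:
        raise ValueError(
            f"query parameters {query.params} do not match database {db.params}"
        )
    scored = []
    for name in db.names:
        member = db.load(name)
        d = distances.mash_distance(distances.jaccard(query, member), query.k)
        scored.append((name, d))
    scored.sort(key=lambda item: (item[1], item[0]))
    return RetrievalResult(query=query.name, neighbors=tuple(scored[: min(n, len(scored))]))


def placement(
    queries,
    db: SketchDatabase,
    n: int = DEFAULT_NEIGHBORS,
    subspace: KmerSubspace | None = None,
    method: str = "nj",
    outdir="sketchtree_out",
    min_multiplicity: int | None = None,
) -> treebuild.TreeNode:
    """Place query genomes among their nearest database neighbors.

    Queries are sketched, each query's n nearest database sketches are
    retrieved (deduplicated by name across queries), and a tree over
    queries plus neighbors is built by the routine stages. A retrieval
    table (query, rank, neighbor, distance) is written as TSV.
    """
    queries = [Path(p) for p in queries]
    if not queries:
        raise ValueError("placement needs at least one query")
    if subspace is None:
        raise ValueError("placement requires the subspace used to build the database")
    if subspace.params != db.params:
        raise ValueError(
            f"subspace parameters {subspace.params} do not match database {db.params}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        query_sketches = _sketch_stage(queries, subspace, outdir, min_multiplicity)
        neighbor_names: list[str] = []
        with open(outdir / "retrieval.tsv", "w") as fh:
            fh.write("query\trank\tneighbor\tdistance\n")
            for qs in query_sketches:
                result = retrieve(qs, db, n)
                for rank, (name, d) in enumerate(result.neighbors, start=1):
                    fh.write(f"{qs.name}\t{rank}\t{name}\t{d:.6f}\n")
                    if name not in neighbor_names:
                        neighbor_names.append(name)
        query_names = {qs.name for qs in query_sketches}
        members = list(query_sketches) + [
            db.load(name) for name in neighbor_names if name not in query_names
        ]
        if len(members) < 3:
            raise ValueError(
                f"placement tree needs >= 3 distinct taxa, got {len(members)}"
            )
        logger.info(
            "placement: %d queries + %d neighbors", len(query_sketches),
            len(members) - len(query_sketches),
        )
        return _tree_stage(members, method, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


_QUICK_REQUIRED = {
    "routine": ("inputs", "subspace", "outdir"),
    "subtract": ("inputs", "subspace", "outdir", "reference"),
    "placement": ("inputs", "subspace", "outdir", "db"),
}


def quick(mode: str, config: dict):
    """Dispatch to one pipeline from a single validated config mapping.

    Keys: ``inputs`` (list of sequence files), ``subspace`` (KmerSubspace),
    ``outdir``; plus ``reference`` for subtract mode, ``db`` (SketchDatabase
    or directory) and optional ``n`` for placement; optional ``method``
    (nj|dnj) and ``min_multiplicity`` everywhere. Re-running with the same
    config deterministically overwrites the same artifacts.
    """
    if mode not in _QUICK_REQUIRED:
        raise ValueError(
            f"invalid mode {mode!r}; expected one of {sorted(_QUICK_REQUIRED)}"
        )
    missing = [key for key in _QUICK_REQUIRED[mode] if config.get(key) is None]
    if missing:
        raise ValueError(f"missing config field(s) for mode {mode!r}: {missing}")
    common = {
        "method": config.get("method", "nj"),
        "outdir": config["outdir"],
        "min_multiplicity": config.get("min_multiplicity"),
    }
    if mode == "routine":
        return routine(config["inputs"], config["subspace"], **common)
    if mode == "subtract":
        return subtract_pipeline(
            config["reference"], config["inputs"], config["subspace"], **common
        )
    db = config["db"]
    if not isinstance(db, SketchDatabase):
        db = SketchDatabase(db)
    return placement(
        config["inputs"],
        db,
        n=config.get("n", DEFAULT_NEIGHBORS),
        subspace=config["subspace"],
        **common,
    )
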