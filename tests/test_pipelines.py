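"""Routine, subtraction and placement pipelines, database retrieval, quick."""

import numpy as np
import pytest

import sketchtree as st


@pytest.fixture(scope="module")
def small_subspace():
    return st.generate_subspace(15, 7, 1, 42)


@pytest.fixture(scope="module")
def trio(tmp_path_factory, small_subspace):
    """Three related 20 kb genomes written as FASTA."""
    tmp = tmp_path_factory.mktemp("trio")
    root = st.simdata.random_genome(20_000, seed=1)
    files = []
    for i, p in enumerate((0.01, 0.03, 0.05)):
        name = f"G{i + 1}"
        seq = st.simdata.mutate(root, p, seed=10 + i)
        path = tmp / f"{name}.fasta"
        st.simdata.write_fasta(path, name, seq)
        files.append(path)
    return files


class TestRoutine:
    def test_artifacts_and_leaf_count(self, trio, small_subspace, tmp_path):
        tree = st.routine(trio, small_subspace, "nj", tmp_path / "out")
        assert sorted(tree.leaf_names()) == ["G1", "G2", "G3"]
        out = tmp_path / "out"
        assert (out / "matrix.phy").read_text().splitlines()[0] == "3"
        assert (out / "tree.nwk").exists() and (out / "tree.txt").exists()
        assert len(list((out / "sketches").glob("*.sketch"))) == 3
        assert (out / "run.log").read_text()

    def test_equals_manual_composition_byte_identical(self, trio, small_subspace,
                                                      tmp_path):
        st.routine(trio, small_subspace, "nj", tmp_path / "pipe")
        sketches = [st.sketch_sequence_file(p, small_subspace) for p in trio]
        matrix = st.pairwise_matrix(sketches)
        tree = st.nj(matrix)
        st.write_newick(tree, tmp_path / "manual.nwk")
        assert (tmp_path / "manual.nwk").read_bytes() == \
            (tmp_path / "pipe" / "tree.nwk").read_bytes()

    def test_known_topology_recovered(self, small_subspace, tmp_path):
        truth = st.parse_newick(
            "(((A:0.02,B:0.02):0.03,(C:0.02,D:0.02):0.03):0.02,"
            "((E:0.02,F:0.02):0.03,(G:0.02,H:0.02):0.03):0.02);"
        )
        st.simdata.evolve_tree(50_000, truth, seed=4, outdir=tmp_path / "genomes")
        files = sorted((tmp_path / "genomes").glob("*.fasta"))
        for method in ("nj", "dnj"):
            tree = st.routine(files, small_subspace, method, tmp_path / method)
            assert st.nrf(tree, truth) == 0.0

    def test_too_few_inputs_rejected(self, trio, small_subspace, tmp_path):
        with pytest.raises(ValueError, match=">= 3"):
            st.routine(trio[:2], small_subspace, "nj", tmp_path / "few")

    def test_rerun_is_deterministic(self, trio, small_subspace, tmp_path):
        st.routine(trio, small_subspace, "dnj", tmp_path / "a")
        st.routine(trio, small_subspace, "dnj", tmp_path / "b")
        assert (tmp_path / "a" / "tree.nwk").read_bytes() == \
            (tmp_path / "b" / "tree.nwk").read_bytes()


class TestSubtractPipeline:
    def test_inputs_equal_to_reference_rejected(self, small_subspace, tmp_path):
        genome = st.simdata.random_genome(10_000, seed=5)
        for name in ("ref", "a", "b", "c"):
            st.simdata.write_fasta(tmp_path / f"{name}.fasta", name, genome)
        with pytest.raises(ValueError, match="no informative"):
            st.subtract_pipeline(
                tmp_path / "ref.fasta",
                [tmp_path / f"{n}.fasta" for n in "abc"],
                small_subspace, "nj", tmp_path / "out",
            )

    def test_remainders_disjoint_and_segment_driven(self, tmp_path):
        """Backbone+segment genomes: remainders carry only segment signal."""
        sub = st.generate_subspace(21, 11, 0, 42)
        backbone = st.simdata.random_genome(50_000, seed=6)
        seg0 = st.simdata.random_genome(10_000, seed=7)
        segments = {
            "A": st.simdata.mutate(seg0, 0.01, 20),
            "B": st.simdata.mutate(seg0, 0.03, 21),
            "C": st.simdata.mutate(seg0, 0.05, 22),
        }
        st.simdata.write_fasta(tmp_path / "ref.fasta", "ref", backbone)
        for name, seg in segments.items():
            st.simdata.write_fasta(tmp_path / f"{name}.fasta", name, backbone + seg)
        tree = st.subtract_pipeline(
            tmp_path / "ref.fasta",
            [tmp_path / f"{n}.fasta" for n in "ABC"],
            sub, "nj", tmp_path / "out",
        )
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]
        ref_sketch = st.sketch_sequence_file(tmp_path / "ref.fasta", sub)
        remainder_sketches = {}
        for name in "ABC":
            rem = st.read_sketch(tmp_path / "out" / "remainders" / f"{name}.sketch")
            assert len(st.intersection(rem, ref_sketch)) == 0
            remainder_sketches[name] = rem
        segment_sketches = {
            name: st.sketch_sequences([seg], sub, name=name)
            for name, seg in segments.items()
        }
        for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
            d_rem = st.mash_distance(
                st.jaccard(remainder_sketches[x], remainder_sketches[y]), 21)
            d_seg = st.mash_distance(
                st.jaccard(segment_sketches[x], segment_sketches[y]), 21)
            assert abs(d_rem - d_seg) < 0.005


@pytest.fixture(scope="module")
def cluster_db(tmp_path_factory):
    """20-genome database: 4 well-separated clusters of 5 mutants each."""
    tmp = tmp_path_factory.mktemp("clusterdb")
    sub = st.generate_subspace(21, 11, 0, 42)
    genome_dir = tmp / "genomes"
    genome_dir.mkdir()
    ancestors = {}
    for c in range(4):
        ancestors[c] = st.simdata.random_genome(30_000, seed=50 + c)
        for m in range(5):
            name = f"c{c}m{m}"
            seq = st.simdata.mutate(ancestors[c], 0.01, seed=60 + 5 * c + m)
            st.simdata.write_fasta(genome_dir / f"{name}.fasta", name, seq)
    db = st.build_database(sorted(genome_dir.glob("*.fasta")), sub, tmp / "db")
    return {"db": db, "sub": sub, "ancestors": ancestors, "tmp": tmp}


class TestRetrievalAndPlacement:
    def test_self_query_ranks_first_at_zero(self, cluster_db):
        db, sub = cluster_db["db"], cluster_db["sub"]
        for name in ("c0m0", "c3m4"):
            result = st.retrieve(db.load(name), db, n=3)
            assert result.neighbors[0] == (name, 0.0)

    def test_n_larger_than_db_returns_full_ranking(self, cluster_db):
        db = cluster_db["db"]
        result = st.retrieve(db.load("c1m1"), db, n=1000)
        assert len(result.neighbors) == len(db) == 20

    def test_mutated_query_retrieves_own_cluster(self, cluster_db):
        db, sub = cluster_db["db"], cluster_db["sub"]
        query_seq = st.simdata.mutate(cluster_db["ancestors"][2], 0.02, seed=99)
        query = st.sketch_sequences([query_seq], sub, name="query")
        result = st.retrieve(query, db, n=3)
        assert all(name.startswith("c2") for name, _ in result.neighbors)

    def test_params_mismatch_rejected(self, cluster_db):
        other = st.generate_subspace(21, 11, 2, 42)
        query = st.sketch_sequences(["ACGT" * 100], other, name="q")
        with pytest.raises(ValueError, match="match"):
            st.retrieve(query, cluster_db["db"], n=3)

    def test_placement_puts_query_in_cluster_clade(self, cluster_db, tmp_path):
        db, sub = cluster_db["db"], cluster_db["sub"]
        query_seq = st.simdata.mutate(cluster_db["ancestors"][1], 0.02, seed=98)
        qpath = tmp_path / "query.fasta"
        st.simdata.write_fasta(qpath, "query", query_seq)
        tree = st.placement([qpath], db, n=5, subspace=sub, method="nj",
                            outdir=tmp_path / "out")
        assert "query" in tree.leaf_names()
        # the clade containing the query holds only cluster-1 members
        splits = st.bipartitions(tree).splits
        query_sides = [s for s in splits if "query" in s]
        smallest = min(query_sides, key=len)
        assert all(x == "query" or x.startswith("c1") for x in smallest)
        assert (tmp_path / "out" / "retrieval.tsv").read_text().startswith(
            "query\trank\tneighbor\tdistance"
        )

    def test_placement_deterministic(self, cluster_db, tmp_path):
        db, sub = cluster_db["db"], cluster_db["sub"]
        query_seq = st.simdata.mutate(cluster_db["ancestors"][0], 0.02, seed=97)
        qpath = tmp_path / "q.fasta"
        st.simdata.write_fasta(qpath, "q", query_seq)
        st.placement([qpath], db, n=4, subspace=sub, outdir=tmp_path / "a")
        st.placement([qpath], db, n=4, subspace=sub, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "tree.nwk").read_bytes() == \
            (tmp_path / "b" / "tree.nwk").read_bytes()


class TestQuick:
    def test_routine_dispatch_equals_direct_call(self, trio, small_subspace,
                                                 tmp_path):
        st.quick("routine", {"inputs": trio, "subspace": small_subspace,
                             "outdir": tmp_path / "q"})
        st.routine(trio, small_subspace, "nj", tmp_path / "direct")
        assert (tmp_path / "q" / "tree.nwk").read_bytes() == \
            (tmp_path / "direct" / "tree.nwk").read_bytes()

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="invalid mode"):
            st.quick("bogus", {})

    def test_missing_reference_named(self, trio, small_subspace, tmp_path):
        with pytest.raises(ValueError, match="reference"):
            st.quick("subtract", {"inputs": trio, "subspace": small_subspace,
                                  "outdir": tmp_path / "o"})
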