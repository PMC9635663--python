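"""Homology graph construction, cluster modes, cascade and profile merge."""

import random

import networkx as nx
import pytest

from oracles import bfs_components
from phamkit.alignment import AMINO_ACIDS, AlignmentCache
from phamkit.clustering import (
    ClusterParams,
    assemble_phams,
    build_graph,
    cascade_cluster,
    cluster_graph,
    profile_merge,
)
from phamkit.fixtures import FixtureSpec, build_fixture, generate_family, random_protein
from phamkit.genome_io import GeneRecord, GenomeRecord, deduplicate


def _graph(edges, nodes=None, lengths=None):
    g = nx.Graph()
    for n in nodes or sorted({x for e in edges for x in e}):
        g.add_node(n, length=(lengths or {}).get(n, 10))
    g.add_edges_from(edges)
    return g


class TestClusterModes:
    def test_path_graph_single_linkage(self):
        g = _graph([("A", "B"), ("B", "C"), ("C", "D")])
        assert cluster_graph(g, 1) == [["A", "B", "C", "D"]]

    def test_path_graph_set_cover(self):
        # B and C both cover 3 uncovered nodes; the id tie-break picks B,
        # leaving D as its own cluster.
        g = _graph([("A", "B"), ("B", "C"), ("C", "D")])
        assert cluster_graph(g, 0) == [["A", "B", "C"], ["D"]]

    def test_triangle_plus_isolate_all_modes(self):
        g = _graph([("A", "B"), ("B", "C"), ("A", "C")], nodes=["A", "B", "C", "D"])
        for mode in (0, 1, 2):
            assert cluster_graph(g, mode) == [["A", "B", "C"], ["D"]]

    def test_greedy_incremental_orders_by_length(self):
        # E is longest so it seeds first and absorbs its neighbor D; the
        # rest of the path then clusters from C.
        g = _graph(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")],
            lengths={"A": 5, "B": 6, "C": 7, "D": 8, "E": 20},
        )
        clusters = cluster_graph(g, 2)
        assert ["D", "E"] in clusters

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cluster_graph(_graph([("A", "B")]), 3)

    def test_mode1_matches_bfs_oracle_on_random_graphs(self):
        rng = random.Random(17)
        for _ in range(100):
            n = rng.randint(2, 30)
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if rng.random() < 0.08
            ]
            g = _graph(edges, nodes=nodes)
            assert cluster_graph(g, 1) == bfs_components(nodes, edges)

    def test_set_cover_refines_components(self):
        rng = random.Random(23)
        for _ in range(30):
            n = rng.randint(2, 25)
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if rng.random() < 0.1
            ]
            g = _graph(edges, nodes=nodes)
            assert len(cluster_graph(g, 0)) >= len(cluster_graph(g, 1))


def _nr_from_seqs(seqs):
    genes = [
        GeneRecord(gene_id=f"g{i}", genome_id="G", protein=s)
        for i, s in enumerate(seqs)
    ]
    return deduplicate(genes)


class TestBuildGraph:
    params = ClusterParams(min_seq_id=0.3, coverage=0.7, evalue=1e-3)

    def test_identical_pair_always_edges(self):
        import numpy as np

        seq = random_protein(100, np.random.default_rng(0))
        nr = _nr_from_seqs([seq, seq + "A"])  # nearly identical
        g = build_graph(nr, self.params)
        assert g.number_of_edges() == 1

    def test_random_pairs_produce_no_edges(self):
        import numpy as np

        rng = np.random.default_rng(1)
        edge_total = 0
        for _ in range(100):
            nr = _nr_from_seqs([random_protein(100, rng), random_protein(100, rng)])
            edge_total += build_graph(nr, self.params).number_of_edges()
        assert edge_total == 0

    def test_domain_chain_pair_excluded_by_coverage(self):
        fx = build_fixture(FixtureSpec(seed=11, domain_chain=True))
        seqs = {
            g.gene_id: g.protein for gm in fx.genomes for g in gm.genes
            if "chain" in g.gene_id
        }
        assert len(seqs) == 2
        from phamkit.alignment import local_align

        a, b = list(seqs.values())
        res = local_align(a, b)
        assert min(res.coverage_query, res.coverage_target) < 0.7
        g = build_graph(seqs, self.params)
        assert g.number_of_edges() == 0

    def test_prefilter_only_removes_candidates(self):
        fx = build_fixture(FixtureSpec(seed=5))
        seqs = {g.gene_id: g.protein for gm in fx.genomes for g in gm.genes}
        exhaustive = build_graph(seqs, self.params)
        filtered = build_graph(
            seqs, ClusterParams(min_seq_id=0.3, coverage=0.7, evalue=1e-3,
                                sensitivity=1)
        )
        assert set(filtered.edges) <= set(exhaustive.edges)

    def test_relaxing_thresholds_never_drops_edges(self):
        fx = build_fixture(FixtureSpec(seed=6))
        seqs = {g.gene_id: g.protein for gm in fx.genomes for g in gm.genes}
        cache = AlignmentCache()
        strict = build_graph(
            seqs, ClusterParams(min_seq_id=0.5, coverage=0.9, evalue=1e-3), cache
        )
        relaxed = build_graph(
            seqs, ClusterParams(min_seq_id=0.3, coverage=0.7, evalue=1e-3), cache
        )
        assert set(strict.edges) <= set(relaxed.edges)
        n_strict = len(cluster_graph(strict, 1))
        n_relaxed = len(cluster_graph(relaxed, 1))
        assert n_relaxed <= n_strict


class TestCascade:
    def test_single_step_equals_plain_clustering(self, small_fixture, shared_cache):
        seqs = {
            g.gene_id: g.protein for gm in small_fixture.genomes for g in gm.genes
        }
        params = ClusterParams(min_seq_id=0.35, coverage=0.8, evalue=1e-3)
        direct = cluster_graph(build_graph(seqs, params, shared_cache),
                               params.cluster_mode)
        cascaded = cascade_cluster(seqs, params, shared_cache)
        assert cascaded == direct

    def test_two_steps_match_one_on_easy_families(self, shared_cache):
        import numpy as np

        rng = np.random.default_rng(33)
        seqs = {}
        for fam, ident in enumerate((0.9, 0.6, 0.4)):
            for i, seq in enumerate(
                generate_family(150, 4, ident, rng=rng, indel_prob=0.0)
            ):
                seqs[f"f{fam}m{i}"] = seq
        one = cascade_cluster(
            seqs, ClusterParams(min_seq_id=0.35, coverage=0.8, cluster_steps=1),
            shared_cache,
        )
        two = cascade_cluster(
            seqs, ClusterParams(min_seq_id=0.35, coverage=0.8, cluster_steps=2),
            shared_cache,
        )
        assert one == two

    def test_singleton_input(self):
        seqs = {"only": "MKTAYIAKQRQISFVKSHFSRQ"}
        for steps in (1, 3):
            assert cascade_cluster(
                seqs, ClusterParams(cluster_steps=steps)
            ) == [["only"]]


@pytest.fixture(scope="module")
def remote_subfamilies():
    """Two sub-families (~25% mutual identity) from a common ancestor."""
    import numpy as np

    rng = np.random.default_rng(21)
    ancestor = random_protein(200, rng)
    # Target 0.15 for the ancestral split realises ~25% mutual identity
    # between the sub-families (biased substitutions re-hit residues),
    # below the stage-1 identity threshold but within profile reach.
    sub = generate_family(200, 2, 0.15, rng=rng, indel_prob=0.0,
                          ancestor=ancestor)
    seqs = {}
    for tag, sub_anc in zip("ab", sub):
        fam = generate_family(200, 4, 0.9, rng=rng, indel_prob=0.0,
                              ancestor=sub_anc)
        for i, seq in enumerate(fam):
            seqs[f"{tag}{i}"] = seq
    return seqs


class TestProfileMerge:
    def test_no_cross_hits_is_identity(self, shared_cache):
        import numpy as np

        rng = np.random.default_rng(2)
        seqs = {f"s{i}": random_protein(120, rng) for i in range(4)}
        partition = [[f"s{i}"] for i in range(4)]
        params = ClusterParams(min_seq_id=0.15, coverage=0.6, evalue=1e-3)
        merged = profile_merge(partition, seqs, params, shared_cache)
        assert sorted(map(sorted, merged)) == sorted(map(sorted, partition))

    def test_remote_subfamilies_merge(self, remote_subfamilies, shared_cache):
        seqs = remote_subfamilies
        stage1 = cascade_cluster(
            seqs, ClusterParams(min_seq_id=0.3, coverage=0.75), shared_cache
        )
        assert len(stage1) == 2  # separately clustered at stage 1
        merged = profile_merge(
            stage1, seqs,
            ClusterParams(min_seq_id=0.15, coverage=0.6, evalue=1e-3),
            shared_cache,
        )
        assert len(merged) == 1

    def test_more_iterations_merge_at_least_as_much(
        self, remote_subfamilies, shared_cache
    ):
        seqs = remote_subfamilies
        stage1 = cascade_cluster(
            seqs, ClusterParams(min_seq_id=0.3, coverage=0.75), shared_cache
        )
        params1 = ClusterParams(min_seq_id=0.15, coverage=0.6, num_iterations=1)
        params2 = ClusterParams(min_seq_id=0.15, coverage=0.6, num_iterations=2)
        merged1 = profile_merge(stage1, seqs, params1, shared_cache)
        merged2 = profile_merge(stage1, seqs, params2, shared_cache)
        # every merge done in one iteration survives two
        cluster_of_2 = {m: i for i, c in enumerate(merged2) for m in c}
        for cluster in merged1:
            assert len({cluster_of_2[m] for m in cluster}) == 1

    def test_output_coarsens_input(self, trapfree_fixture, shared_cache):
        seqs = {
            g.gene_id: g.protein
            for gm in trapfree_fixture.genomes
            for g in gm.genes
        }
        stage1 = cascade_cluster(
            seqs, ClusterParams(min_seq_id=0.3, coverage=0.75), shared_cache
        )
        merged = profile_merge(
            stage1, seqs,
            ClusterParams(min_seq_id=0.15, coverage=0.65, evalue=1e-3),
            shared_cache,
        )
        cluster_of = {m: i for i, c in enumerate(merged) for m in c}
        for cluster in stage1:
            assert len({cluster_of[m] for m in cluster}) == 1


class TestAssemblePhams:
    def test_unrelated_genes_become_orphams(self):
        import numpy as np

        rng = np.random.default_rng(14)
        genes = [
            GeneRecord(gene_id=f"g{i}", genome_id="G1",
                       protein=random_protein(100, rng))
            for i in range(5)
        ]
        phams = assemble_phams([GenomeRecord("G1", "G1", genes)],
                               skip_profile=True)
        assert len(phams) == 5
        assert all(len(p) == 1 for p in phams)

    def test_duplicate_genome_doubles_membership(self, small_fixture, shared_cache):
        genomes = small_fixture.genomes
        copy = [
            GenomeRecord(
                genome_id=f"{g.genome_id}dup", name=g.name,
                genes=[
                    GeneRecord(
                        gene_id=f"{x.gene_id}_dup", genome_id=f"{g.genome_id}dup",
                        protein=x.protein, annotation=x.annotation,
                    )
                    for x in g.genes
                ],
            )
            for g in genomes
        ]
        base = assemble_phams(genomes, skip_profile=True, cache=shared_cache)
        doubled = assemble_phams(genomes + copy, skip_profile=True,
                                 cache=shared_cache)
        assert len(doubled) == len(base)
        assert sorted(len(p) for p in doubled) == sorted(2 * len(p) for p in base)

    def test_planted_families_recovered(self, trapfree_fixture, trapfree_phams):
        truth = trapfree_fixture.planted_partition()
        recovered = {tuple(sorted(p.members)) for p in trapfree_phams}
        expected = {tuple(v) for v in truth.values()}
        assert recovered == expected

    def test_phams_partition_gene_set(self, trapfree_fixture, trapfree_phams):
        all_genes = sorted(trapfree_fixture.truth)
        members = sorted(m for p in trapfree_phams for m in p.members)
        assert members == all_genes
        for p in trapfree_phams:
            assert p.representative in p.members

    def test_pham_ids_ordered_by_size(self, trapfree_phams):
        sizes = [len(p) for p in trapfree_phams]
        assert sizes == sorted(sizes, reverse=True)
        assert [p.pham_id for p in trapfree_phams] == list(
            range(1, len(trapfree_phams) + 1)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assemble_phams([])

    def test_rerun_is_identical(self, small_fixture, shared_cache):
        first = assemble_phams(small_fixture.genomes, cache=shared_cache)
        second = assemble_phams(small_fixture.genomes, cache=shared_cache)
        assert [(p.pham_id, p.members, p.representative) for p in first] == [
            (p.pham_id, p.members, p.representative) for p in second
        ]
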