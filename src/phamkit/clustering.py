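"""Homology-graph construction and its interpretation into phams.

The pipeline mirrors cascaded sequence clustering as practised by tools
like MMseqs2 and CD-HIT: all-vs-all local alignments are filtered by
identity, bidirectional coverage and E-value thresholds into a homology
graph, which one of three cluster modes interprets into clusters:

* mode 0 — greedy set cover: repeatedly pick the node covering the most
  still-uncovered nodes (itself plus uncovered neighbors) and form a
  cluster from them;
* mode 1 — single-linkage: connected components (blastclust-like);
* mode 2 — greedy-incremental: iterate nodes by descending sequence
  length; each unassigned node becomes a representative and absorbs its
  unassigned neighbors (CD-HIT-like).

Cascaded clustering starts from stricter thresholds and relaxes them over
``cluster_steps`` rounds, re-clustering the representatives of the previous
round and merging their clusters.  An optional profile–sequence stage then
merges phams whose members are remote homologs invisible to plain pairwise
search.

Everything is deterministic: tie-breaks are by sequence length then
lexicographic id, and iteration order follows input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .alignment import AlignmentCache, compute_evalue
from .genome_io import (
    GenomeRecord,
    NonRedundantSet,
    deduplicate,
    expand_clusters,
    sequence_digest,
)
from .profiles import ProfileMatrix, build_profile, center_star_msa, profile_local_align

logger = logging.getLogger(__name__)

#: k-mer length of the exact-word prefilter enabled at sensitivity < 7.
PREFILTER_K = 5

#: Upper anchors from which cascaded clustering relaxes towards the target.
CASCADE_IDENTITY_CEILING = 0.9
CASCADE_COVERAGE_CEILING = 0.95


@dataclass(frozen=True)
class ClusterParams:
    """The six tunable clustering parameters plus their validation.

    ``cluster_steps`` applies to the sequence–sequence stage and
    ``num_iterations`` to the profile–sequence stage; each stage reads only
    its own knob.
    """

    min_seq_id: float = 0.30
    coverage: float = 0.75
    evalue: float = 1e-5
    sensitivity: int = 7
    cluster_mode: int = 0
    cluster_steps: int = 1
    num_iterations: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.min_seq_id <= 1.0):
            raise ValueError("min_seq_id must be in (0, 1]")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.cluster_mode not in (0, 1, 2):
            raise ValueError("cluster_mode must be 0, 1 or 2")
        if self.cluster_steps < 1 or self.num_iterations < 1:
            raise ValueError("cluster_steps/num_iterations must be >= 1")


#: Defaults selected by the synthetic-data grid-search harness (see docs).
DEFAULT_SEQUENCE_PARAMS = ClusterParams(
    min_seq_id=0.30, coverage=0.75, evalue=1e-5,
    sensitivity=7, cluster_mode=0, cluster_steps=1,
)
DEFAULT_PROFILE_PARAMS = ClusterParams(
    min_seq_id=0.15, coverage=0.65, evalue=1e-3,
    sensitivity=7, cluster_mode=0, num_iterations=1,
)


@dataclass
class Pham:
    """One gene phamily over the full (redundant) gene set."""

    pham_id: int
    members: list[str]
    representative: str
    sequences: dict[str, str]
    annotations: dict[str, str] = field(default_factory=dict)
    msa: list[tuple[str, str]] | None = None

    def __len__(self) -> int:
        return len(self.members)

    def sequence_of(self, gene_id: str) -> str:
        return self.sequences[gene_id]


def _kmer_candidates(seqs: dict[str, str], k: int = PREFILTER_K) -> set[frozenset]:
    """Unordered id pairs sharing at least one exact k-mer."""
    index: dict[str, list[str]] = {}
    for sid, seq in seqs.items():
        for i in range(max(len(seq) - k + 1, 0)):
            index.setdefault(seq[i : i + k], []).append(sid)
    pairs: set[frozenset] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        uniq = sorted(set(ids))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                pairs.add(frozenset((a, b)))
    return pairs


def build_graph(
    nr: NonRedundantSet | dict[str, str],
    params: ClusterParams,
    cache: AlignmentCache | None = None,
) -> nx.Graph:
    """All-vs-all homology graph over nonredundant sequences.

    Nodes carry a ``length`` attribute; edges carry the filtered
    :class:`~phamkit.alignment.AlignmentResult` under ``result``.  At
    sensitivity below 7 an exact 5-mer prefilter limits which pairs are
    aligned; it can only remove candidate edges, never add them.
    """
    if isinstance(nr, NonRedundantSet):
        seqs = {d: nr.sequence(d) for d in nr.digests()}
    else:
        seqs = dict(nr)
    if not seqs:
        raise ValueError("empty sequence set")
    cache = cache or AlignmentCache()
    db_size = sum(len(s) for s in seqs.values())
    g = nx.Graph()
    for sid, seq in seqs.items():
        g.add_node(sid, length=len(seq))
    ids = list(seqs)
    candidates = None
    if params.sensitivity < 7:
        candidates = _kmer_candidates(seqs)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if candidates is not None and frozenset((a, b)) not in candidates:
                continue
            res = cache.local_align(seqs[a], seqs[b])
            if res.identity < params.min_seq_id:
                continue
            if min(res.coverage_query, res.coverage_target) < params.coverage:
                continue
            ev = compute_evalue(
                res.raw_score, len(seqs[a]), len(seqs[b]), db_size, cache.scheme
            )
            if ev > params.evalue:
                continue
            g.add_edge(a, b, result=res, evalue=ev)
    return g


def _sorted_partition(clusters: list[list[str]]) -> list[list[str]]:
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def cluster_graph(g: nx.Graph, mode: int) -> list[list[str]]:
    """Interpret a homology graph into clusters under one cluster mode."""
    if mode == 1:
        return _sorted_partition([list(c) for c in nx.connected_components(g)])
    if mode == 0:
        uncovered = set(g.nodes)
        clusters = []
        while uncovered:
            best = min(
                uncovered,
                key=lambda n: (
                    -(1 + sum(1 for nb in g[n] if nb in uncovered)),
                    -g.nodes[n]["length"],
                    n,
                ),
            )
            cluster = [best] + [nb for nb in g[best] if nb in uncovered and nb != best]
            uncovered -= set(cluster)
            clusters.append(cluster)
        return _sorted_partition(clusters)
    if mode == 2:
        unassigned = set(g.nodes)
        order = sorted(g.nodes, key=lambda n: (-g.nodes[n]["length"], n))
        clusters = []
        for node in order:
            if node not in unassigned:
                continue
            cluster = [node] + [nb for nb in g[node] if nb in unassigned and nb != node]
            unassigned -= set(cluster)
            clusters.append(cluster)
        return _sorted_partition(clusters)
    raise ValueError(f"unknown cluster mode {mode}")


def _step_params(params: ClusterParams, step: int, n_steps: int) -> ClusterParams:
    """Thresholds for cascade step ``step`` (1-based) of ``n_steps``.

    Linear relaxation from strict anchors down to the target values; the
    final step uses the target thresholds exactly.
    """
    frac = (n_steps - step) / n_steps
    min_id = params.min_seq_id + (
        max(CASCADE_IDENTITY_CEILING, params.min_seq_id) - params.min_seq_id
    ) * frac
    cov = params.coverage + (
        max(CASCADE_COVERAGE_CEILING, params.coverage) - params.coverage
    ) * frac
    return replace(params, min_seq_id=min_id, coverage=cov, cluster_steps=1)


def _cluster_representative(members: list[str], seqs: dict[str, str]) -> str:
    """Longest member, ties by lexicographically smallest id."""
    return min(members, key=lambda m: (-len(seqs[m]), m))


def cascade_cluster(
    nr: NonRedundantSet | dict[str, str],
    params: ClusterParams,
    cache: AlignmentCache | None = None,
) -> list[list[str]]:
    """Cascaded clustering of the nonredundant set into digest clusters.

    With ``cluster_steps`` = 1 this is exactly ``cluster_graph`` applied to
    ``build_graph``.  With more steps, earlier rounds run at interpolated,
    stricter thresholds and later rounds re-cluster the representatives of
    the previous round, merging their clusters.
    """
    if isinstance(nr, NonRedundantSet):
        seqs = {d: nr.sequence(d) for d in nr.digests()}
    else:
        seqs = dict(nr)
    cache = cache or AlignmentCache()
    partition = [[d] for d in seqs]
    for step in range(1, params.cluster_steps + 1):
        step_params = _step_params(params, step, params.cluster_steps)
        reps = {
            _cluster_representative(cluster, seqs): idx
            for idx, cluster in enumerate(partition)
        }
        rep_seqs = {rep: seqs[rep] for rep in reps}
        g = build_graph(rep_seqs, step_params, cache)
        rep_clusters = cluster_graph(g, step_params.cluster_mode)
        merged = [
            sorted(sum((partition[reps[rep]] for rep in cluster), []))
            for cluster in rep_clusters
        ]
        partition = merged
    return _sorted_partition(partition)


def profile_merge(
    partition: list[list[str]],
    nr: NonRedundantSet | dict[str, str],
    params: ClusterParams,
    cache: AlignmentCache | None = None,
) -> list[list[str]]:
    """Merge clusters via iterative profile–sequence search.

    Each iteration builds a profile per cluster (center-star MSA around the
    longest member plus any sequences attached in earlier iterations),
    searches it against every nonredundant sequence, and records a
    cluster–cluster edge whenever a profile hits a sequence of a different
    cluster at the given identity/coverage/E-value thresholds.  Profiles
    absorb their hits between iterations (PSI-BLAST-like).  The cluster
    graph is finally interpreted by ``cluster_mode``; the result is always
    a coarsening of the input partition.
    """
    if isinstance(nr, NonRedundantSet):
        seqs = {d: nr.sequence(d) for d in nr.digests()}
    else:
        seqs = dict(nr)
    cache = cache or AlignmentCache()
    db_size = sum(len(s) for s in seqs.values())
    cluster_of = {
        digest: idx for idx, cluster in enumerate(partition) for digest in cluster
    }
    attached: dict[int, list[str]] = {idx: [] for idx in range(len(partition))}
    edges: set[tuple[int, int]] = set()
    for _ in range(params.num_iterations):
        for idx, cluster in enumerate(partition):
            members = list(dict.fromkeys(cluster + attached[idx]))
            center = _cluster_representative(members, seqs)
            others = [seqs[m] for m in members if m != center]
            msa = center_star_msa(seqs[center], others, cache.scheme)
            profile = build_profile(msa, source_pham=idx, scheme=cache.scheme)
            for digest, seq in seqs.items():
                other_idx = cluster_of[digest]
                if other_idx == idx:
                    continue
                hit = profile_local_align(profile, seq)
                if hit.identity < params.min_seq_id:
                    continue
                if min(hit.coverage_profile, hit.coverage_sequence) < params.coverage:
                    continue
                ev = compute_evalue(
                    hit.raw_score, profile.n_cols, len(seq), db_size, cache.scheme
                )
                if ev > params.evalue:
                    continue
                edges.add((min(idx, other_idx), max(idx, other_idx)))
                if digest not in attached[idx]:
                    attached[idx].append(digest)
    g = nx.Graph()
    for idx, cluster in enumerate(partition):
        rep = _cluster_representative(cluster, seqs)
        g.add_node(str(idx), length=len(seqs[rep]))
    for a, b in sorted(edges):
        g.add_edge(str(a), str(b))
    merged = [
        sorted(sum((partition[int(i)] for i in cluster), []))
        for cluster in cluster_graph(g, params.cluster_mode)
    ]
    return _sorted_partition(merged)


def select_representative_seq(
    member_seqs: dict[str, str], cache: AlignmentCache | None = None
) -> str:
    """Member id with the highest mean global similarity to the others.

    Ties go to the longest sequence, then the smallest id.  A singleton is
    its own representative.
    """
    if not member_seqs:
        raise ValueError("empty member set")
    ids = sorted(member_seqs)
    if len(ids) == 1:
        return ids[0]
    cache = cache or AlignmentCache()
    best_id, best_key = None, None
    for mid in ids:
        sims = [
            cache.global_align(member_seqs[mid], member_seqs[other]).similarity
            for other in ids
            if other != mid
        ]
        mean_sim = sum(sims) / len(sims)
        key = (-mean_sim, -len(member_seqs[mid]), mid)
        if best_key is None or key < best_key:
            best_id, best_key = mid, key
    return best_id


def assemble_phams(
    genomes: list[GenomeRecord],
    params: ClusterParams = DEFAULT_SEQUENCE_PARAMS,
    profile_params: ClusterParams = DEFAULT_PROFILE_PARAMS,
    skip_profile: bool = False,
    cache: AlignmentCache | None = None,
) -> list[Pham]:
    """Full pham-assembly pipeline over parsed genomes.

    deduplicate → cascaded sequence clustering → optional profile merge →
    expansion to gene copies.  Pham ids are assigned by descending size,
    ties by smallest member gene_id; the representative is the member with
    the highest average similarity to the rest.
    """
    genes = [gene for genome in genomes for gene in genome.genes]
    if not genes:
        raise ValueError("no genes in input")
    cache = cache or AlignmentCache()
    nr = deduplicate(genes)
    partition = cascade_cluster(nr, params, cache)
    if not skip_profile:
        partition = profile_merge(partition, nr, profile_params, cache)
    gene_clusters = expand_clusters(partition, nr)
    gene_index = {gene.gene_id: gene for gene in genes}
    gene_clusters = [sorted(c) for c in gene_clusters]
    gene_clusters.sort(key=lambda c: (-len(c), c[0]))
    phams = []
    for pham_id, members in enumerate(gene_clusters, start=1):
        sequences = {m: gene_index[m].protein for m in members}
        annotations = {m: gene_index[m].annotation for m in members}
        rep = select_representative_seq(sequences, cache)
        phams.append(
            Pham(
                pham_id=pham_id,
                members=members,
                representative=rep,
                sequences=sequences,
                annotations=annotations,
            )
        )
    logger.info(
        "assembled %d phams from %d genes (%d nonredundant)",
        len(phams), len(genes), nr.n_sequences,
    )
    return phams


def compute_pham_msa(pham: Pham, cache: AlignmentCache | None = None) -> None:
    """Attach a center-star MSA (around the representative) to ``pham``."""
    cache = cache or AlignmentCache()
    rep_seq = pham.sequences[pham.representative]
    # Distinct sequences only; duplicate copies reuse the same aligned row.
    others = [m for m in pham.members if m != pham.representative]
    rows = center_star_msa(rep_seq, [pham.sequences[m] for m in others], cache.scheme)
    pham.msa = [(pham.representative, rows[0])] + list(zip(others, rows[1:]))


def write_pham_fastas(phams: list[Pham], outdir: str | Path) -> list[Path]:
    """Write each pham to ``pham_<id>.faa`` (one FASTA per pham)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pham in phams:
        path = outdir / f"pham_{pham.pham_id}.faa"
        with open(path, "w") as fh:
            for member in pham.members:
                fh.write(f">{member}\n{pham.sequences[member]}\n")
        paths.append(path)
    return paths


def write_pham_alignments(phams: list[Pham], outdir: str | Path) -> list[Path]:
    """Write per-pham aligned FASTA files (computing MSAs as needed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pham in phams:
        if pham.msa is None:
            compute_pham_msa(pham)
        path = outdir / f"pham_{pham.pham_id}_aligned.faa"
        with open(path, "w") as fh:
            for gene_id, row in pham.msa:
                fh.write(f">{gene_id}\n{row}\n")
        paths.append(path)
    return paths
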