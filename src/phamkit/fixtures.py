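"""Deterministic synthetic genomes with planted protein families.

The generator emulates the structure of a phage comparative-genomics
dataset — families of globally homologous proteins at controlled identity
levels, singleton genes without homologs (orphams), and the known failure
modes of homology clustering: domain chaining (two unrelated backbones
sharing one local domain), intein-like insertions interrupting otherwise
close homologs, and short gene fragments.

Members of a family are derived independently from a random ancestor by
point substitutions sampled proportionally to ``exp(BLOSUM62 score)`` (so
substitutions prefer biochemically plausible replacements) plus rare short
indels.  A per-member substitution rate of ``1 - sqrt(t)`` yields a mean
pairwise identity close to the target ``t``.

Everything derives from a single integer seed: the same spec and seed give
byte-identical output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .alignment import AMINO_ACIDS, BACKGROUND_FREQUENCIES, DEFAULT_SCHEME
from .genome_io import GeneRecord, GenomeRecord

#: Family function labels cycled over planted families (with one synonym
#: variant per family to exercise annotation normalization).
_FAMILY_LABELS = [
    ("portal", "Portal protein"),
    ("terminase, large subunit", "TerL"),
    ("major capsid protein", "Major Capsid Protein"),
    ("minor tail protein", "minor tail"),
    ("lysin B", "LysB"),
    ("DNA primase", "dna primase"),
    ("DNA helicase", "DNA Helicase"),
    ("immunity repressor", "repressor"),
]

_BACKGROUND = np.array([BACKGROUND_FREQUENCIES[aa] for aa in AMINO_ACIDS])
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

# Substitution proposal distributions, one row per original residue,
# proportional to exp(BLOSUM62 score), diagonal excluded.
_SUB_PROBS = {}
for _orig in AMINO_ACIDS:
    _w = np.array(
        [
            math.exp(DEFAULT_SCHEME.score(_orig, aa)) if aa != _orig else 0.0
            for aa in AMINO_ACIDS
        ]
    )
    _SUB_PROBS[_orig] = _w / _w.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint of a synthetic dataset with known ground truth."""

    n_families: int = 5
    members_per_family: int = 8
    family_identities: tuple[float, ...] = (0.9, 0.7, 0.5, 0.4, 0.35)
    ancestor_length: int = 200
    n_orphams: int = 10
    orpham_length: int = 200
    domain_chain: bool = False
    intein: bool = False
    short_fragment: bool = False
    indel_prob: float = 0.1
    seed: int = 0


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random protein drawn from BLOSUM62 background frequencies."""
    idx = rng.choice(20, size=length, p=_BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(
    seq: str, sub_rate: float, rng: np.random.Generator, indel_prob: float
) -> str:
    out = list(seq)
    for i, res in enumerate(out):
        if rng.random() < sub_rate:
            out[i] = AMINO_ACIDS[int(rng.choice(20, p=_SUB_PROBS[res]))]
    if indel_prob > 0 and rng.random() < indel_prob and len(out) > 20:
        length = int(rng.integers(1, 4))
        pos = int(rng.integers(5, len(out) - 5))
        if rng.random() < 0.5:
            del out[pos : pos + length]
        else:
            out[pos:pos] = list(random_protein(length, rng))
    return "".join(out)


def generate_family(
    ancestor_length: int,
    n: int,
    identity: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    indel_prob: float = 0.1,
    ancestor: str | None = None,
) -> list[str]:
    """``n`` proteins derived from one ancestor at a target mean identity.

    Each member is mutated independently at per-site rate ``1 - sqrt(t)``
    so pairwise identity concentrates near ``t``; with ``identity`` = 1 the
    members are exact copies.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = random_protein(ancestor_length, rng)
    if identity >= 1.0:
        return [ancestor] * n
    sub_rate = 1.0 - math.sqrt(identity)
    return [_mutate(ancestor, sub_rate, rng, indel_prob) for _ in range(n)]


@dataclass
class TrapGene:
    """One planted trap protein with its ground-truth expectation."""

    name: str
    protein: str
    family: str  # true family id ("" when unrelated to everything)
    trap: str  # "domain_chain", "intein" or "short_fragment"
    annotation: str = "hypothetical protein"


def generate_traps(spec: FixtureSpec, rng: np.random.Generator) -> list[TrapGene]:
    """Planted failure-mode proteins with known expected behavior."""
    traps: list[TrapGene] = []
    if spec.domain_chain:
        # One shared 60-residue domain (25% of length) inside two otherwise
        # unrelated 240-residue backbones: must not co-cluster at
        # coverage thresholds >= 0.7.
        domain = random_protein(60, rng)
        for tag in ("A", "B"):
            backbone_l = random_protein(90, rng)
            backbone_r = random_protein(90, rng)
            traps.append(
                TrapGene(
                    name=f"trap_chain_{tag}",
                    protein=backbone_l + domain + backbone_r,
                    family=f"chain_{tag}",
                    trap="domain_chain",
                )
            )
    if spec.intein:
        # Close homologs (identity 0.8) where half the members carry a
        # 150-residue intein-like insertion; the family should survive
        # clustering intact once the profile stage runs at relaxed coverage.
        core = generate_family(300, 6, 0.8, rng=rng, indel_prob=0.0)
        intein_seq = random_protein(150, rng)
        for i, seq in enumerate(core):
            protein = seq if i < 3 else seq[:150] + intein_seq + seq[150:]
            traps.append(
                TrapGene(
                    name=f"trap_intein_{i}",
                    protein=protein,
                    family="intein_family",
                    trap="intein",
                    annotation="DNA polymerase I",
                )
            )
    return traps


@dataclass
class Fixture:
    """Generated genomes plus their ground truth."""

    spec: FixtureSpec
    genomes: list[GenomeRecord]
    truth: dict[str, dict] = field(default_factory=dict)

    def planted_partition(self) -> dict[str, list[str]]:
        """Ground-truth family → gene ids (orphams are their own family)."""
        partition: dict[str, list[str]] = {}
        for gene_id, info in self.truth.items():
            partition.setdefault(info["family"], []).append(gene_id)
        return {fam: sorted(ids) for fam, ids in partition.items()}


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the in-memory dataset described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n_genomes = spec.members_per_family
    genome_genes: list[list[tuple[str, str, str]]] = [[] for _ in range(n_genomes)]
    truth: dict[str, dict] = {}

    identities = list(spec.family_identities)
    while len(identities) < spec.n_families:
        identities.append(identities[-1] if identities else 0.5)
    family_ancestors: dict[str, str] = {}
    for f in range(spec.n_families):
        fam = f"F{f + 1}"
        canonical, variant = _FAMILY_LABELS[f % len(_FAMILY_LABELS)]
        ancestor = random_protein(spec.ancestor_length, rng)
        family_ancestors[fam] = ancestor
        members = generate_family(
            spec.ancestor_length,
            spec.members_per_family,
            identities[f],
            rng=rng,
            indel_prob=spec.indel_prob,
            ancestor=ancestor,
        )
        for i, protein in enumerate(members):
            gene_id = f"G{i + 1}_{fam}"
            annotation = variant if i == 0 else canonical
            genome_genes[i].append((gene_id, protein, annotation))
            truth[gene_id] = {"family": fam, "trap": ""}

    for k in range(spec.n_orphams):
        gene_id = f"G{k % n_genomes + 1}_orpham{k + 1}"
        protein = random_protein(spec.orpham_length, rng)
        genome_genes[k % n_genomes].append((gene_id, protein, "hypothetical protein"))
        truth[gene_id] = {"family": f"orpham{k + 1}", "trap": ""}

    traps = generate_traps(spec, rng)
    if spec.short_fragment:
        # Truncated member of family 1: belongs there by descent but is
        # under 60% of the family length, so an audit must flag it.
        frag_len = int(0.4 * spec.ancestor_length)
        fragment = family_ancestors["F1"][:frag_len]
        traps.append(
            TrapGene(
                name="trap_fragment",
                protein=fragment,
                family="F1",
                trap="short_fragment",
                annotation=_FAMILY_LABELS[0][0],
            )
        )
    for k, trap in enumerate(traps):
        genome_idx = k % n_genomes
        gene_id = f"G{genome_idx + 1}_{trap.name}"
        genome_genes[genome_idx].append((gene_id, trap.protein, trap.annotation))
        truth[gene_id] = {"family": trap.family, "trap": trap.trap}

    genomes = []
    for i, gene_list in enumerate(genome_genes):
        genome_id = f"G{i + 1}"
        genes = []
        offset = 1
        for gene_id, protein, annotation in gene_list:
            nt_len = 3 * len(protein) + 3
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    protein=protein,
                    annotation=annotation,
                    start=offset,
                    stop=offset + nt_len - 1,
                    strand="+",
                )
            )
            offset += nt_len + 100  # synthetic spacing between genes
        genomes.append(GenomeRecord(genome_id=genome_id, name=genome_id, genes=genes))
    return Fixture(spec=spec, genomes=genomes, truth=truth)


_CODON_OF = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[11].forward_table.items():
    if _aa not in _CODON_OF or _codon < _CODON_OF[_aa]:
        _CODON_OF[_aa] = _codon
_CODON_OF["M"] = "ATG"
_CODON_OF["X"] = "GCT"  # arbitrary sense codon for unknown residues


def back_translate(protein: str) -> str:
    """Fixed-codon reverse translation with a terminal stop (TAA)."""
    return "".join(_CODON_OF[res] for res in protein) + "TAA"


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Write per-genome GenBank and FASTA files plus a ground-truth TSV."""
    fixture = build_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO

    for genome in fixture.genomes:
        segments = []
        features = []
        cursor = 0
        for gene in genome.genes:
            spacer = gene.start - 1 - cursor
            if spacer > 0:
                segments.append("A" * spacer)
            nt = back_translate(gene.protein)
            segments.append(nt)
            cursor = gene.stop
            features.append(
                SeqFeature(
                    FeatureLocation(gene.start - 1, gene.stop, strand=1),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [gene.gene_id],
                        "product": [gene.annotation],
                        "transl_table": ["11"],
                        "translation": [gene.protein],
                    },
                )
            )
        record = SeqRecord(
            Seq("".join(segments)),
            id=genome.genome_id,
            name=genome.genome_id,
            description=f"synthetic genome {genome.genome_id}",
            features=features,
            annotations={"molecule_type": "DNA"},
        )
        SeqIO.write(record, outdir / f"{genome.genome_id}.gbk", "genbank")
        with open(outdir / f"{genome.genome_id}.faa", "w") as fh:
            for gene in genome.genes:
                fh.write(f">{gene.gene_id} {gene.annotation}\n{gene.protein}\n")

    with open(outdir / "truth.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "genome_id", "family", "trap"])
        for genome in fixture.genomes:
            for gene in genome.genes:
                info = fixture.truth[gene.gene_id]
                writer.writerow([gene.gene_id, genome.genome_id,
                                 info["family"], info["trap"]])
    return fixture
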