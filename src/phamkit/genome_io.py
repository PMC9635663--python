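"""Parsing of GenBank/FASTA inputs into gene records and redundancy handling.

Genomes are read with Biopython; every protein-coding gene becomes a
:class:`GeneRecord`.  Identical amino-acid sequences occurring in multiple
genomes are collapsed into a :class:`NonRedundantSet` before clustering and
expanded back to gene copies afterwards, so all homology computations run
once per distinct sequence.

Coordinates are 1-based inclusive, exactly as printed in GenBank flat files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Residues accepted in a protein string; anything else is mapped to X.
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Minimum protein length below which a parsed gene is skipped as junk.
MIN_PROTEIN_LENGTH = 10

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_START_CODONS_11 = set(_TABLE11.start_codons)


class InputError(Exception):
    """An input file could not be read or parsed."""


class ConsistencyError(Exception):
    """Cross-references between records are inconsistent."""


@dataclass
class GeneRecord:
    """One protein-coding gene.

    ``start``/``stop`` are 1-based inclusive nucleotide coordinates (absent
    for plain FASTA input); ``strand`` is "+" or "-".  ``protein`` holds the
    uppercase amino-acid sequence without a terminal stop.
    """

    gene_id: str
    genome_id: str
    protein: str
    annotation: str = ""
    start: int | None = None
    stop: int | None = None
    strand: str | None = None
    translation_table: int = 11

    def __post_init__(self) -> None:
        self.protein = clean_protein(self.protein)
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")

    def __len__(self) -> int:
        return len(self.protein)


@dataclass
class GenomeRecord:
    """A genome and its ordered list of genes."""

    genome_id: str
    name: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if all(g.start is not None for g in self.genes):
            self.genes.sort(key=lambda g: (g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class NonRedundantSet:
    """Exact-duplicate collapse of a gene set.

    ``entries`` maps a sequence digest to ``(protein, [gene_ids])``; all
    genes listed under one digest share the identical protein string.
    """

    entries: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return sum(len(ids) for _, ids in self.entries.values())

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for seq, _ in self.entries.values())

    def sequence(self, digest: str) -> str:
        return self.entries[digest][0]

    def gene_ids(self, digest: str) -> list[str]:
        return self.entries[digest][1]

    def digests(self) -> list[str]:
        return list(self.entries)


def sequence_digest(protein: str) -> str:
    """Stable short digest of an uppercased protein string."""
    return hashlib.sha256(protein.upper().encode()).hexdigest()[:16]


def clean_protein(raw: str) -> str:
    """Uppercase, strip stops/gaps, and map non-standard residues to X."""
    out = []
    for ch in raw.upper().strip():
        if ch in ("*", "-", ".", " "):
            continue
        out.append(ch if ch in STANDARD_RESIDUES or ch == "X" else "X")
    return "".join(out)


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a complete CDS, rendering the initiator codon as M.

    The terminal stop is removed; ambiguous codons become X.  An internal
    stop or a length not divisible by 3 raises ``ValueError`` — both signal
    a malformed CDS rather than a biological edge case.
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} is not a positive multiple of 3")
    prot = str(Seq(nt).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    if prot and nt[:3] in set(codon_table.start_codons):
        prot = "M" + prot[1:]
    return clean_protein(prot)


def _gene_id_for_feature(feature, genome_id: str, index: int) -> str:
    for key in ("locus_tag", "protein_id", "gene"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"{genome_id}_CDS_{index}"


def _parse_genbank(path: Path) -> GenomeRecord:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise InputError(f"{path}: no GenBank records found")
    # Multi-record files are treated as one genome (e.g. multi-contig drafts).
    genome_id = records[0].id if records[0].id != "unknown" else path.stem
    genes: list[GeneRecord] = []
    index = 0
    for rec in records:
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            index += 1
            gene_id = _gene_id_for_feature(feature, genome_id, index)
            annotation = ""
            for key in ("product", "function"):
                if key in feature.qualifiers:
                    annotation = feature.qualifiers[key][0]
                    break
            table = int(feature.qualifiers.get("transl_table", ["11"])[0])
            protein = None
            if "translation" in feature.qualifiers:
                # The depositor's conceptual translation wins over our own.
                protein = clean_protein(feature.qualifiers["translation"][0])
            elif len(rec.seq) > 0:
                nt = str(feature.location.extract(rec.seq))
                try:
                    protein = translate_cds(nt, table=table)
                except ValueError as exc:
                    logger.warning("skipping CDS %s: %s", gene_id, exc)
                    continue
            if not protein:
                logger.warning(
                    "skipping CDS %s: no translation and no sequence", gene_id
                )
                continue
            if len(protein) < MIN_PROTEIN_LENGTH:
                logger.warning(
                    "skipping CDS %s: translation shorter than %d residues",
                    gene_id,
                    MIN_PROTEIN_LENGTH,
                )
                continue
            start = int(feature.location.start) + 1  # to 1-based inclusive
            stop = int(feature.location.end)
            strand = "-" if feature.location.strand == -1 else "+"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    protein=protein,
                    annotation=annotation,
                    start=start,
                    stop=stop,
                    strand=strand,
                    translation_table=table,
                )
            )
    return GenomeRecord(genome_id=genome_id, name=records[0].description, genes=genes)


def _parse_fasta(path: Path, translate: bool) -> GenomeRecord:
    genome_id = path.stem
    genes: list[GeneRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        annotation = rec.description.partition(" ")[2].strip()
        if translate:
            try:
                protein = translate_cds(str(rec.seq))
            except ValueError as exc:
                logger.warning("skipping record %s: %s", rec.id, exc)
                continue
        else:
            protein = clean_protein(str(rec.seq))
        if len(protein) < MIN_PROTEIN_LENGTH:
            logger.warning("skipping record %s: protein too short", rec.id)
            continue
        genes.append(
            GeneRecord(
                gene_id=rec.id,
                genome_id=genome_id,
                protein=protein,
                annotation=annotation,
            )
        )
    if not genes:
        raise InputError(f"{path}: no usable FASTA records")
    return GenomeRecord(genome_id=genome_id, name=genome_id, genes=genes)


def parse_genome(path: str | Path, format: str = "auto") -> GenomeRecord:
    """Parse one input file into a :class:`GenomeRecord`.

    ``format`` is one of ``genbank``, ``fasta-aa``, ``fasta-nt`` or ``auto``
    (sniffed from the extension: .gb/.gbk/.gbff → GenBank, else protein
    FASTA).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    if format == "auto":
        format = (
            "genbank"
            if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank")
            else "fasta-aa"
        )
    try:
        if format == "genbank":
            return _parse_genbank(path)
        if format == "fasta-aa":
            return _parse_fasta(path, translate=False)
        if format == "fasta-nt":
            return _parse_fasta(path, translate=True)
    except InputError:
        raise
    except Exception as exc:  # malformed file under the named standard
        raise InputError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown format {format!r}")


def deduplicate(genes: Iterable[GeneRecord]) -> NonRedundantSet:
    """Collapse genes with byte-identical protein sequences.

    Entry order follows first occurrence in the input, which keeps all
    downstream iteration deterministic for a fixed input order.
    """
    nr = NonRedundantSet()
    seen_ids: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen_ids:
            raise ConsistencyError(f"duplicate gene_id {gene.gene_id!r}")
        seen_ids.add(gene.gene_id)
        digest = sequence_digest(gene.protein)
        if digest in nr.entries:
            nr.entries[digest][1].append(gene.gene_id)
        else:
            nr.entries[digest] = (gene.protein, [gene.gene_id])
    return nr


def expand_clusters(
    clusters: Iterable[Iterable[str]], nr: NonRedundantSet
) -> list[list[str]]:
    """Expand clusters of nonredundant digests back to gene_id lists.

    Genes sharing an identical sequence always land in the same cluster.
    """
    expanded: list[list[str]] = []
    seen: set[str] = set()
    for cluster in clusters:
        gene_ids: list[str] = []
        for digest in cluster:
            if digest not in nr.entries:
                raise ConsistencyError(f"unknown nonredundant id {digest!r}")
            if digest in seen:
                raise ConsistencyError(f"digest {digest!r} assigned twice")
            seen.add(digest)
            gene_ids.extend(nr.gene_ids(digest))
        expanded.append(gene_ids)
    return expanded
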