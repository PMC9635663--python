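"""Pangenome-style reports over an assembled pham set.

Three outputs, available when each input file held a single genome:
conservation categories per pham (core / soft-core / shell / cloud by the
percentage of genomes carrying a member), a Roary-style summary with a
presence–absence matrix, and a genome → pham map.

Category boundaries are strict: core > 99%, soft-core > 95%, shell > 15%,
cloud > 0% of genomes; a percentage exactly on a boundary falls in the
lower (less conserved) category.  "Percentage of genomes" counts genomes
with at least one member gene, not gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clustering import Pham
from .genome_io import ConsistencyError, GenomeRecord

CATEGORIES = ("core", "soft-core", "shell", "cloud")


def classify_conservation(percent_genomes: float) -> str:
    """Conservation category for the percentage of genomes with a member."""
    if not (0.0 < percent_genomes <= 100.0):
        raise ValueError("percentage must be in (0, 100]")
    if percent_genomes > 99.0:
        return "core"
    if percent_genomes > 95.0:
        return "soft-core"
    if percent_genomes > 15.0:
        return "shell"
    return "cloud"


@dataclass
class PangenomeSummary:
    """Per-pham conservation stats and the presence–absence matrix."""

    table: pd.DataFrame  # one row per pham, one trailing column per genome
    genome_ids: list[str]
    categories: dict[int, str] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for cat in self.categories.values():
            counts[cat] += 1
        return counts


@dataclass
class PhamSummaryStats:
    """Dataset-level pham statistics (means and percentages rounded as printed)."""

    n_phams: int
    total_genes: int
    mean_size: float  # 2 decimals
    largest_size: int
    n_orphams: int
    orpham_percent: float  # 1 decimal


def summary_from_counts(
    total_genes: int, n_phams: int, n_orphams: int, largest_size: int = 0
) -> PhamSummaryStats:
    """Derive the summary statistics from plain counts."""
    if n_phams <= 0:
        raise ValueError("at least one pham is required")
    return PhamSummaryStats(
        n_phams=n_phams,
        total_genes=total_genes,
        mean_size=round(total_genes / n_phams, 2),
        largest_size=largest_size,
        n_orphams=n_orphams,
        orpham_percent=round(100.0 * n_orphams / n_phams, 1),
    )


def summarize(phams: list[Pham]) -> PhamSummaryStats:
    """Pham count, total genes, mean size, largest pham, orpham share."""
    if not phams:
        raise ValueError("empty pham list")
    sizes = [len(p.members) for p in phams]
    return summary_from_counts(
        total_genes=sum(sizes),
        n_phams=len(phams),
        n_orphams=sum(1 for s in sizes if s == 1),
        largest_size=max(sizes),
    )


def _genome_of_gene(genomes: list[GenomeRecord]) -> dict[str, str]:
    return {
        gene.gene_id: genome.genome_id
        for genome in genomes
        for gene in genome.genes
    }


def presence_absence(
    phams: list[Pham],
    genomes: list[GenomeRecord],
    consensus: dict[int, tuple[str, float]] | None = None,
) -> PangenomeSummary:
    """Roary-style per-pham summary plus presence–absence matrix.

    ``consensus`` optionally maps pham_id to (consensus function,
    proportion); without it the Annotation column is left empty.  Cells of
    the matrix hold semicolon-joined gene ids or the empty string.
    """
    gene_to_genome = _genome_of_gene(genomes)
    genome_ids = [g.genome_id for g in genomes]
    n_genomes = len(genome_ids)
    rows = []
    categories: dict[int, str] = {}
    for pham in phams:
        cells: dict[str, list[str]] = {gid: [] for gid in genome_ids}
        for member in pham.members:
            genome_id = gene_to_genome.get(member)
            if genome_id is None:
                raise ConsistencyError(
                    f"gene {member!r} does not belong to any listed genome"
                )
            cells[genome_id].append(member)
        n_isolates = sum(1 for gid in genome_ids if cells[gid])
        n_sequences = len(pham.members)
        percent = 100.0 * n_isolates / n_genomes
        categories[pham.pham_id] = classify_conservation(percent)
        label = consensus.get(pham.pham_id, ("", 0.0))[0] if consensus else ""
        row = {
            "Gene": f"pham_{pham.pham_id}",
            "Annotation": label,
            "No. isolates": n_isolates,
            "No. sequences": n_sequences,
            "Avg sequences per isolate": round(n_sequences / n_isolates, 2),
            "Conservation": categories[pham.pham_id],
        }
        for gid in genome_ids:
            row[gid] = ";".join(cells[gid])
        rows.append(row)
    table = pd.DataFrame(rows)
    return PangenomeSummary(table=table, genome_ids=genome_ids, categories=categories)


def genome_pham_map(
    phams: list[Pham], genomes: list[GenomeRecord]
) -> pd.DataFrame:
    """One row per genome listing the distinct phams its genes fall into."""
    pham_of_gene = {
        member: pham.pham_id for pham in phams for member in pham.members
    }
    rows = []
    for genome in genomes:
        ids = sorted({pham_of_gene[g.gene_id] for g in genome.genes
                      if g.gene_id in pham_of_gene})
        rows.append({
            "genome": genome.genome_id,
            "phams": " ".join(str(i) for i in ids),
        })
    return pd.DataFrame(rows)


def write_presence_absence(summary: PangenomeSummary, path: str | Path) -> None:
    summary.table.to_csv(path, index=False, quoting=1)  # QUOTE_ALL, Roary-style


def write_genome_pham_map(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_summary(stats: PhamSummaryStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"phams\t{stats.n_phams}\n")
        fh.write(f"genes\t{stats.total_genes}\n")
        fh.write(f"mean_genes_per_pham\t{stats.mean_size:.2f}\n")
        fh.write(f"largest_pham\t{stats.largest_size}\n")
        fh.write(f"orphams\t{stats.n_orphams}\n")
        fh.write(f"orpham_percent\t{stats.orpham_percent:.1f}\n")
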