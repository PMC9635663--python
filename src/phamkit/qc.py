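"""Auditing assembled phams for false positives and false negatives.

A false positive is a gene sitting in a pham it does not belong to.  Two
alignment-based criteria flag it: the gene is shorter than 60% of the
longest pham member (its homology cannot be global in scope), or its best
within-pham global alignment scores below 0.5 half-bits per column — the
level at which an alignment is no better than one between unrelated genes.

A false negative is a gene missing from a pham it belongs to.  Each pham's
representative (the member with the highest average similarity to the
rest) is searched against the complete nonredundant gene set; any hit
passing E-value ≤ 0.001, query coverage ≥ 60% and query length ≥ 60% of
the subject length that is not already a member is reported.

Within-pham audits use global alignments; the representative search uses
local (BLASTP-like) alignments with Karlin–Altschul E-values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlignmentCache, compute_evalue
from .clustering import Pham, select_representative_seq
from .genome_io import NonRedundantSet, sequence_digest


@dataclass(frozen=True)
class QCThresholds:
    """Audit cut-offs; defaults are the workflow's standard values."""

    fp_length_fraction: float = 0.60
    fp_score_threshold: float = 0.5  # half-bits per column
    fn_evalue: float = 0.001
    fn_query_coverage: float = 0.60
    fn_length_fraction: float = 0.60


DEFAULT_QC_THRESHOLDS = QCThresholds()


@dataclass(frozen=True)
class QCFlag:
    """One flagged gene with the statistic that tripped the threshold."""

    pham_id: int
    gene_id: str
    flag_type: str  # "length", "score" or "false_negative"
    statistic: float
    threshold: float


@dataclass
class QCReport:
    """Aggregated audit outcome over a pham set."""

    false_positives: list[QCFlag] = field(default_factory=list)
    false_negatives: list[QCFlag] = field(default_factory=list)
    total_genes: int = 0

    @property
    def fp_rate(self) -> float:
        """Flagged genes divided by all clustered genes."""
        if self.total_genes == 0:
            return 0.0
        return len(self.false_positives) / self.total_genes

    @property
    def fn_count(self) -> int:
        return len(self.false_negatives)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["pham_id", "gene_id", "flag_type", "statistic", "threshold"])
            for flag in self.false_positives + self.false_negatives:
                writer.writerow(
                    [flag.pham_id, flag.gene_id, flag.flag_type,
                     f"{flag.statistic:.4g}", f"{flag.threshold:.4g}"]
                )


def find_false_positives(
    pham: Pham,
    thresholds: QCThresholds = DEFAULT_QC_THRESHOLDS,
    cache: AlignmentCache | None = None,
) -> list[QCFlag]:
    """Flag pham members failing the length or best-score criterion.

    Singletons cannot contain false positives and return an empty list.
    A member tripping both criteria is reported once, as "length".
    """
    if len(pham.members) < 2:
        return []
    cache = cache or AlignmentCache()
    longest = max(len(seq) for seq in pham.sequences.values())
    flags = []
    # Distinct sequences only; identical copies share their statistics.
    for member in pham.members:
        seq = pham.sequences[member]
        ratio = len(seq) / longest
        if ratio < thresholds.fp_length_fraction:
            flags.append(
                QCFlag(pham.pham_id, member, "length", ratio,
                       thresholds.fp_length_fraction)
            )
            continue
        best = max(
            cache.global_align(seq, pham.sequences[other]).normalized_score
            for other in pham.members
            if other != member
        )
        if best < thresholds.fp_score_threshold:
            flags.append(
                QCFlag(pham.pham_id, member, "score", best,
                       thresholds.fp_score_threshold)
            )
    return flags


def select_representative(
    pham: Pham, cache: AlignmentCache | None = None
) -> str:
    """Pham member with the highest average similarity to all others."""
    return select_representative_seq(pham.sequences, cache)


def find_false_negatives(
    phams: list[Pham],
    all_genes: NonRedundantSet,
    thresholds: QCThresholds = DEFAULT_QC_THRESHOLDS,
    cache: AlignmentCache | None = None,
) -> list[QCFlag]:
    """Search each pham representative against the full nonredundant set.

    Hits passing the E-value, query-coverage and length criteria whose
    genes are outside the pham are that pham's false negatives.  Results
    are expanded to all redundant gene copies.
    """
    cache = cache or AlignmentCache()
    db_size = all_genes.total_residues
    flags = []
    for pham in phams:
        rep_seq = pham.sequences[pham.representative]
        member_set = set(pham.members)
        for digest in all_genes.digests():
            subject = all_genes.sequence(digest)
            gene_ids = [g for g in all_genes.gene_ids(digest) if g not in member_set]
            if not gene_ids:
                continue
            if len(rep_seq) < thresholds.fn_length_fraction * len(subject):
                continue
            hit = cache.local_align(rep_seq, subject)
            if hit.coverage_query < thresholds.fn_query_coverage:
                continue
            ev = compute_evalue(
                hit.raw_score, len(rep_seq), len(subject), db_size, cache.scheme
            )
            if ev > thresholds.fn_evalue:
                continue
            for gene_id in gene_ids:
                flags.append(
                    QCFlag(pham.pham_id, gene_id, "false_negative", ev,
                           thresholds.fn_evalue)
                )
    return flags


def audit(
    phams: list[Pham],
    thresholds: QCThresholds = DEFAULT_QC_THRESHOLDS,
    cache: AlignmentCache | None = None,
) -> QCReport:
    """Run both detectors over a pham set that partitions the gene set."""
    cache = cache or AlignmentCache()
    report = QCReport(total_genes=sum(len(p.members) for p in phams))
    for pham in phams:
        report.false_positives.extend(find_false_positives(pham, thresholds, cache))
    # The phams partition the complete dataset, so the union of their
    # member sequences is the search database.
    nr = NonRedundantSet()
    for pham in phams:
        for member in pham.members:
            seq = pham.sequences[member]
            digest = sequence_digest(seq)
            if digest in nr.entries:
                nr.entries[digest][1].append(member)
            else:
                nr.entries[digest] = (seq, [member])
    report.false_negatives = find_false_negatives(phams, nr, thresholds, cache)
    return report
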