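"""Consensus functional annotation per pham, with synonym normalization.

Free-text gene annotations are notoriously inconsistent ("terminase, large
subunit", "TerL" and "large terminase" all name the same protein), so raw
labels are normalized — lower-cased, whitespace-collapsed, and mapped
through a user-extensible synonym rule file — before the modal label is
taken as the pham's consensus function.

Empty and placeholder labels become "hypothetical protein".  That label
competes for the consensus like any other but loses ties to any specific
function.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .clustering import Pham

HYPOTHETICAL = "hypothetical protein"

_WHITESPACE = re.compile(r"\s+")


@dataclass
class SynonymMap:
    """Ordered (pattern, canonical) rules; the first full match wins.

    Applying the map twice equals applying it once: every canonical label
    is a fixed point of its own rules.
    """

    rules: list[tuple[re.Pattern, str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymMap":
        rules = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].lstrip().startswith("#") or len(row) < 2:
                    continue
                rules.append((re.compile(row[0].strip(), re.IGNORECASE), row[1].strip()))
        return cls(rules=rules)

    @classmethod
    def default(cls) -> "SynonymMap":
        ref = resources.files("phamkit").joinpath("data/synonyms.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def canonicalize(self, normalized: str) -> str:
        for pattern, canonical in self.rules:
            if pattern.fullmatch(normalized):
                return canonical
        return normalized


def normalize_label(raw: str, synonyms: SynonymMap | None = None) -> str:
    """Canonical form of a raw annotation label."""
    label = _WHITESPACE.sub(" ", raw.strip().lower()).strip(" .;,")
    if label in ("", "-", "none", "n/a", "na"):
        return HYPOTHETICAL
    if synonyms is None:
        synonyms = SynonymMap.default()
    return synonyms.canonicalize(label)


def consensus_function(
    pham_or_labels: Pham | list[str],
    synonyms: SynonymMap | None = None,
) -> tuple[str, float]:
    """Modal normalized label and its share of members, in percent.

    Ties prefer any specific label over "hypothetical protein", then the
    lexicographically smallest label.
    """
    if isinstance(pham_or_labels, Pham):
        labels = [pham_or_labels.annotations.get(m, "") for m in pham_or_labels.members]
    else:
        labels = list(pham_or_labels)
    if not labels:
        raise ValueError("cannot take the consensus of an empty pham")
    if synonyms is None:
        synonyms = SynonymMap.default()
    counts: dict[str, int] = {}
    for raw in labels:
        label = normalize_label(raw, synonyms)
        counts[label] = counts.get(label, 0) + 1
    best = min(
        counts.items(),
        key=lambda kv: (-kv[1], kv[0] == HYPOTHETICAL, kv[0]),
    )
    return best[0], round(100.0 * best[1] / len(labels), 1)


def consensus_table(
    phams: list[Pham], synonyms: SynonymMap | None = None
) -> list[dict]:
    """Consensus report rows: pham_id, n_genes, function, proportion."""
    synonyms = synonyms or SynonymMap.default()
    rows = []
    for pham in phams:
        label, proportion = consensus_function(pham, synonyms)
        rows.append({
            "pham_id": pham.pham_id,
            "n_genes": len(pham.members),
            "consensus_function": label,
            "consensus_proportion": proportion,
        })
    return rows


def write_consensus_csv(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["pham_id", "n_genes", "consensus_function",
                            "consensus_proportion"]
        )
        writer.writeheader()
        writer.writerows(rows)
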