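"""Position-specific scoring profiles for remote-homolog detection.

A pham's members are stacked into a center-star multiple sequence alignment
around the pham representative, and each alignment column is converted into
log-odds scores over the 20 standard residues:

    s(a) = 2 * log2( (f_a + beta * p_a) / ((1 + beta) * p_a) )

with observed column frequency ``f_a``, pseudocount weight ``beta`` = 1 and
BLOSUM62 background frequencies ``p_a``.  Scores are in half-bits, the same
units as BLOSUM62, so profile–sequence alignments are directly comparable
with sequence–sequence alignments and share the Karlin–Altschul E-value
parameters.

A profile built from a single distinct sequence degenerates to that
sequence's BLOSUM62 substitution-score rows, which makes the single-member
profile search equivalent to an ordinary sequence–sequence search.

Profile–sequence alignment is a local (Smith–Waterman) affine-gap dynamic
program; no general-purpose library exposes PSSM-vs-sequence alignment
under this scoring, so the recurrence is implemented here directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import (
    AMINO_ACIDS,
    BACKGROUND_FREQUENCIES,
    DEFAULT_SCHEME,
    ScoringScheme,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_BACKGROUND = np.array([BACKGROUND_FREQUENCIES[aa] for aa in AMINO_ACIDS])
_PSEUDOCOUNT_BETA = 1.0


def center_star_msa(
    center: str,
    others: list[str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[str]:
    """Merge pairwise center↔member global alignments into one rectangular MSA.

    Returns rows in order (center, *others).  Deterministic: merging uses
    the optimal pairwise alignments as produced, with insertions left-packed.
    """
    from .alignment import _make_aligner

    n = len(center)
    if not others:
        return [center]
    aligner = _make_aligner(scheme, "global")
    # Per member: residue aligned to each center position ('-' if deletion),
    # plus insertions keyed by the slot before each center position
    # (slot i = between center residues i-1 and i; slot n = after the end).
    aligned_chars: list[list[str]] = []
    inserts: list[dict[int, str]] = []
    max_insert = [0] * (n + 1)
    for other in others:
        aln = aligner.align(center, other)[0]
        row_c, row_o = aln[0], aln[1]
        chars = []
        member_inserts: dict[int, str] = {}
        pos = 0
        for cc, oc in zip(row_c, row_o):
            if cc == "-":
                member_inserts[pos] = member_inserts.get(pos, "") + oc
            else:
                chars.append(oc)
                pos += 1
        aligned_chars.append(chars)
        inserts.append(member_inserts)
        for slot, ins in member_inserts.items():
            max_insert[slot] = max(max_insert[slot], len(ins))

    def build_row(chars: list[str], member_inserts: dict[int, str]) -> str:
        parts = []
        for slot in range(n + 1):
            ins = member_inserts.get(slot, "")
            parts.append(ins.ljust(max_insert[slot], "-"))
            if slot < n:
                parts.append(chars[slot])
        return "".join(parts)

    rows = [build_row(list(center), {})]
    for chars, member_inserts in zip(aligned_chars, inserts):
        rows.append(build_row(chars, member_inserts))
    return rows


@dataclass
class ProfileMatrix:
    """Per-column half-bit scores over the 20 standard residues.

    ``consensus`` carries the modal residue of each column and is used for
    identity bookkeeping in profile–sequence alignments.
    """

    columns: np.ndarray  # shape (n_cols, 20)
    consensus: str
    source_pham: int = -1
    gap_open: int = DEFAULT_SCHEME.gap_open
    gap_extend: int = DEFAULT_SCHEME.gap_extend

    @property
    def n_cols(self) -> int:
        return self.columns.shape[0]


def build_profile(
    msa: list[str],
    source_pham: int = -1,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ProfileMatrix:
    """Build a :class:`ProfileMatrix` from a rectangular MSA."""
    if not msa:
        raise ValueError("empty MSA")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged MSA")
    if width == 0:
        raise ValueError("zero-width MSA")

    distinct = {row for row in msa}
    if len(distinct) == 1:
        seq = msa[0].replace("-", "")
        cols = np.zeros((len(seq), 20))
        for i, res in enumerate(seq):
            if res in _AA_INDEX:
                cols[i] = [scheme.score(res, aa) for aa in AMINO_ACIDS]
        return ProfileMatrix(
            columns=cols, consensus=seq, source_pham=source_pham,
            gap_open=scheme.gap_open, gap_extend=scheme.gap_extend,
        )

    cols = np.zeros((width, 20))
    consensus = []
    for i in range(width):
        counts = np.zeros(20)
        for row in msa:
            idx = _AA_INDEX.get(row[i])
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        if total == 0:
            consensus.append("X")
            continue
        freqs = counts / total
        cols[i] = 2.0 * np.log2(
            (freqs + _PSEUDOCOUNT_BETA * _BACKGROUND)
            / ((1.0 + _PSEUDOCOUNT_BETA) * _BACKGROUND)
        )
        consensus.append(AMINO_ACIDS[int(np.argmax(counts))])
    return ProfileMatrix(
        columns=cols, consensus="".join(consensus), source_pham=source_pham,
        gap_open=scheme.gap_open, gap_extend=scheme.gap_extend,
    )


@dataclass(frozen=True)
class ProfileAlignment:
    """Local profile–sequence alignment statistics."""

    raw_score: float
    alignment_length: int
    identity: float
    coverage_profile: float
    coverage_sequence: float
    evalue: float = math.inf

    @property
    def normalized_score(self) -> float:
        return self.raw_score / self.alignment_length


def profile_local_align(profile: ProfileMatrix, seq: str) -> ProfileAlignment:
    """Smith–Waterman alignment of a profile against one protein sequence.

    Affine gaps use the profile's gap penalties (open applied to the first
    gap residue, extend to each additional one), matching the pairwise
    aligner's convention.
    """
    if not seq:
        raise ValueError("cannot align an empty sequence")
    L, m = profile.n_cols, len(seq)
    seq_idx = np.array([_AA_INDEX.get(c, -1) for c in seq])
    # Substitution score of profile column i against sequence position j.
    sub = np.zeros((L, m))
    valid = seq_idx >= 0
    sub[:, valid] = profile.columns[:, seq_idx[valid]]

    open_, ext = float(profile.gap_open), float(profile.gap_extend)
    NEG = -1e30
    H = np.zeros((L + 1, m + 1))
    E = np.full((L + 1, m + 1), NEG)  # gap in profile (consumes sequence)
    F = np.full((L + 1, m + 1), NEG)  # gap in sequence (consumes profile)
    for i in range(1, L + 1):
        e_prev = NEG
        h_row = H[i]
        h_up = H[i - 1]
        F[i, 1:] = np.maximum(h_up[1:] + open_, F[i - 1, 1:] + ext)
        diag = h_up[:-1] + sub[i - 1]
        for j in range(1, m + 1):
            e_prev = max(h_row[j - 1] + open_, e_prev + ext)
            E[i, j] = e_prev
            h_row[j] = max(0.0, diag[j - 1], e_prev, F[i, j])
    best = float(H.max())
    if best <= 0.0:
        return ProfileAlignment(
            raw_score=0.0, alignment_length=1, identity=0.0,
            coverage_profile=0.0, coverage_sequence=0.0,
        )
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    # Traceback from the best cell to the start of the local alignment.
    end_i, end_j = i, j
    n_cols = ident = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            # diagonal match state
            n_cols += 1
            if seq[j - 1] == profile.consensus[i - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif state == "E":
            n_cols += 1
            if E[i, j] == H[i, j - 1] + open_:
                state = "H"
            j -= 1
        else:  # F
            n_cols += 1
            if F[i, j] == H[i - 1, j] + open_:
                state = "H"
            i -= 1
    start_i, start_j = i, j
    n_cols = max(n_cols, 1)
    return ProfileAlignment(
        raw_score=best,
        alignment_length=n_cols,
        identity=ident / n_cols,
        coverage_profile=(end_i - start_i) / L,
        coverage_sequence=(end_j - start_j) / m,
    )
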