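"""Pairwise protein alignment with BLOSUM62 and affine gaps.

Global (Needleman–Wunsch) and local (Smith–Waterman) alignments are computed
with Biopython's ``PairwiseAligner`` under the BLOSUM62 matrix with gap open
−11 and gap extension −1 (BLAST convention: the first gap residue costs 11,
each additional residue 1).  BLOSUM62 entries are half-bit log-odds scores,
so the length-normalized score — raw score divided by alignment columns — is
directly in half-bits per column.

E-values follow the Karlin–Altschul form E = K·m·n·exp(−λS) with the
published gapped BLOSUM62(11,1) constants λ = 0.267, K = 0.041, where m is
the query length and n the total residue count of the searched set.

All statistics share one denominator: the number of alignment columns,
counting gap columns.  Identity counts identical residue pairs, similarity
counts residue pairs with a positive substitution score, and the gap
fraction counts columns with a gap in either row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import sequence_digest

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Gapped Karlin–Altschul parameters for BLOSUM62 with gap costs 11/1.
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

#: BLOSUM62 background residue frequencies (Henikoff & Henikoff marginals).
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap penalties.

    ``gap_open`` is the cost of the first residue of a gap and
    ``gap_extend`` the cost of each additional residue.
    """

    gap_open: int = -11
    gap_extend: int = -1
    karlin_lambda: float = KARLIN_LAMBDA
    karlin_k: float = KARLIN_K

    @property
    def matrix(self):
        return _BLOSUM62

    def score(self, a: str, b: str) -> float:
        return float(_BLOSUM62[a, b])


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """Statistics of one pairwise alignment.

    ``raw_score`` is in half-bits (BLOSUM62 units); ``normalized_score`` is
    raw_score / alignment_length, i.e. half-bits per column.  Coverages are
    the aligned span of each sequence divided by its full length; a global
    alignment has coverage 1 on both sides by construction.
    """

    raw_score: float
    alignment_length: int
    identity: float
    similarity: float
    gap_fraction: float
    coverage_query: float
    coverage_target: float
    evalue: float = math.inf

    @property
    def normalized_score(self) -> float:
        return self.raw_score / self.alignment_length


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    aligner.mode = mode
    return aligner


def _column_stats(row_a: str, row_b: str, scheme: ScoringScheme):
    """Identity / similarity / gap counts over paired gapped rows."""
    n_cols = len(row_a)
    ident = simil = gaps = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            ident += 1
        if scheme.score(ca, cb) > 0:
            simil += 1
    return n_cols, ident, simil, gaps


def _result_from_alignment(
    aln, len_a: int, len_b: int, scheme: ScoringScheme, local: bool
) -> AlignmentResult:
    row_a, row_b = aln[0], aln[1]
    n_cols, ident, simil, gaps = _column_stats(row_a, row_b, scheme)
    if n_cols == 0:
        # Degenerate local alignment with no positive-scoring pair.
        return AlignmentResult(
            raw_score=0.0, alignment_length=1, identity=0.0, similarity=0.0,
            gap_fraction=0.0, coverage_query=0.0, coverage_target=0.0,
        )
    if local:
        seg_a, seg_b = aln.aligned
        span_a = int(seg_a[-1][1] - seg_a[0][0])
        span_b = int(seg_b[-1][1] - seg_b[0][0])
        cov_a, cov_b = span_a / len_a, span_b / len_b
    else:
        cov_a = cov_b = 1.0
    return AlignmentResult(
        raw_score=float(aln.score),
        alignment_length=n_cols,
        identity=ident / n_cols,
        similarity=simil / n_cols,
        gap_fraction=gaps / n_cols,
        coverage_query=cov_a,
        coverage_target=cov_b,
    )


def global_align(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Optimal Needleman–Wunsch global alignment of two proteins."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _make_aligner(scheme, "global").align(a, b)[0]
    return _result_from_alignment(aln, len(a), len(b), scheme, local=False)


def local_align(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of two proteins."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alns = _make_aligner(scheme, "local").align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return AlignmentResult(
            raw_score=0.0, alignment_length=1, identity=0.0, similarity=0.0,
            gap_fraction=0.0, coverage_query=0.0, coverage_target=0.0,
        )
    return _result_from_alignment(alns[0], len(a), len(b), scheme, local=True)


def compute_evalue(
    raw_score: float,
    len_a: int,
    len_b: int,
    db_size: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Karlin–Altschul E-value for a raw half-bit score.

    ``db_size`` is the total residue count of the searched sequence set
    (it already includes the target, so ``len_b`` only enters validation).
    """
    if len_a <= 0 or len_b <= 0 or db_size <= 0:
        raise ValueError("sequence and database lengths must be positive")
    return scheme.karlin_k * len_a * db_size * math.exp(
        -scheme.karlin_lambda * max(raw_score, 0.0)
    )


def with_evalue(
    result: AlignmentResult, len_a: int, len_b: int, db_size: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentResult:
    """Return a copy of ``result`` carrying its E-value against ``db_size``."""
    ev = compute_evalue(result.raw_score, len_a, len_b, db_size, scheme)
    return AlignmentResult(
        raw_score=result.raw_score,
        alignment_length=result.alignment_length,
        identity=result.identity,
        similarity=result.similarity,
        gap_fraction=result.gap_fraction,
        coverage_query=result.coverage_query,
        coverage_target=result.coverage_target,
        evalue=ev,
    )


@dataclass
class AlignmentCache:
    """Memoized pairwise aligner, symmetric in pair order.

    Keys are unordered pairs of sequence digests, so two genes with
    identical sequences share cache entries with their duplicates.
    ``n_computed`` counts actual alignment runs (for cache-hit accounting).
    """

    scheme: ScoringScheme = DEFAULT_SCHEME
    _store: dict = field(default_factory=dict)
    n_computed: int = 0

    def _key(self, a: str, b: str, mode: str):
        da, db = sequence_digest(a), sequence_digest(b)
        return (mode, frozenset((da, db)))

    def _get(self, a: str, b: str, mode: str, fn) -> AlignmentResult:
        key = self._key(a, b, mode)
        if key not in self._store:
            self.n_computed += 1
            # Canonical orientation keeps the cached statistics identical
            # regardless of request order (scores are symmetric anyway).
            first, second = sorted((a, b))
            self._store[key] = fn(first, second, self.scheme)
        result = self._store[key]
        if a > b:
            # Swap coverages back into the caller's query/target orientation.
            result = AlignmentResult(
                raw_score=result.raw_score,
                alignment_length=result.alignment_length,
                identity=result.identity,
                similarity=result.similarity,
                gap_fraction=result.gap_fraction,
                coverage_query=result.coverage_target,
                coverage_target=result.coverage_query,
                evalue=result.evalue,
            )
        return result

    def global_align(self, a: str, b: str) -> AlignmentResult:
        return self._get(a, b, "global", global_align)

    def local_align(self, a: str, b: str) -> AlignmentResult:
        return self._get(a, b, "local", local_align)

    def clear(self) -> None:
        self._store.clear()
        self.n_computed = 0
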