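"""Global (Needleman–Wunsch) and local (Smith–Waterman) pairwise alignment.

Scoring defaults to BLOSUM62 with affine gaps: the first residue of a gap
costs ``gap_open`` and every further residue ``gap_extend`` (a gap of length
L scores ``-(gap_open + (L-1)*gap_extend)``).  End gaps are penalized in
global mode.  Identity and positive fractions use the full alignment length
(gap columns included) as denominator; a column is *positive* when both
residues are present and their substitution score is > 0.

The ``selfalign`` statistic normalizes the global score of a pair by each
sequence's self-alignment score and averages the two ratios:

    selfalign(a, b) = ( S(a,b)/S(a,a) + S(a,b)/S(b,b) ) / 2

with S the raw global alignment score.  For identical sequences it is 1; the
value is clamped to [0, 1] (unrelated sequences can score negatively under
affine gap penalties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringConfig:
    """Substitution matrix and affine gap penalties (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def substitution_matrix(self):
        return _load_matrix(self.matrix)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    raw_score: float
    identity: float
    positive: float
    mode: str  # "global" | "local"


def _make_aligner(params: ScoringConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = params.substitution_matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _column_stats(aligned_a: str, aligned_b: str, params: ScoringConfig) -> tuple[float, float]:
    """(identity, positive) fractions over all alignment columns."""
    n = len(aligned_a)
    if n == 0:
        return 0.0, 0.0
    matrix = params.substitution_matrix()
    ident = pos = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if matrix[x, y] > 0:
            pos += 1
    return ident / n, pos / n


def _check_inputs(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("alignment requires two non-empty sequences")


def _align(a: str, b: str, params: ScoringConfig, mode: str) -> AlignmentResult:
    # Canonicalize the argument order before traceback so co-optimal
    # alignments are resolved identically for (a, b) and (b, a); the score
    # is symmetric regardless.
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aligner = _make_aligner(params, mode)
    if mode == "local":
        score = float(aligner.score(x, y))
        if score <= 0:
            return AlignmentResult("", "", 0.0, 0.0, 0.0, "local")
    alignment = aligner.align(x, y)[0]
    aligned_x, aligned_y = alignment[0], alignment[1]
    if swapped:
        aligned_x, aligned_y = aligned_y, aligned_x
    identity, positive = _column_stats(aligned_x, aligned_y, params)
    return AlignmentResult(aligned_x, aligned_y, float(alignment.score),
                           identity, positive, mode)


def global_align(a: str, b: str, params: ScoringConfig = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal global alignment of two residue strings.

    Ties between co-optimal tracebacks are broken deterministically and
    symmetrically in the input order (the score is unique in any case).
    """
    _check_inputs(a, b)
    return _align(a, b, params, "global")


def local_align(a: str, b: str, params: ScoringConfig = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal local alignment; score floored at 0, empty alignment if no
    positive-scoring subpath exists."""
    _check_inputs(a, b)
    return _align(a, b, params, "local")


def global_score(a: str, b: str, params: ScoringConfig = DEFAULT_SCORING) -> float:
    """Raw global alignment score (no traceback; faster than global_align)."""
    _check_inputs(a, b)
    return float(_make_aligner(params, "global").score(a, b))


def selfalign(a: str, b: str, params: ScoringConfig = DEFAULT_SCORING) -> float:
    """Self-normalized global alignment similarity in [0, 1]."""
    _check_inputs(a, b)
    s_aa = global_score(a, a, params)
    s_bb = global_score(b, b, params)
    if s_aa <= 0 or s_bb <= 0:
        raise ValueError(
            "selfalign undefined: non-positive self-alignment score "
            f"(S(a,a)={s_aa}, S(b,b)={s_bb})"
        )
    s_ab = global_score(a, b, params)
    value = 0.5 * (s_ab / s_aa + s_ab / s_bb)
    return min(1.0, max(0.0, value))
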