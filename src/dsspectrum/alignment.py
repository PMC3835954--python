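"""Pairwise global alignment of the trigger dsRNA against each ortholog.

The specificity metrics (SNP counts, percent identity, shared k-mer windows)
are all defined on a gapped pairwise alignment of the 240-nt trigger region
against the corresponding ortholog region. Orthologs of the same coding
region are typically gap-free at this length, so default scoring strongly
discourages gaps; pre-aligned (gapped FASTA) input is also accepted with its
columns taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .seq_io import GappedRecord, SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring: a gap of length g costs gap_open + (g-1)*gap_extend.

    Defaults (match +1, mismatch -1, open -5, extend -2) strongly discourage
    gaps, matching the gap-free same-length ortholog comparisons this screen
    is built for.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self):
        if self.match_score <= self.mismatch_score:
            raise ValidationError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("gap penalties must be non-positive")


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows: trigger (row_a) over ortholog (row_b)."""

    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValidationError("aligned rows differ in length")
        if not self.row_a:
            raise ValidationError("empty alignment")
        for i, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == GAP and y == GAP:
                raise ValidationError(f"column {i + 1} is gap in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def ungapped_a(self) -> str:
        return self.row_a.replace(GAP, "")

    def ungapped_b(self) -> str:
        return self.row_b.replace(GAP, "")


def _matrix(params: AlignmentParams):
    # N is scored as a mismatch against everything, including N: ambiguous
    # residues never reward the alignment, conservative for a specificity screen.
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            mat[x, y] = (
                params.match_score
                if (x == y and x != "N")
                else params.mismatch_score
            )
    return mat


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    params: AlignmentParams | None = None,
) -> AlignedPair:
    """Optimal Needleman–Wunsch global alignment with affine gap penalties.

    Deterministic: of the optimal alignments the first in the aligner's
    traceback order is returned, so identical inputs always give identical
    output.
    """
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(params)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    row_a, row_b = str(best[0]), str(best[1])
    return AlignedPair(row_a=row_a, row_b=row_b)


def alignment_score(pair: AlignedPair, params: AlignmentParams | None = None) -> float:
    """Score an existing alignment under the affine-gap scheme.

    Used to verify that global_align's reported optimum is attained by the
    alignment it returns.
    """
    params = params or AlignmentParams()
    score = 0.0
    for row in (pair.row_a, pair.row_b):
        in_gap = False
        for ch in row:
            if ch == GAP:
                score += params.gap_extend if in_gap else params.gap_open
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(pair.row_a, pair.row_b):
        if GAP in (x, y):
            continue
        score += (
            params.match_score if (x == y and x != "N") else params.mismatch_score
        )
    return score


def pair_from_gapped(a: GappedRecord, b: GappedRecord) -> AlignedPair:
    """Build an AlignedPair from two rows of a pre-aligned FASTA."""
    return AlignedPair(row_a=a.row, row_b=b.row)


def _is_identity_column(x: str, y: str) -> bool:
    return x == y and x != GAP and x != "N"


def count_snps(pair: AlignedPair) -> int:
    """Number of substitution columns: both rows non-gap, residues differ.

    A column containing N counts as differing; gap columns are excluded
    (they are indels, not SNPs).
    """
    n = 0
    for x, y in zip(pair.row_a, pair.row_b):
        if x != GAP and y != GAP and not _is_identity_column(x, y):
            n += 1
    return n


def gap_columns(pair: AlignedPair) -> int:
    """Number of columns with a gap in either row."""
    return sum(1 for x, y in zip(pair.row_a, pair.row_b) if GAP in (x, y))


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (98.75 -> 98.8), as printed in reports."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_identity(pair: AlignedPair, rounded: bool = True) -> float:
    """Percent identity over the full alignment length.

    100 x (identical non-gap columns) / (alignment columns); gap and N
    columns count in the denominator and as non-identical. Reported values
    are rounded half-up to one decimal; pass ``rounded=False`` for the exact
    value (used for distance matrices).
    """
    ident = sum(
        1 for x, y in zip(pair.row_a, pair.row_b) if _is_identity_column(x, y)
    )
    pid = 100.0 * ident / pair.n_columns
    return round_half_up(pid, 1) if rounded else pid
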