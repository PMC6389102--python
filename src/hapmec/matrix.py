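"""Core data types for SNP-fragment matrices and the MEC objective.

A diploid individual carries two haplotypes, coded as binary strings over
the heterozygous SNP sites (0 = major allele, 1 = minor allele).  Sequencing
reads observe short stretches of one of the two haplotypes, with errors; a
read is a ternary string over ``{0, 1, -}`` where ``-`` is a gap (a site the
read does not cover, or missing data between two covered segments).  The
haplotype assembly problem asks for a pair ``(h, h')`` of binary strings
minimising the *MEC score*

    sum over reads r of  min{ d(h, r), d(h', r) }

where ``d`` counts positions at which both characters are alleles (not gaps)
and disagree.  This module provides the matrix container, the distance, the
MEC score, and the read-to-haplotype alignment rule; everything downstream
(reductions, ILP models, the brute-force oracle) is built on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

GAP = "-"
#: Characters a matrix row may contain.  Unicode minus (as printed in some
#: documents) is normalised to the ASCII hyphen on input.
ALLELES = ("0", "1")

# het_status values per column
ASSUMED_HET = "assumed_het"
INTRINSIC_HET = "intrinsic_het"
UNKNOWN = "unknown"

_GAP_ALIASES = {"-", "−", "–"}


class MatrixFormatError(ValueError):
    """Raised for structurally invalid fragment matrices or files."""


def _normalise_row(row: str) -> str:
    out = []
    for ch in row:
        if ch in _GAP_ALIASES:
            out.append(GAP)
        elif ch in ("0", "1"):
            out.append(ch)
        else:
            raise MatrixFormatError(f"illegal character {ch!r} in row {row!r}")
    return "".join(out)


@dataclass
class ReadMatrix:
    """A weighted SNP-fragment matrix over ``{0, 1, -}``.

    Rows carry integer multiplicities ``row_weights`` (w_i) and columns carry
    ``col_weights`` (c_j); both default to 1 and become larger when identical
    rows or identical/complementary columns are merged during reduction.

    Bookkeeping fields let reduced matrices be traced back to the matrix they
    came from:

    ``row_ids``
        original row index of each current row (representative row after a
        row merge).
    ``col_ids``
        original column index of each current column.  A duplicated block
        boundary column appears in two reduced blocks with the same id.
    ``col_origin``
        current column index -> tuple of ``(original column id, flipped)``
        pairs it represents; ``flipped`` records that the member column was
        merged in complemented orientation.
    ``het_status``
        per current column, one of :data:`ASSUMED_HET` (all-heterozygous
        mode), :data:`INTRINSIC_HET` (supplied by the user in general mode)
        or :data:`UNKNOWN`.
    """

    rows: List[str]
    num_columns: int
    row_weights: List[int] = field(default_factory=list)
    col_weights: List[int] = field(default_factory=list)
    row_ids: List[int] = field(default_factory=list)
    col_ids: List[int] = field(default_factory=list)
    col_origin: Dict[int, Tuple[Tuple[int, bool], ...]] = field(default_factory=dict)
    het_status: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = [_normalise_row(r) for r in self.rows]
        m = self.num_columns
        for idx, row in enumerate(self.rows):
            if len(row) != m:
                raise MatrixFormatError(
                    f"row {idx} has length {len(row)}, expected {m}"
                )
            if all(ch == GAP for ch in row):
                raise MatrixFormatError(f"row {idx} contains no allele (all gaps)")
        if not self.row_weights:
            self.row_weights = [1] * len(self.rows)
        if not self.col_weights:
            self.col_weights = [1] * m
        if not self.row_ids:
            self.row_ids = list(range(len(self.rows)))
        if not self.col_ids:
            self.col_ids = list(range(m))
        if not self.col_origin:
            self.col_origin = {j: ((self.col_ids[j], False),) for j in range(m)}
        if not self.het_status:
            self.het_status = [UNKNOWN] * m
        if len(self.row_weights) != len(self.rows):
            raise MatrixFormatError("row_weights length mismatch")
        if len(self.col_weights) != m or len(self.het_status) != m:
            raise MatrixFormatError("per-column metadata length mismatch")
        if any(w < 1 for w in self.row_weights) or any(c < 1 for c in self.col_weights):
            raise MatrixFormatError("multiplicities must be >= 1")

    # -- basic accessors ---------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Sequence[str], row_weights: Optional[Sequence[int]] = None) -> "ReadMatrix":
        rows = [_normalise_row(r) for r in rows]
        if not rows:
            raise MatrixFormatError("matrix needs at least one row")
        return cls(
            rows=list(rows),
            num_columns=len(rows[0]),
            row_weights=list(row_weights) if row_weights is not None else [],
        )

    @property
    def num_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def nonzero_entries(self) -> int:
        """Total number of non-gap entries (unweighted)."""
        return sum(len(r) - r.count(GAP) for r in self.rows)

    def row_start(self, i: int) -> int:
        """0-based column of the first allele in row i."""
        row = self.rows[i]
        for j, ch in enumerate(row):
            if ch != GAP:
                return j
        raise AssertionError("all-gap row")  # excluded by invariant

    def row_end(self, i: int) -> int:
        """0-based column of the last allele in row i."""
        row = self.rows[i]
        for j in range(len(row) - 1, -1, -1):
            if row[j] != GAP:
                return j
        raise AssertionError("all-gap row")


@dataclass
class HaplotypePair:
    """A candidate pair ``(h, h')`` of binary haplotype strings.

    ``zygosity`` flags each column ``"het"`` or ``"hom"``; when omitted it is
    derived by comparing the two strings.
    """

    h: str
    h_prime: str
    zygosity: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if len(self.h) != len(self.h_prime):
            raise ValueError("haplotypes must have equal length")
        for s in (self.h, self.h_prime):
            if any(ch not in ("0", "1") for ch in s):
                raise ValueError("haplotypes must be binary strings")
        if self.zygosity is None:
            self.zygosity = [
                "het" if a != b else "hom" for a, b in zip(self.h, self.h_prime)
            ]

    @classmethod
    def complementary(cls, h: str) -> "HaplotypePair":
        """All-heterozygous pair: h' is the bitwise complement of h."""
        return cls(h, complement(h))

    def swapped(self) -> "HaplotypePair":
        return HaplotypePair(self.h_prime, self.h, list(self.zygosity or []))

    def __len__(self) -> int:
        return len(self.h)


@dataclass
class Assignment:
    """Per-row alignment flags: True when the row is aligned to ``h``."""

    to_h: List[bool]


def complement(s: str) -> str:
    return s.translate(str.maketrans("01", "10"))


def mismatch_distance(s: str, t: str) -> int:
    """Number of positions where both characters are alleles and differ.

    Gap positions (in either string) never contribute.
    """
    if len(s) != len(t):
        raise MatrixFormatError(
            f"length mismatch: {len(s)} vs {len(t)}"
        )
    return sum(
        1
        for a, b in zip(s, t)
        if a != b and a in ("0", "1") and b in ("0", "1")
    )


def _weighted_distance(s: str, t: str, col_weights: Sequence[int]) -> int:
    return sum(
        w
        for a, b, w in zip(s, t, col_weights)
        if a != b and a in ("0", "1") and b in ("0", "1")
    )


def mec_score(matrix: ReadMatrix, pair: HaplotypePair) -> int:
    """Weighted MEC score of ``pair`` on ``matrix``.

    Each row contributes ``w_i * min(d(h, r), d(h', r))`` where the distance
    weights column ``j`` by its multiplicity ``c_j`` (both weights are 1 for
    unreduced matrices, in which case this is exactly the plain MEC score).
    """
    if len(pair) != matrix.num_columns:
        raise MatrixFormatError(
            f"haplotype length {len(pair)} != matrix columns {matrix.num_columns}"
        )
    cw = matrix.col_weights
    total = 0
    for row, w in zip(matrix.rows, matrix.row_weights):
        total += w * min(
            _weighted_distance(pair.h, row, cw),
            _weighted_distance(pair.h_prime, row, cw),
        )
    return total


def align_reads(matrix: ReadMatrix, pair: HaplotypePair) -> Assignment:
    """Assign every row to the nearer haplotype; ties go to ``h``."""
    if len(pair) != matrix.num_columns:
        raise MatrixFormatError(
            f"haplotype length {len(pair)} != matrix columns {matrix.num_columns}"
        )
    cw = matrix.col_weights
    flags = [
        _weighted_distance(pair.h, row, cw) <= _weighted_distance(pair.h_prime, row, cw)
        for row in matrix.rows
    ]
    return Assignment(to_h=flags)
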