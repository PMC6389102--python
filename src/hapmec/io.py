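"""Text formats and run statistics.

Three formats are handled, all plain text and all 1-based in file
coordinates (columns are 0-based everywhere in memory):

* the *native matrix* format — one read per line as a string over
  ``{0, 1, -}``, optionally followed by an integer multiplicity;
  ``#`` starts a comment line;
* the *fragment file* format used for interchange by haplotype-assembly
  tools — per line: a segment count, a read id, then (start position,
  allele string) pairs; a trailing quality string is accepted and ignored
  (the MEC score here is unweighted);
* the *phased blocks* output — per phase block a header
  ``BLOCK start=<col> span=<n> mec=<int>`` followed by one line per column
  ``<col> <h allele> <h' allele> <het|hom>``, and a trailing
  ``TOTAL_MEC=<int>`` line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import List, Optional, TextIO, Union

from .matrix import GAP, MatrixFormatError, ReadMatrix
from .reductions import PhasedResult

logger = logging.getLogger("hapmec")

STATS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# native matrix format
# ---------------------------------------------------------------------------


def read_native_matrix(path) -> ReadMatrix:
    """Read the one-row-per-line ternary matrix format."""
    rows: List[str] = []
    weights: List[int] = []
    width: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            token = parts[0]
            weight = 1
            if len(parts) == 2:
                try:
                    weight = int(parts[1])
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: weight {parts[1]!r} is not an integer"
                    )
                if weight < 1:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: weight must be positive"
                    )
            elif len(parts) > 2:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 'ROW [WEIGHT]', got {len(parts)} fields"
                )
            for col, ch in enumerate(token, start=1):
                if ch not in "01" and ch not in ("-", "−", "–"):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: illegal character {ch!r} at column {col}"
                    )
            if width is None:
                width = len(token)
            elif len(token) != width:
                raise MatrixFormatError(
                    f"{path}:{lineno}: row length {len(token)} != {width}"
                )
            if all(ch not in "01" for ch in token):
                raise MatrixFormatError(f"{path}:{lineno}: row contains no allele")
            rows.append(token)
            weights.append(weight)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    return ReadMatrix.from_rows(rows, row_weights=weights)


def write_native_matrix(matrix: ReadMatrix, path) -> None:
    with open(path, "w") as fh:
        for row, w in zip(matrix.rows, matrix.row_weights):
            fh.write(f"{row} {w}\n" if w != 1 else f"{row}\n")


# ---------------------------------------------------------------------------
# fragment file format
# ---------------------------------------------------------------------------


def read_fragment_file(path, num_columns: Optional[int] = None) -> ReadMatrix:
    """Read a fragment interchange file into a matrix.

    Line layout: ``<nseg> <read-id> <start1> <alleles1> ... [quality]``
    with 1-based, inclusive start positions.  ``num_columns`` is inferred
    as the maximum end position when not given.
    """
    parsed = []  # (lineno, [(start0, alleles), ...])
    max_end = 0
    saw_quality = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                nseg = int(parts[0])
            except (ValueError, IndexError):
                raise MatrixFormatError(
                    f"{path}:{lineno}: first field must be the segment count"
                )
            if nseg < 1:
                raise MatrixFormatError(f"{path}:{lineno}: segment count must be >= 1")
            expected = 2 + 2 * nseg
            if len(parts) == expected + 1:
                saw_quality = True  # trailing quality string, ignored
            elif len(parts) != expected:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {expected} fields for "
                    f"{nseg} segments, got {len(parts)}"
                )
            segs = []
            for k in range(nseg):
                start_tok, alleles = parts[2 + 2 * k], parts[3 + 2 * k]
                try:
                    start = int(start_tok)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: segment start {start_tok!r} not an integer"
                    )
                if start < 1:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: positions are 1-based; got {start}"
                    )
                if not alleles or any(ch not in "01" for ch in alleles):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: allele string {alleles!r} must be over {{0,1}}"
                    )
                segs.append((start - 1, alleles))
                max_end = max(max_end, start - 1 + len(alleles))
            # overlap check
            covered = set()
            for start0, alleles in segs:
                span = set(range(start0, start0 + len(alleles)))
                if covered & span:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: overlapping segments within one read"
                    )
                covered |= span
            parsed.append((lineno, segs))
    if not parsed:
        raise MatrixFormatError(f"{path}: no fragments")
    if num_columns is None:
        num_columns = max_end
    rows = []
    for lineno, segs in parsed:
        chars = [GAP] * num_columns
        for start0, alleles in segs:
            if start0 + len(alleles) > num_columns:
                raise MatrixFormatError(
                    f"{path}:{lineno}: segment at position {start0 + 1} "
                    f"exceeds {num_columns} columns"
                )
            for k, ch in enumerate(alleles):
                chars[start0 + k] = ch
        rows.append("".join(chars))
    if saw_quality:
        logger.info("quality strings present in %s were ignored (unweighted MEC)", path)
    return ReadMatrix.from_rows(rows)


# ---------------------------------------------------------------------------
# phased block output
# ---------------------------------------------------------------------------


def write_phased_blocks(result: PhasedResult, dest: Union[str, TextIO]) -> None:
    """Write the phased haplotypes block by block (1-based columns)."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        for cols, mec in zip(result.phase_blocks, result.block_mecs):
            start, end = cols[0], cols[-1]
            span = end - start + 1
            fh.write(f"BLOCK start={start + 1} span={span} mec={mec}\n")
            for j in range(start, end + 1):
                fh.write(
                    f"{j + 1} {result.h[j]} {result.h_prime[j]} {result.zygosity[j]}\n"
                )
        fh.write(f"TOTAL_MEC={result.total_mec}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# run statistics
# ---------------------------------------------------------------------------


@dataclass
class ReducedBlockStats:
    block_index: int
    index_in_block: int
    num_rows: int
    num_columns: int
    nonzero_entries: int
    formulation: str
    num_variables: int
    num_constraints: int
    status: str
    objective: int
    elapsed_seconds: float


@dataclass
class RunStats:
    """Per-reduced-block solve records plus totals.

    ``num_failed`` counts reduced blocks not solved to proven optimality
    within the time limit.
    """

    mode: str
    model: str
    blocks: List[ReducedBlockStats] = field(default_factory=list)
    total_mec: int = 0
    num_blocks: int = 0
    num_reduced_blocks: int = 0
    num_failed: int = 0
    schema_version: int = STATS_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
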