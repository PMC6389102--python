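"""MEC-preserving reductions of a fragment matrix and solution stitching.

Five reductions shrink the problem without changing the optimal MEC score:

1. *Monotone-column removal* — a column containing at most one of the two
   allele symbols can be called homozygous for the observed allele and
   dropped (no read disagrees with the call).
2. *Singleton-Removal* — a read covering a single site that is known to be
   heterozygous matches one of the two complementary alleles whatever the
   phasing, so it contributes 0 and can be dropped.
3. *Block split* — cutting between columns i and i+1 is safe when no read
   spans the cut; the matrix falls apart into independent blocks (set S of
   cut positions).
4. *Reduced-block split* — inside a block, a known-heterozygous column i at
   which every read either ends (end <= i) or starts (start >= i) can be
   duplicated, the block cut between the original and the copy (set T), and
   the two halves solved independently; the shared column pins the relative
   phase of the halves when stitching.
5. *Row/column merging* — identical rows, and identical-or-complementary
   columns, collapse into one carrier with an integer multiplicity.

Every reduction emits a :class:`ReductionTrace`; :func:`stitch` inverts the
whole chain, reconciling phases of adjacent reduced blocks at their shared
heterozygous columns and reinserting homozygous calls, to produce a
:class:`PhasedResult` over the original columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .matrix import (
    ASSUMED_HET,
    GAP,
    INTRINSIC_HET,
    Assignment,
    HaplotypePair,
    ReadMatrix,
    align_reads,
    complement,
    mec_score,
)


@dataclass
class ReductionTrace:
    """Invertible record of reduction steps.

    Only the fields touched by a given reduction are populated; the pipeline
    merges the traces of successive steps with :meth:`update`.
    """

    #: original column id -> homozygous allele call ("0"/"1")
    homozygous_calls: Dict[int, str] = field(default_factory=dict)
    #: (original row id, reason) for rows dropped; reason in
    #: {"empty", "singleton"}
    removed_rows: List[Tuple[int, str]] = field(default_factory=list)
    #: S: cut positions, as the original column id of the last column of
    #: each block except the final one
    block_cuts: List[int] = field(default_factory=list)
    #: per block index: original column ids of the shared (duplicated)
    #: heterozygous boundary columns (set T)
    reduced_block_boundaries: Dict[int, List[int]] = field(default_factory=dict)
    #: merged row index -> original row ids of the group
    row_merge_groups: List[List[int]] = field(default_factory=list)
    #: merged column index -> [(original column id, flipped), ...]
    col_merge_groups: List[List[Tuple[int, bool]]] = field(default_factory=list)
    #: shape of the matrix the trace chain started from
    original_num_rows: Optional[int] = None
    original_num_columns: Optional[int] = None
    #: the matrix the chain started from (used to report per-read alignment)
    original_matrix: Optional[ReadMatrix] = None

    def update(self, other: "ReductionTrace") -> None:
        self.homozygous_calls.update(other.homozygous_calls)
        self.removed_rows.extend(other.removed_rows)
        self.block_cuts.extend(other.block_cuts)
        for k, v in other.reduced_block_boundaries.items():
            self.reduced_block_boundaries.setdefault(k, []).extend(v)


@dataclass
class Block:
    """An independent sub-matrix obtained by cutting at the positions in S."""

    matrix: ReadMatrix
    index: int
    #: original column ids covered, in order
    col_span: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.col_span:
            self.col_span = list(self.matrix.col_ids)


@dataclass
class ReducedBlock:
    """A block segment obtained by duplicating shared heterozygous columns.

    ``matrix`` is ``None`` for a read-free segment (only possible when the
    function is applied standalone to a matrix that was not first cut at its
    S positions); column metadata is kept on the segment itself so stitching
    works either way.
    """

    matrix: Optional[ReadMatrix]
    block_index: int
    index_in_block: int
    #: original column ids covered by this segment, in order
    col_ids: List[int] = field(default_factory=list)
    #: current column -> ((original column id, flipped), ...)
    col_origin: Dict[int, Tuple[Tuple[int, bool], ...]] = field(default_factory=dict)
    het_status: List[str] = field(default_factory=list)
    #: True when the first/last column is a duplicated boundary shared with
    #: the neighbouring reduced block
    first_shared: bool = False
    last_shared: bool = False

    @property
    def num_columns(self) -> int:
        return len(self.col_ids)

    def refresh_from_matrix(self) -> None:
        """Re-sync column metadata after the matrix was merged/reduced."""
        if self.matrix is not None:
            self.col_ids = list(self.matrix.col_ids)
            self.col_origin = dict(self.matrix.col_origin)
            self.het_status = list(self.matrix.het_status)


@dataclass
class PhasedResult:
    """Full-length phasing reassembled from per-reduced-block solutions.

    ``h``/``h_prime`` cover every original column; the relative phase
    *between* different phase blocks is arbitrary (unlinked by any read), so
    ``phase_blocks`` lists, per block, the original column ids whose phasing
    is mutually consistent.  ``zygosity[j]`` is "hom" for monotone-column
    calls and for columns where the two haplotypes agree.
    """

    h: str
    h_prime: str
    zygosity: List[str]
    phase_blocks: List[List[int]]
    block_mecs: List[int]
    total_mec: int
    assignment: Optional[Assignment] = None
    solver_statuses: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual reductions
# ---------------------------------------------------------------------------


def force_heterozygous(matrix: ReadMatrix, columns: Iterable[int]) -> ReadMatrix:
    """Protect columns from monotone removal by adding one-site dummy reads.

    For each listed column missing one of the two alleles, a read covering
    only that column with the missing allele is appended, so the column is
    no longer monotone.  The dummy read is later deleted by
    Singleton-Removal and never changes the optimal MEC score.
    """
    rows = list(matrix.rows)
    weights = list(matrix.row_weights)
    ids = list(matrix.row_ids)
    next_id = (max(ids) + 1) if ids else 0
    m = matrix.num_columns
    for j in sorted(set(columns)):
        if not 0 <= j < m:
            raise ValueError(f"column {j} out of range 0..{m - 1}")
        col = "".join(r[j] for r in rows)
        for allele in ("0", "1"):
            if allele not in col:
                rows.append(GAP * j + allele + GAP * (m - j - 1))
                weights.append(1)
                ids.append(next_id)
                next_id += 1
    return ReadMatrix(
        rows=rows,
        num_columns=m,
        row_weights=weights,
        col_weights=list(matrix.col_weights),
        row_ids=ids,
        col_ids=list(matrix.col_ids),
        col_origin=dict(matrix.col_origin),
        het_status=list(matrix.het_status),
    )


def remove_monotone_columns(
    matrix: ReadMatrix,
) -> Tuple[Optional[ReadMatrix], ReductionTrace]:
    """Drop columns in which 0 or 1 never appears, recording homozygous calls.

    A column showing a single allele is called homozygous for that allele;
    an all-gap column receives the arbitrary call "0".  Rows left without
    any allele are removed and recorded.  Returns ``None`` as the matrix when
    nothing survives.
    """
    trace = ReductionTrace()
    keep: List[int] = []
    for j in range(matrix.num_columns):
        col = matrix.column(j)
        has0 = "0" in col
        has1 = "1" in col
        if has0 and has1:
            keep.append(j)
        else:
            call = "1" if has1 else "0"  # all-gap column -> arbitrary "0"
            trace.homozygous_calls[matrix.col_ids[j]] = call

    new_rows: List[str] = []
    new_w: List[int] = []
    new_ids: List[int] = []
    for i, row in enumerate(matrix.rows):
        sub = "".join(row[j] for j in keep)
        if sub and any(ch != GAP for ch in sub):
            new_rows.append(sub)
            new_w.append(matrix.row_weights[i])
            new_ids.append(matrix.row_ids[i])
        else:
            trace.removed_rows.append((matrix.row_ids[i], "empty"))

    if not keep or not new_rows:
        return None, trace
    reduced = ReadMatrix(
        rows=new_rows,
        num_columns=len(keep),
        row_weights=new_w,
        col_weights=[matrix.col_weights[j] for j in keep],
        row_ids=new_ids,
        col_ids=[matrix.col_ids[j] for j in keep],
        col_origin={k: matrix.col_origin[j] for k, j in enumerate(keep)},
        het_status=[matrix.het_status[j] for j in keep],
    )
    return reduced, trace


def remove_singleton_rows(
    matrix: ReadMatrix, het_columns: Set[int]
) -> Tuple[Optional[ReadMatrix], ReductionTrace]:
    """Drop reads whose single covered site is a known heterozygous column.

    ``het_columns`` holds *current* column indices.  Such a read matches one
    of the two complementary alleles at the site under any phasing, so it
    always contributes 0 to the MEC score.
    """
    trace = ReductionTrace()
    keep_rows: List[int] = []
    for i, row in enumerate(matrix.rows):
        covered = [j for j, ch in enumerate(row) if ch != GAP]
        if len(covered) == 1 and covered[0] in het_columns:
            trace.removed_rows.append((matrix.row_ids[i], "singleton"))
        else:
            keep_rows.append(i)
    if not keep_rows:
        return None, trace
    if len(keep_rows) == matrix.num_rows:
        return matrix, trace
    reduced = ReadMatrix(
        rows=[matrix.rows[i] for i in keep_rows],
        num_columns=matrix.num_columns,
        row_weights=[matrix.row_weights[i] for i in keep_rows],
        col_weights=list(matrix.col_weights),
        row_ids=[matrix.row_ids[i] for i in keep_rows],
        col_ids=list(matrix.col_ids),
        col_origin=dict(matrix.col_origin),
        het_status=list(matrix.het_status),
    )
    return reduced, trace


def _cut_positions(matrix: ReadMatrix) -> List[int]:
    """The set S: indices i (0-based, cut after column i) no read straddles."""
    m = matrix.num_columns
    spans = [(matrix.row_start(i), matrix.row_end(i)) for i in range(matrix.num_rows)]
    cuts = []
    for i in range(m - 1):
        if all(en <= i or st >= i + 1 for st, en in spans):
            cuts.append(i)
    return cuts


def split_blocks(matrix: ReadMatrix) -> Tuple[List[Block], ReductionTrace]:
    """Cut the matrix at every position of S into independent blocks."""
    cuts = _cut_positions(matrix)
    trace = ReductionTrace(block_cuts=[matrix.col_ids[i] for i in cuts])
    bounds = [-1] + cuts + [matrix.num_columns - 1]
    blocks: List[Block] = []
    for b in range(len(bounds) - 1):
        lo, hi = bounds[b] + 1, bounds[b + 1]  # inclusive column range
        cols = list(range(lo, hi + 1))
        rows_idx = [
            i
            for i in range(matrix.num_rows)
            if lo <= matrix.row_start(i) and matrix.row_end(i) <= hi
        ]
        sub = ReadMatrix(
            rows=["".join(matrix.rows[i][j] for j in cols) for i in rows_idx],
            num_columns=len(cols),
            row_weights=[matrix.row_weights[i] for i in rows_idx],
            col_weights=[matrix.col_weights[j] for j in cols],
            row_ids=[matrix.row_ids[i] for i in rows_idx],
            col_ids=[matrix.col_ids[j] for j in cols],
            col_origin={k: matrix.col_origin[j] for k, j in enumerate(cols)},
            het_status=[matrix.het_status[j] for j in cols],
        )
        blocks.append(Block(matrix=sub, index=b))
    return blocks, trace


def split_reduced_blocks(
    block: Block, het_columns: Set[int]
) -> Tuple[List[ReducedBlock], ReductionTrace]:
    """Duplicate shared heterozygous columns (set T) and cut the block.

    T holds the interior columns i (0-based, excluding the first and last
    column of the block) that are known heterozygous and at which every read
    either ends (end <= i) or starts (start >= i).  Each i in T becomes the
    last column of the left segment and, as a duplicate, the first column of
    the right segment.  A read starting and ending exactly at i goes to the
    left segment (it is then a singleton there and removable).
    """
    mat = block.matrix
    m = mat.num_columns
    spans = [(mat.row_start(i), mat.row_end(i)) for i in range(mat.num_rows)]
    t_cols = [
        i
        for i in range(1, m - 1)
        if i in het_columns and all(en <= i or st >= i for st, en in spans)
    ]
    trace = ReductionTrace(
        reduced_block_boundaries={block.index: [mat.col_ids[i] for i in t_cols]}
    )
    segs: List[Tuple[int, int]] = []  # inclusive local column ranges
    bounds = [0] + t_cols + [m - 1]
    for k in range(len(bounds) - 1):
        segs.append((bounds[k], bounds[k + 1]))

    reduced: List[ReducedBlock] = []
    assigned: Set[int] = set()
    for k, (lo, hi) in enumerate(segs):
        cols = list(range(lo, hi + 1))
        rows_idx = []
        for i, (st, en) in enumerate(spans):
            if i in assigned:
                continue
            if lo <= st and en <= hi:
                rows_idx.append(i)
                assigned.add(i)
        if not rows_idx:
            sub = None  # read-free segment; see ReducedBlock docstring
        else:
            sub = ReadMatrix(
                rows=["".join(mat.rows[i][j] for j in cols) for i in rows_idx],
                num_columns=len(cols),
                row_weights=[mat.row_weights[i] for i in rows_idx],
                col_weights=[mat.col_weights[j] for j in cols],
                row_ids=[mat.row_ids[i] for i in rows_idx],
                col_ids=[mat.col_ids[j] for j in cols],
                col_origin={c: mat.col_origin[j] for c, j in enumerate(cols)},
                het_status=[mat.het_status[j] for j in cols],
            )
        reduced.append(
            ReducedBlock(
                matrix=sub,
                block_index=block.index,
                index_in_block=k,
                col_ids=[mat.col_ids[j] for j in cols],
                col_origin={c: mat.col_origin[j] for c, j in enumerate(cols)},
                het_status=[mat.het_status[j] for j in cols],
                first_shared=k > 0,
                last_shared=k < len(segs) - 1,
            )
        )
    return reduced, trace


def merge_rows(matrix: ReadMatrix) -> Tuple[ReadMatrix, ReductionTrace]:
    """Collapse identical rows into one row with summed multiplicity."""
    groups: Dict[str, int] = {}
    order: List[str] = []
    members: List[List[int]] = []
    weights: List[int] = []
    for i, row in enumerate(matrix.rows):
        if row in groups:
            g = groups[row]
            members[g].append(matrix.row_ids[i])
            weights[g] += matrix.row_weights[i]
        else:
            groups[row] = len(order)
            order.append(row)
            members.append([matrix.row_ids[i]])
            weights.append(matrix.row_weights[i])
    trace = ReductionTrace(row_merge_groups=[list(g) for g in members])
    merged = ReadMatrix(
        rows=order,
        num_columns=matrix.num_columns,
        row_weights=weights,
        col_weights=list(matrix.col_weights),
        row_ids=[g[0] for g in members],
        col_ids=list(matrix.col_ids),
        col_origin=dict(matrix.col_origin),
        het_status=list(matrix.het_status),
    )
    return merged, trace


def merge_columns(matrix: ReadMatrix) -> Tuple[ReadMatrix, ReductionTrace]:
    """Collapse identical-or-complementary columns into weighted carriers.

    Two columns merge when they share the same gap pattern, the same
    heterozygosity status, and their allele characters are position-wise
    identical or position-wise complementary.  The leftmost member is kept
    in its own orientation; every member records a flipped flag relative to
    it, used when expanding a solved haplotype back over the members.
    """
    canon_index: Dict[str, int] = {}
    reps: List[int] = []
    group_origin: List[List[Tuple[int, bool]]] = []
    group_weight: List[int] = []
    for j in range(matrix.num_columns):
        col = matrix.column(j)
        comp = complement(col)  # gaps untouched by complement translation
        key = min(col, comp) + "|" + matrix.het_status[j]
        if key in canon_index:
            g = canon_index[key]
            rep_col = matrix.column(reps[g])
            flipped = col != rep_col
            group_weight[g] += matrix.col_weights[j]
            for gid, fl in matrix.col_origin[j]:
                group_origin[g].append((gid, fl ^ flipped))
        else:
            canon_index[key] = len(reps)
            reps.append(j)
            group_weight.append(matrix.col_weights[j])
            group_origin.append([(gid, fl) for gid, fl in matrix.col_origin[j]])
    trace = ReductionTrace(col_merge_groups=[list(g) for g in group_origin])
    merged = ReadMatrix(
        rows=["".join(row[j] for j in reps) for row in matrix.rows],
        num_columns=len(reps),
        row_weights=list(matrix.row_weights),
        col_weights=group_weight,
        row_ids=list(matrix.row_ids),
        col_ids=[matrix.col_ids[j] for j in reps],
        col_origin={k: tuple(group_origin[k]) for k in range(len(reps))},
        het_status=[matrix.het_status[j] for j in reps],
    )
    return merged, trace


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------


class StitchError(RuntimeError):
    """Raised when per-block solutions cannot be reconciled."""


def _expand_solution(
    rb: ReducedBlock, pair: HaplotypePair
) -> Dict[int, Tuple[str, str]]:
    """Map original column id -> (h bit, h' bit) for one reduced block."""
    out: Dict[int, Tuple[str, str]] = {}
    for j in range(rb.num_columns):
        hb, pb = pair.h[j], pair.h_prime[j]
        for gid, flipped in rb.col_origin[j]:
            if flipped:
                out[gid] = (complement(hb), complement(pb))
            else:
                out[gid] = (hb, pb)
    return out


def stitch(
    block_solutions: Sequence[Tuple[ReducedBlock, HaplotypePair, int]],
    trace: ReductionTrace,
) -> PhasedResult:
    """Combine per-reduced-block optima into a full phased result.

    Within a block, adjacent reduced blocks share one duplicated heterozygous
    column; if the right solution's ``h`` letter there differs from the
    left's, the right pair is swapped (legitimate, as swapping ``(h, h')``
    preserves the MEC score).  Homozygous calls for removed monotone columns
    are reinserted, and S-cut blocks are reported as separate phase blocks.
    """
    m = trace.original_num_columns
    if m is None:
        raise StitchError("trace does not record the original column count")

    # group by block, order segments left to right
    by_block: Dict[int, List[Tuple[ReducedBlock, HaplotypePair, int]]] = {}
    for rb, pair, mec in block_solutions:
        by_block.setdefault(rb.block_index, []).append((rb, pair, mec))
    for sols in by_block.values():
        sols.sort(key=lambda s: s[0].index_in_block)

    values: Dict[int, Tuple[str, str]] = {}
    block_cols: Dict[int, Set[int]] = {}
    block_mec: Dict[int, int] = {}
    for b, sols in sorted(by_block.items()):
        merged_vals: Dict[int, Tuple[str, str]] = {}
        block_mec[b] = 0
        for rb, pair, mec in sols:
            block_mec[b] += mec
            vals = _expand_solution(rb, pair)
            if rb.first_shared:
                shared_gid = rb.col_ids[0]
                if shared_gid not in merged_vals:
                    raise StitchError(
                        f"shared column {shared_gid} missing from left segment"
                    )
                left_h, left_hp = merged_vals[shared_gid]
                if vals[shared_gid][0] != left_h:
                    pair = pair.swapped()
                    vals = _expand_solution(rb, pair)
                if vals[shared_gid] != (left_h, left_hp):
                    raise StitchError(
                        f"segments disagree at shared column {shared_gid} "
                        "in both orientations"
                    )
            for gid, hv in vals.items():
                merged_vals.setdefault(gid, hv)  # left value wins at shared col
        values.update(merged_vals)
        block_cols[b] = set(merged_vals)

    h_chars: List[str] = []
    hp_chars: List[str] = []
    zyg: List[str] = []
    for gid in range(m):
        if gid in values:
            hb, pb = values[gid]
        elif gid in trace.homozygous_calls:
            hb = pb = trace.homozygous_calls[gid]
        else:
            raise StitchError(f"no solution covers original column {gid}")
        h_chars.append(hb)
        hp_chars.append(pb)
        zyg.append("het" if hb != pb else "hom")

    h = "".join(h_chars)
    hp = "".join(hp_chars)
    phase_blocks = [sorted(block_cols[b]) for b in sorted(block_cols)]
    total = sum(block_mec.values())

    assignment = None
    if trace.original_matrix is not None:
        assignment = align_reads(
            trace.original_matrix, HaplotypePair(h, hp, list(zyg))
        )
    return PhasedResult(
        h=h,
        h_prime=hp,
        zygosity=zyg,
        phase_blocks=phase_blocks,
        block_mecs=[block_mec[b] for b in sorted(block_mec)],
        total_mec=total,
        assignment=assignment,
    )
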