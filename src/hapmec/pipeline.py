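"""End-to-end phasing: reductions, per-reduced-block ILP, stitching.

The driver applies the reduction chain in a single pass —

    monotone-column removal
    -> Singleton-Removal
    -> block split (set S)
    -> reduced-block split (set T, with column duplication)
    -> Singleton-Removal within each reduced block
    -> row merge -> column merge

— solves each merged reduced block with the selected ILP formulation, and
stitches the per-block optima back into full-length haplotypes.  The MEC
score of the stitched result equals the sum of the reduced-block optima;
each reduction above provably preserves the optimal score.

Heterozygosity semantics: in ``allhet`` mode every column surviving
monotone removal is assumed heterozygous (h' complementary everywhere); in
``general`` mode only user-supplied *intrinsically heterozygous* columns
are treated that way and all other columns phase freely, so a column may
come out homozygous.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set, Tuple

from . import ilp
from .io import ReducedBlockStats, RunStats
from .matrix import (
    ASSUMED_HET,
    INTRINSIC_HET,
    UNKNOWN,
    Assignment,
    HaplotypePair,
    ReadMatrix,
    align_reads,
)
from .reductions import (
    PhasedResult,
    ReducedBlock,
    ReductionTrace,
    force_heterozygous,
    merge_columns,
    merge_rows,
    remove_monotone_columns,
    remove_singleton_rows,
    split_blocks,
    split_reduced_blocks,
    stitch,
)

MODE_ALLHET = "allhet"
MODE_GENERAL = "general"

_BUILDERS = {
    (MODE_ALLHET, "new"): ilp.build_new_model_a,
    (MODE_ALLHET, "old"): ilp.build_old_model_a,
    (MODE_GENERAL, "new"): ilp.build_new_model_g,
    (MODE_GENERAL, "old"): ilp.build_old_model_g,
}


def _trivial_solution(rb: ReducedBlock) -> HaplotypePair:
    """Arbitrary optimal pair for a segment with no reads left: score 0."""
    h = "0" * rb.num_columns
    hp = "".join(
        "1" if st in (ASSUMED_HET, INTRINSIC_HET) else "0" for st in rb.het_status
    )
    return HaplotypePair(h, hp)


def _degenerate_result(
    matrix: ReadMatrix,
    trace: ReductionTrace,
    surviving: Sequence[int],
    mode: str,
    model: str,
) -> Tuple[PhasedResult, RunStats]:
    """All columns resolved without solving (no reads remain)."""
    m = matrix.num_columns
    h = []
    hp = []
    zyg = []
    for j in range(m):
        if j in trace.homozygous_calls:
            h.append(trace.homozygous_calls[j])
            hp.append(trace.homozygous_calls[j])
            zyg.append("hom")
        else:
            h.append("0")
            hp.append("1")
            zyg.append("het")
    pair = HaplotypePair("".join(h), "".join(hp), list(zyg))
    result = PhasedResult(
        h=pair.h,
        h_prime=pair.h_prime,
        zygosity=zyg,
        phase_blocks=[[j] for j in surviving],
        block_mecs=[0] * len(surviving),
        total_mec=0,
        assignment=align_reads(matrix, pair),
    )
    return result, RunStats(mode=mode, model=model)


def assemble(
    matrix: ReadMatrix,
    mode: str = MODE_ALLHET,
    model: str = "new",
    intrinsic_het: Optional[Iterable[int]] = None,
    time_limit: float = 86400.0,
    solver: str = "highs",
    force_het: Optional[Iterable[int]] = None,
) -> Tuple[PhasedResult, RunStats]:
    """Phase a fragment matrix exactly, minimising the MEC score.

    Parameters
    ----------
    matrix:
        the input fragment matrix (original coordinates).
    mode:
        ``"allhet"`` or ``"general"``.
    model:
        ``"new"`` (single-constraint formulations) or ``"old"``
        (three-constraint product linearisations); optima are identical.
    intrinsic_het:
        0-based original column indices known to be intrinsically
        heterozygous (general mode only).
    time_limit:
        per-reduced-block solver limit in seconds (default one day).
    force_het:
        columns to protect from monotone removal via dummy reads.

    Returns the stitched :class:`PhasedResult` and per-block
    :class:`RunStats`.
    """
    if mode not in (MODE_ALLHET, MODE_GENERAL):
        raise ValueError(f"unknown mode {mode!r}")
    if model not in ("new", "old"):
        raise ValueError(f"unknown model {model!r}")
    intrinsic = set(intrinsic_het or ())
    if mode == MODE_ALLHET and intrinsic:
        raise ValueError("intrinsic_het only applies in general mode")

    work = matrix
    if force_het:
        work = force_heterozygous(work, force_het)

    trace = ReductionTrace(
        original_num_rows=matrix.num_rows,
        original_num_columns=matrix.num_columns,
        original_matrix=matrix,
    )

    reduced, tr = remove_monotone_columns(work)
    trace.update(tr)
    if reduced is None:
        return _degenerate_result(matrix, trace, [], mode, model)

    # mark heterozygosity status on the surviving columns
    if mode == MODE_ALLHET:
        reduced.het_status = [ASSUMED_HET] * reduced.num_columns
    else:
        reduced.het_status = [
            INTRINSIC_HET if gid in intrinsic else UNKNOWN
            for gid in reduced.col_ids
        ]
    het_now = {
        j for j, st in enumerate(reduced.het_status)
        if st in (ASSUMED_HET, INTRINSIC_HET)
    }

    reduced2, tr = remove_singleton_rows(reduced, het_now)
    trace.update(tr)
    if reduced2 is None:
        return _degenerate_result(matrix, trace, list(reduced.col_ids), mode, model)

    blocks, tr = split_blocks(reduced2)
    trace.update(tr)

    stats = RunStats(mode=mode, model=model, num_blocks=len(blocks))
    solutions: List[Tuple[ReducedBlock, HaplotypePair, int]] = []
    builder = _BUILDERS[(mode, model)]

    for block in blocks:
        het_local = {
            j for j, st in enumerate(block.matrix.het_status)
            if st in (ASSUMED_HET, INTRINSIC_HET)
        }
        rbs, tr = split_reduced_blocks(block, het_local)
        trace.update(tr)
        for rb in rbs:
            stats.num_reduced_blocks += 1
            if rb.matrix is not None:
                het_rb = {
                    j for j, st in enumerate(rb.matrix.het_status)
                    if st in (ASSUMED_HET, INTRINSIC_HET)
                }
                slim, tr2 = remove_singleton_rows(rb.matrix, het_rb)
                trace.update(tr2)
                rb.matrix = slim
            if rb.matrix is None:
                solutions.append((rb, _trivial_solution(rb), 0))
                stats.blocks.append(
                    ReducedBlockStats(
                        block_index=rb.block_index,
                        index_in_block=rb.index_in_block,
                        num_rows=0,
                        num_columns=rb.num_columns,
                        nonzero_entries=0,
                        formulation="-",
                        num_variables=0,
                        num_constraints=0,
                        status=ilp.STATUS_OPTIMAL,
                        objective=0,
                        elapsed_seconds=0.0,
                    )
                )
                continue
            merged, _ = merge_rows(rb.matrix)
            merged, _ = merge_columns(merged)
            rb.matrix = merged
            rb.refresh_from_matrix()

            if mode == MODE_GENERAL:
                intr_local = {
                    j for j, st in enumerate(merged.het_status)
                    if st == INTRINSIC_HET
                }
                ilp_model = builder(merged, intr_local)
            else:
                ilp_model = builder(merged)
            res = ilp.solve(ilp_model, time_limit_seconds=time_limit, solver=solver)
            if res.status == ilp.STATUS_INFEASIBLE_ERROR:
                raise ilp.SolverError(
                    "backend returned no solution for a reduced block "
                    f"(block {rb.block_index}.{rb.index_in_block})"
                )
            pair, _assignment, mec = ilp.decode(ilp_model, res)
            if res.status != ilp.STATUS_OPTIMAL:
                stats.num_failed += 1
            solutions.append((rb, pair, mec))
            stats.blocks.append(
                ReducedBlockStats(
                    block_index=rb.block_index,
                    index_in_block=rb.index_in_block,
                    num_rows=merged.num_rows,
                    num_columns=merged.num_columns,
                    nonzero_entries=merged.nonzero_entries(),
                    formulation=ilp_model.tag,
                    num_variables=ilp_model.num_variables,
                    num_constraints=ilp_model.num_constraints,
                    status=res.status,
                    objective=mec,
                    elapsed_seconds=res.elapsed_seconds,
                )
            )

    result = stitch(solutions, trace)
    result.solver_statuses = [b.status for b in stats.blocks]
    stats.total_mec = result.total_mec
    return result, stats
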