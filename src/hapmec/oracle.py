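"""Exhaustive MEC optimisation for small matrices.

Ground truth for testing the ILP formulations and the reduction chain.  The
search enumerates bipartitions of the reads rather than candidate
haplotypes: once each read is assigned to one of the two haplotypes, the
optimal allele of each haplotype at each column is determined independently
per column by a majority count, in both the all-heterozygous and the
general case.  Identical rows are grouped first (there is always an optimal
solution assigning an identical group to one side), so the enumeration is
over ``2^(p-1)`` bipartitions of the ``p`` distinct rows, with the first row
fixed to the ``h`` side.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .matrix import GAP, HaplotypePair, ReadMatrix, complement, mec_score
from .reductions import merge_rows

ALL_HET = "all_het"
GENERAL = "general"


class OracleCapExceeded(ValueError):
    """Raised when the matrix has more distinct rows than the search cap."""


def brute_force_mec(
    matrix: ReadMatrix, mode: str = ALL_HET, max_rows: int = 20
) -> Tuple[int, HaplotypePair]:
    """Optimal MEC score and one witness haplotype pair, by enumeration.

    In ``all_het`` mode the pair is constrained to be complementary at every
    column; in ``general`` mode each haplotype picks its majority allele per
    column independently.  Ties are broken towards allele ``0`` and, across
    bipartitions with equal score, towards the lexicographically smallest
    ``(h, h')``.
    """
    if mode not in (ALL_HET, GENERAL):
        raise ValueError(f"unknown mode {mode!r}")
    merged, _ = merge_rows(matrix)
    p, q = merged.num_rows, merged.num_columns
    if p > max_rows:
        raise OracleCapExceeded(f"{p} distinct rows exceeds cap {max_rows}")

    w = np.asarray(merged.row_weights, dtype=np.int64)[:, None]
    cw = np.asarray(merged.col_weights, dtype=np.int64)
    is0 = np.array([[ch == "0" for ch in row] for row in merged.rows]) * w
    is1 = np.array([[ch == "1" for ch in row] for row in merged.rows]) * w

    best: Tuple[int, str, str] | None = None
    for mask in range(1 << max(p - 1, 0)):
        side = np.array(
            [True] + [((mask >> i) & 1) == 0 for i in range(p - 1)]
        )  # True -> aligned to h
        a0 = is0[side].sum(axis=0)
        a1 = is1[side].sum(axis=0)
        b0 = is0[~side].sum(axis=0)
        b1 = is1[~side].sum(axis=0)
        if mode == ALL_HET:
            cost0 = a1 + b0  # h_j = 0, h'_j = 1
            cost1 = a0 + b1  # h_j = 1, h'_j = 0
            col_cost = np.minimum(cost0, cost1)
            h_bits = cost1 < cost0  # tie -> 0
            hp_bits = ~h_bits
        else:
            col_cost = np.minimum(a0, a1) + np.minimum(b0, b1)
            h_bits = a0 < a1  # h_j = 1 only when strictly fewer errors
            hp_bits = b0 < b1
        score = int((cw * col_cost).sum())
        h = "".join("1" if b else "0" for b in h_bits)
        hp = "".join("1" if b else "0" for b in hp_bits)
        cand = (score, h, hp)
        if best is None or cand < best:
            best = cand

    assert best is not None
    score, h, hp = best
    return score, HaplotypePair(h, hp)


def verify_pair(matrix: ReadMatrix, pair: HaplotypePair, claimed: int) -> bool:
    """Recompute the MEC score of ``pair`` and compare with ``claimed``."""
    return mec_score(matrix, pair) == claimed
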