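"""Integer linear programs for exact MEC phasing of one reduced block.

Four formulations are provided.  In all of them, for a reduced block with p
rows (multiplicities w_i) and q columns (multiplicities c_j):

* ``x_j`` = 1  iff the j-th bit of haplotype h is 1,
* ``z_i`` = 1  iff row i is aligned to h,
* ``t_ij`` = 1 iff row i is aligned to h but disagrees with h at column j,

and, in the general case, for columns not known to be intrinsically
heterozygous,

* ``y_j`` = 1  iff the j-th bit of h' is 1,
* ``u_ij`` = 1 iff row i is aligned to h' but disagrees with h' at column j
  (in ``old_g`` the role of ``u_ij`` is instead ``y_j AND z_i``, as that
  formulation was originally stated).

``new_a``/``new_g`` enforce each t/u with a *single* lower-bound constraint
per non-gap entry, relying on the positive objective coefficient to pin the
variable at its minimum; ``old_a``/``old_g`` are the earlier three-constraint
linearisations of the products, kept for comparison.  All four minimise the
same weighted MEC score and have equal optima.

t and u variables are allocated sparsely, only for non-gap entries: gap
positions appear in no objective term and no constraint, so a dense grid
would only add free variables.

The solver backend is pluggable behind :func:`solve`; the default (and
currently only) backend is HiGHS via :func:`scipy.optimize.milp`, driven by
a wall-clock time limit with proven-optimality reporting.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .matrix import GAP, Assignment, HaplotypePair, ReadMatrix, complement, mec_score
from .reductions import ReducedBlock

NEW_MODEL_A = "NewModelA"
OLD_MODEL_A = "OldModelA"
NEW_MODEL_G = "NewModelG"
OLD_MODEL_G = "OldModelG"

STATUS_OPTIMAL = "optimal"
STATUS_FEASIBLE_TIMEOUT = "feasible_timeout"
STATUS_INFEASIBLE_ERROR = "infeasible_error"

#: integrality tolerance when reading binary variable values back
INT_TOL = 1e-6

BlockLike = Union[ReadMatrix, ReducedBlock]


class SolverError(RuntimeError):
    """Backend failure: unknown solver or no incumbent returned."""


def _as_matrix(block: BlockLike) -> ReadMatrix:
    if isinstance(block, ReducedBlock):
        if block.matrix is None:
            raise ValueError("reduced block has no reads to phase")
        return block.matrix
    return block


class _ModelBuilder:
    """Accumulates variables, objective terms and <= constraints."""

    def __init__(self) -> None:
        self.names: List[str] = []
        self.obj: List[float] = []
        self.offset = 0.0
        self.con_rows: List[int] = []
        self.con_cols: List[int] = []
        self.con_vals: List[float] = []
        self.rhs: List[float] = []

    def var(self, name: str) -> int:
        self.names.append(name)
        self.obj.append(0.0)
        return len(self.names) - 1

    def add_obj(self, idx: int, coef: float) -> None:
        self.obj[idx] += coef

    def add_le(self, terms: Sequence[Tuple[int, float]], rhs: float) -> None:
        r = len(self.rhs)
        for idx, coef in terms:
            self.con_rows.append(r)
            self.con_cols.append(idx)
            self.con_vals.append(coef)
        self.rhs.append(rhs)


@dataclass
class IlpModel:
    """One ILP formulation instantiated for one reduced block."""

    tag: str
    matrix: ReadMatrix
    c: np.ndarray
    offset: float
    A: sp.csr_matrix
    b: np.ndarray
    var_names: List[str]
    x_index: Dict[int, int]
    z_index: Dict[int, int]
    t_index: Dict[Tuple[int, int], int]
    y_index: Dict[int, int] = field(default_factory=dict)
    u_index: Dict[Tuple[int, int], int] = field(default_factory=dict)
    intrinsic: FrozenSet[int] = frozenset()

    @property
    def num_variables(self) -> int:
        return len(self.var_names)

    @property
    def num_constraints(self) -> int:
        return len(self.b)


@dataclass
class SolveResult:
    status: str
    objective: Optional[int]
    values: Optional[np.ndarray]
    elapsed_seconds: float


def _entries(mat: ReadMatrix):
    for i, row in enumerate(mat.rows):
        for j, ch in enumerate(row):
            if ch != GAP:
                yield i, j, ch


# ---------------------------------------------------------------------------
# all-heterozygous case
# ---------------------------------------------------------------------------


def build_new_model_a(block: BlockLike) -> IlpModel:
    """Single-constraint-per-entry model for complementary haplotypes.

    Objective:  sum_i w_i [ sum_{j in J_i0} c_j (1 - x_j - z_i + 2 t_ij)
                          + sum_{j in J_i1} c_j (x_j - z_i + 2 t_ij) ]
    Constraints: x_j + z_i - 1 <= t_ij  (entry 0),
                 z_i - x_j    <= t_ij  (entry 1).
    """
    mat = _as_matrix(block)
    b = _ModelBuilder()
    x = {j: b.var(f"x{j + 1}") for j in range(mat.num_columns)}
    z = {i: b.var(f"z{i + 1}") for i in range(mat.num_rows)}
    t: Dict[Tuple[int, int], int] = {}
    for i, j, ch in _entries(mat):
        wc = mat.row_weights[i] * mat.col_weights[j]
        tij = b.var(f"t{i + 1}_{j + 1}")
        t[(i, j)] = tij
        if ch == "0":
            # c_j (1 - x_j - z_i + 2 t_ij)
            b.offset += wc
            b.add_obj(x[j], -wc)
            b.add_obj(z[i], -wc)
            b.add_obj(tij, 2 * wc)
            b.add_le([(x[j], 1.0), (z[i], 1.0), (tij, -1.0)], 1.0)
        else:
            # c_j (x_j - z_i + 2 t_ij)
            b.add_obj(x[j], wc)
            b.add_obj(z[i], -wc)
            b.add_obj(tij, 2 * wc)
            b.add_le([(z[i], 1.0), (x[j], -1.0), (tij, -1.0)], 0.0)
    return _finish(NEW_MODEL_A, mat, b, x, z, t)


def build_old_model_a(block: BlockLike) -> IlpModel:
    """Three-constraint product linearisation (t_ij = x_j AND z_i)."""
    mat = _as_matrix(block)
    b = _ModelBuilder()
    x = {j: b.var(f"x{j + 1}") for j in range(mat.num_columns)}
    z = {i: b.var(f"z{i + 1}") for i in range(mat.num_rows)}
    t: Dict[Tuple[int, int], int] = {}
    for i, j, ch in _entries(mat):
        wc = mat.row_weights[i] * mat.col_weights[j]
        tij = b.var(f"t{i + 1}_{j + 1}")
        t[(i, j)] = tij
        if ch == "0":
            b.offset += wc
            b.add_obj(x[j], -wc)
            b.add_obj(z[i], -wc)
            b.add_obj(tij, 2 * wc)
        else:
            # c_j (z_i + x_j - 2 t_ij)
            b.add_obj(z[i], wc)
            b.add_obj(x[j], wc)
            b.add_obj(tij, -2 * wc)
        _product_constraints(b, tij, z[i], x[j])
    return _finish(OLD_MODEL_A, mat, b, x, z, t)


def _product_constraints(b: _ModelBuilder, prod: int, u: int, v: int) -> None:
    """prod = u AND v via prod <= u, prod <= v, prod >= u + v - 1."""
    b.add_le([(prod, 1.0), (u, -1.0)], 0.0)
    b.add_le([(prod, 1.0), (v, -1.0)], 0.0)
    b.add_le([(u, 1.0), (v, 1.0), (prod, -1.0)], 1.0)


# ---------------------------------------------------------------------------
# general case
# ---------------------------------------------------------------------------


def _split_intrinsic(block: BlockLike, intrinsic_het) -> Tuple[ReadMatrix, FrozenSet[int]]:
    mat = _as_matrix(block)
    intr = frozenset(intrinsic_het or ())
    bad = [j for j in intr if not 0 <= j < mat.num_columns]
    if bad:
        raise ValueError(f"intrinsic columns {bad} out of range")
    return mat, intr


def build_new_model_g(block: BlockLike, intrinsic_het: Set[int] = frozenset()) -> IlpModel:
    """General-case model with one lower-bound constraint per t/u variable.

    Columns in ``intrinsic_het`` are treated as in the all-heterozygous
    model (h' complementary there, no y/u variables); every other column
    gets an independent h' bit y_j and mismatch indicators u_ij, with

        t + u cost  c_j (t_ij + u_ij)
        x_j + z_i - 1 <= t_ij,   y_j - z_i     <= u_ij  (entry 0)
        z_i - x_j     <= t_ij,   1 - y_j - z_i <= u_ij  (entry 1)
    """
    mat, intr = _split_intrinsic(block, intrinsic_het)
    b = _ModelBuilder()
    x = {j: b.var(f"x{j + 1}") for j in range(mat.num_columns)}
    y = {j: b.var(f"y{j + 1}") for j in range(mat.num_columns) if j not in intr}
    z = {i: b.var(f"z{i + 1}") for i in range(mat.num_rows)}
    t: Dict[Tuple[int, int], int] = {}
    u: Dict[Tuple[int, int], int] = {}
    for i, j, ch in _entries(mat):
        wc = mat.row_weights[i] * mat.col_weights[j]
        tij = b.var(f"t{i + 1}_{j + 1}")
        t[(i, j)] = tij
        if j in intr:
            if ch == "0":
                b.offset += wc
                b.add_obj(x[j], -wc)
                b.add_obj(z[i], -wc)
                b.add_obj(tij, 2 * wc)
                b.add_le([(x[j], 1.0), (z[i], 1.0), (tij, -1.0)], 1.0)
            else:
                b.add_obj(x[j], wc)
                b.add_obj(z[i], -wc)
                b.add_obj(tij, 2 * wc)
                b.add_le([(z[i], 1.0), (x[j], -1.0), (tij, -1.0)], 0.0)
        else:
            uij = b.var(f"u{i + 1}_{j + 1}")
            u[(i, j)] = uij
            b.add_obj(tij, wc)
            b.add_obj(uij, wc)
            if ch == "0":
                b.add_le([(x[j], 1.0), (z[i], 1.0), (tij, -1.0)], 1.0)
                b.add_le([(y[j], 1.0), (z[i], -1.0), (uij, -1.0)], 0.0)
            else:
                b.add_le([(z[i], 1.0), (x[j], -1.0), (tij, -1.0)], 0.0)
                # 1 - y_j - z_i <= u_ij
                b.add_le([(y[j], -1.0), (z[i], -1.0), (uij, -1.0)], -1.0)
    return _finish(NEW_MODEL_G, mat, b, x, z, t, y=y, u=u, intrinsic=intr)


def build_old_model_g(block: BlockLike, intrinsic_het: Set[int] = frozenset()) -> IlpModel:
    """Earlier general-case model with product linearisations.

    t_ij = x_j AND z_i everywhere; u_ij = y_j AND z_i on non-intrinsic
    columns, whose per-entry cost is c_j (y_j + t_ij - u_ij) for entry 0 and
    c_j (1 - y_j - t_ij + u_ij) for entry 1.
    """
    mat, intr = _split_intrinsic(block, intrinsic_het)
    b = _ModelBuilder()
    x = {j: b.var(f"x{j + 1}") for j in range(mat.num_columns)}
    y = {j: b.var(f"y{j + 1}") for j in range(mat.num_columns) if j not in intr}
    z = {i: b.var(f"z{i + 1}") for i in range(mat.num_rows)}
    t: Dict[Tuple[int, int], int] = {}
    u: Dict[Tuple[int, int], int] = {}
    for i, j, ch in _entries(mat):
        wc = mat.row_weights[i] * mat.col_weights[j]
        tij = b.var(f"t{i + 1}_{j + 1}")
        t[(i, j)] = tij
        if j in intr:
            if ch == "0":
                b.offset += wc
                b.add_obj(x[j], -wc)
                b.add_obj(z[i], -wc)
                b.add_obj(tij, 2 * wc)
            else:
                b.add_obj(z[i], wc)
                b.add_obj(x[j], wc)
                b.add_obj(tij, -2 * wc)
            _product_constraints(b, tij, z[i], x[j])
        else:
            uij = b.var(f"u{i + 1}_{j + 1}")
            u[(i, j)] = uij
            if ch == "0":
                # c_j (y_j + t_ij - u_ij)
                b.add_obj(y[j], wc)
                b.add_obj(tij, wc)
                b.add_obj(uij, -wc)
            else:
                # c_j (1 - y_j - t_ij + u_ij)
                b.offset += wc
                b.add_obj(y[j], -wc)
                b.add_obj(tij, -wc)
                b.add_obj(uij, wc)
            _product_constraints(b, tij, z[i], x[j])
            _product_constraints(b, uij, z[i], y[j])
    return _finish(OLD_MODEL_G, mat, b, x, z, t, y=y, u=u, intrinsic=intr)


def _finish(
    tag: str,
    mat: ReadMatrix,
    b: _ModelBuilder,
    x: Dict[int, int],
    z: Dict[int, int],
    t: Dict[Tuple[int, int], int],
    y: Optional[Dict[int, int]] = None,
    u: Optional[Dict[Tuple[int, int], int]] = None,
    intrinsic: FrozenSet[int] = frozenset(),
) -> IlpModel:
    n = len(b.names)
    A = sp.csr_matrix(
        (b.con_vals, (b.con_rows, b.con_cols)), shape=(len(b.rhs), n)
    )
    return IlpModel(
        tag=tag,
        matrix=mat,
        c=np.asarray(b.obj, dtype=float),
        offset=b.offset,
        A=A,
        b=np.asarray(b.rhs, dtype=float),
        var_names=b.names,
        x_index=x,
        z_index=z,
        t_index=t,
        y_index=y or {},
        u_index=u or {},
        intrinsic=intrinsic,
    )


# ---------------------------------------------------------------------------
# solving / decoding
# ---------------------------------------------------------------------------


def model_stats(model: IlpModel) -> Tuple[int, int]:
    """(number of variables, number of constraints)."""
    return model.num_variables, model.num_constraints


def solve(
    model: IlpModel, time_limit_seconds: float = 86400.0, solver: str = "highs"
) -> SolveResult:
    """Minimise the model with the named MILP backend under a time limit.

    Status is ``optimal`` only when the backend proves optimality;
    ``feasible_timeout`` reports the incumbent at the limit.  The objective
    is rounded to the nearest integer (the formulations are integral).
    """
    if solver != "highs":
        raise SolverError(
            f"unknown solver {solver!r}; available backends: 'highs'"
        )
    n = model.num_variables
    start = time.perf_counter()
    res = milp(
        c=model.c,
        constraints=LinearConstraint(model.A, -np.inf, model.b),
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
        options={"time_limit": float(time_limit_seconds)},
    )
    elapsed = time.perf_counter() - start
    if res.status == 0 and res.x is not None:
        status = STATUS_OPTIMAL
    elif res.status == 1 and res.x is not None:
        status = STATUS_FEASIBLE_TIMEOUT
    else:
        return SolveResult(STATUS_INFEASIBLE_ERROR, None, None, elapsed)
    raw = float(res.fun) + model.offset
    objective = int(round(raw))
    if abs(raw - objective) > 1e-4:
        raise SolverError(f"non-integral objective {raw!r} from backend")
    return SolveResult(status, objective, np.asarray(res.x), elapsed)


def _read_binary(values: np.ndarray, idx: int) -> str:
    v = float(values[idx])
    if min(abs(v), abs(v - 1.0)) > 1e-4:
        raise SolverError(f"non-binary value {v!r}")
    return "1" if v > 0.5 else "0"


def decode(
    model: IlpModel, result: SolveResult, block: Optional[BlockLike] = None
) -> Tuple[HaplotypePair, Assignment, int]:
    """Read haplotypes, row alignment and the MEC score out of a solution.

    ``h`` comes from the x variables; ``h'`` is the complement of ``h`` at
    intrinsically heterozygous columns (all columns for the
    all-heterozygous models) and comes from the y variables elsewhere.  The
    MEC score is recomputed from the decoded pair and, for a proven-optimal
    solution, must equal the solver objective.
    """
    if result.values is None:
        raise SolverError("result carries no variable values")
    mat = _as_matrix(block) if block is not None else model.matrix
    vals = result.values
    h = "".join(_read_binary(vals, model.x_index[j]) for j in range(mat.num_columns))
    if model.tag in (NEW_MODEL_A, OLD_MODEL_A):
        hp = complement(h)
    else:
        hp = "".join(
            complement(h[j]) if j in model.intrinsic else _read_binary(vals, model.y_index[j])
            for j in range(mat.num_columns)
        )
    pair = HaplotypePair(h, hp)
    assignment = Assignment(
        to_h=[vals[model.z_index[i]] > 0.5 for i in range(mat.num_rows)]
    )
    mec = mec_score(mat, pair)
    if result.status == STATUS_OPTIMAL and result.objective != mec:
        raise SolverError(
            f"objective {result.objective} != recomputed MEC {mec} "
            f"for {model.tag}"
        )
    return pair, assignment, mec


# ---------------------------------------------------------------------------
# LP-format export
# ---------------------------------------------------------------------------


def write_lp(model: IlpModel, path) -> None:
    """Write the model in CPLEX LP text format for inspection.

    The constant term of the objective is not representable in LP format
    and is emitted as a leading comment.
    """
    lines = [f"\\ {model.tag}; objective constant {model.offset:+g}", "Minimize"]
    terms = []
    for idx, coef in enumerate(model.c):
        if coef:
            terms.append(f"{coef:+g} {model.var_names[idx]}")
    lines.append(" obj: " + " ".join(terms) if terms else " obj: 0 x1")
    lines.append("Subject To")
    A = model.A.tocsr()
    for r in range(model.num_constraints):
        row = A.getrow(r)
        parts = [
            f"{v:+g} {model.var_names[c]}"
            for c, v in zip(row.indices, row.data)
        ]
        lines.append(f" c{r + 1}: " + " ".join(parts) + f" <= {model.b[r]:g}")
    lines.append("Binary")
    lines.append(" " + " ".join(model.var_names))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
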