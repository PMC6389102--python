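"""hapmec: exact diploid haplotype assembly by minimum error correction.

Reads are phased by partitioning them between the two haplotypes of a
diploid individual so that the total number of corrected alleles (the MEC
score) is minimal.  The optimum is found exactly: the fragment matrix is
shrunk by a chain of score-preserving reductions, each resulting reduced
block is solved as a small integer linear program, and the per-block
solutions are stitched back together.
"""

from .matrix import (
    Assignment,
    HaplotypePair,
    MatrixFormatError,
    ReadMatrix,
    align_reads,
    complement,
    mec_score,
    mismatch_distance,
)
from .reductions import (
    Block,
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
from .ilp import (
    IlpModel,
    SolveResult,
    SolverError,
    build_new_model_a,
    build_new_model_g,
    build_old_model_a,
    build_old_model_g,
    decode,
    model_stats,
    solve,
    write_lp,
)
from .oracle import brute_force_mec, verify_pair
from .simulate import (
    GeraciParams,
    Sim95Params,
    expected_quality,
    generate_instance,
    random_matrix,
    sample_qualities,
    sim95_transform,
)
from .io import (
    RunStats,
    read_fragment_file,
    read_native_matrix,
    write_native_matrix,
    write_phased_blocks,
)
from .pipeline import assemble

__version__ = "0.1.0"

#: the six-read example matrix used throughout the documentation
EXAMPLE_ROWS = (
    "-100--",
    "11-0--",
    "01-101",
    "-01---",
    "1--01-",
    "101--0",
)


def example_matrix() -> ReadMatrix:
    """The 6x6 worked-example fragment matrix."""
    return ReadMatrix.from_rows(EXAMPLE_ROWS)
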