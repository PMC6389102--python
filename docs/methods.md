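# Methods

## Problem and objective

The input is a fragment matrix *A* with rows = reads, columns =
heterozygous SNP sites, entries in `{0, 1, -}`. For ternary strings *s*,
*t* of equal length, *d(s, t)* counts positions where both characters are
alleles (`0`/`1`) and differ; gaps never contribute. The goal is a
haplotype pair (*h*, *h′*) minimising `Σ_r min{d(h, r), d(h′, r)}` (the MEC
score). A read *r* is *aligned to h* when `d(h, r) ≤ d(h′, r)` — ties go
to *h*, exactly as the defining inequality reads. Row multiplicities *w_i*
and column multiplicities *c_j* (introduced by merging, below) weight the
score; on unreduced matrices all weights are 1 and the weighted score is
the plain MEC.

Two problem variants are supported. In the **all-heterozygous** case *h′*
is constrained to be the bitwise complement of *h* at every column — the
standard assumption that every column showing both alleles is a true
heterozygous site. In the **general** case the pair is unconstrained, so a
column may come out homozygous; columns *known* to be intrinsically
heterozygous may be supplied by the user and are then handled like the
all-heterozygous case (the literature contains a detection procedure for
such columns; this package deliberately accepts the set as input rather
than re-deriving it).

Note that by construction the general-case optimum never exceeds the
all-heterozygous optimum on the same matrix: every complementary pair is
also a candidate in the general case.

## Reduction chain

A single pass, in this order; each step provably preserves the optimal
score and records an invertible trace:

1. **Monotone-column removal.** A column in which `0` or `1` never appears
   is called homozygous for the observed allele (all-gap columns get the
   arbitrary call `0`) and dropped; rows left with no allele are dropped.
   Under the all-heterozygous mode this means the complementarity
   constraint applies to the *surviving* columns — a monotone column is
   reported `hom`, not forced heterozygous. Users who know a monotone
   column is heterozygous can protect it with `--force-het`, which inserts
   a one-site dummy read carrying the missing allele (removed again by
   singleton removal, so the optimum of the modified problem is unchanged).
2. **Singleton-Removal.** A read covering a single site that is known
   heterozygous matches one of the two complementary alleles under any
   phasing and contributes 0; it is dropped. In all-heterozygous mode
   "known heterozygous" is every surviving column; in general mode it is
   only the user-supplied intrinsic set (default empty).
3. **Block split (set S).** Cut between columns *i* and *i+1* whenever
   every read ends at or before *i* or starts at or after *i+1*. Blocks
   are phased independently and reported as separate phase blocks (no read
   links them, so their relative phase is arbitrary).
4. **Reduced-block split (set T).** Within a block, an interior
   known-heterozygous column at which every read ends (≤ *i*) or starts
   (≥ *i*) is duplicated; the block is cut between original and copy. The
   shared column pins the relative phase of the two halves at stitch time.
   A read that starts *and* ends at the shared column goes to the left
   half (either choice is sound — it becomes a removable singleton — and a
   fixed choice keeps traces deterministic). Singleton removal is applied
   again inside each reduced block.
5. **Row/column merging.** Identical rows collapse into one row with
   multiplicity = group size; columns with identical gap pattern whose
   allele characters are position-wise identical or complementary collapse
   into the leftmost member, with per-member orientation flags
   (same/flipped) recorded for expansion. Columns are only grouped within
   the same heterozygosity status, since intrinsic and unconstrained
   columns build different variables in the general-case models.

Reductions are **not** iterated to a fixpoint: a column that becomes
monotone after singleton removal stays in the model (it is still solved
correctly, just not shrunk). This matches the presentation the chain is
drawn from and avoids order-dependence subtleties.

**Stitching** inverts the chain: expand merged columns through their
orientation flags, reconcile each adjacent pair of reduced blocks at their
shared column (swap the right-hand (*h*, *h′*) if its *h* letter disagrees
— a score-preserving operation; disagreement in both orientations is an
internal error), drop the duplicates, reinsert homozygous calls, and sum
the per-block optima. The per-read alignment is recomputed from the
stitched pair with the tie-to-*h* rule. The total MEC equals the sum of
reduced-block objectives, and equals the weighted MEC of the stitched pair
on the original matrix.

## ILP formulations

For a reduced block with rows *i* = 1..*p*, columns *j* = 1..*q*: binary
variables `x_j` (*h*'s bit), `z_i` (row aligned to *h*), `t_ij` (aligned
to *h* and mismatching at *j*); in the general case additionally `y_j`
(*h′*'s bit) and `u_ij` for columns outside the intrinsic set *I*. Index
sets `J_i0`/`J_i1` hold the 0/1 entries of row *i* in intrinsic columns
(all columns, for the all-heterozygous case) and `J̄_i0`/`J̄_i1` the
entries in the remaining columns.

The **new** models use a single lower-bound constraint per mismatch
variable and objective terms whose truth tables equal the mismatch
indicators once `t`/`u` sit at their constraint floors (which minimisation
forces, as their objective coefficients are positive):

* entry 0, intrinsic: cost `c_j (1 − x_j − z_i + 2 t_ij)` s.t.
  `x_j + z_i − 1 ≤ t_ij`;
* entry 1, intrinsic: cost `c_j (x_j − z_i + 2 t_ij)` s.t.
  `z_i − x_j ≤ t_ij`;
* entry 0, general: cost `c_j (t_ij + u_ij)` s.t. `x_j + z_i − 1 ≤ t_ij`,
  `y_j − z_i ≤ u_ij`;
* entry 1, general: cost `c_j (t_ij + u_ij)` s.t. `z_i − x_j ≤ t_ij`,
  `1 − y_j − z_i ≤ u_ij`.

The **old** models linearise the products `t_ij = x_j ∧ z_i` (and
`u_ij = y_j ∧ z_i`) with three constraints each and the corresponding
objective forms. Constraint counts are therefore exactly
`Σ_i (|J_i0| + |J_i1| + 2|J̄_i0| + 2|J̄_i1|)` for the new models and three
times that for the old ones.

`t`/`u` variables are allocated **sparsely**, only for non-gap entries; a
dense row×column grid would add variables that appear in no term. With
sparse allocation the all-heterozygous variable count is `p + q + nnz`
(where `nnz` is the number of non-gap entries) rather than the dense
`p + q + pq`; the general-case count `p + 2q − |I| + Σ(...)` is already
the sparse one.

## Solving

The backend contract is: binary variables, linear constraints, minimise,
wall-clock time limit, report the incumbent and whether optimality was
proven. The registered backend is **HiGHS** through `scipy.optimize.milp`.
Defaults: per-reduced-block time limit 86 400 s (one day, CLI
`--time-limit`); objective read back with integrality tolerance 1e-4 and
rounded to the nearest integer; decoded solutions are re-scored with the
weighted MEC function and must equal the objective when optimality was
proven. Reduced blocks not proven optimal are counted (`num_failed` in the
run statistics) and `hapmec assemble` exits with code 3 when any block
timed out; their incumbent haplotypes are still stitched and reported.
Any built model can be exported in LP text format for inspection.

The brute-force oracle enumerates the `2^(p−1)` bipartitions of the
distinct rows (first row fixed to the *h* side; identical rows can always
share a side), computing per-column optimal allele costs —
`min(a1+b0, a0+b1)` all-heterozygous, `min(a0,a1) + min(b0,b1)` general —
and is capped at 20 distinct rows by default. It is the testing ground
truth for every formulation and for the reduction chain.

## Simulators

`generate_instance` emulates the classic three-parameter benchmark:
haplotype length ℓ, coverage *c*, error rate *e* (grids
ℓ ∈ {100, 350, 700}, c ∈ {3, 5, 8, 10}, e ∈ {0, 0.1, 0.2, 0.3}). A random
*h* is drawn with *h′* its complement; each haplotype is read *c* times in
full with i.i.d. per-allele flips at rate *e*, and each read is split into
two gapless fragments at a uniform cut (policy configurable; published
descriptions of the original fragmentation are not detailed enough to
replicate exactly, so this generator is an emulation, not a replication —
in particular real fragment-length and gap-structure distributions are not
modelled).

`sim95_transform` replays a quality-degradation scheme on any matrix's gap
pattern: reads are assigned uniformly to an all-0 or all-1 truth side,
then every allele is flipped with probability 1 − *t*, where the per-bit
quality *t* ~ Normal(0.95, 0.05) is *clamped* into [0.6, 1.0] (values
outside the band are reset to the nearer bound, giving point masses at the
bounds; `expected_quality` integrates this clamped law in closed form,
E[t] ≈ 0.9458, so the expected flip rate is ≈ 0.0542).

What passing simulator-based tests shows: the solver stack recovers
planted truth exactly in the noise-free limits and tracks calibrated noise
statistically. What it does not show: performance on real fosmid/shotgun
gap structures, quality-weighted phasing, or indel/genotyping artefacts —
all outside this package's abstraction (coded allele matrices).

## Problem sizes used in tests and the acceptance script

Randomised equivalence sweeps use matrices with 2–8 distinct rows and 2–10
columns (gap probability 0.3, error 0.1), 200 instances in the acceptance
sweep; simulated-MEC means use ℓ = 50, c = 3, e = 0.1 with 10 replicates
per mode. These sizes keep the full suite fast while every individual
optimum remains exact; larger instances change nothing qualitatively,
only solve time.

## Known limitations

* The general case without supplied intrinsic columns admits no T-cuts
  and no singleton removal, so reduced blocks are larger — consistent
  with the general case being the harder one.
* Switch-error and N50-style phasing quality metrics are not computed;
  the package's figure of merit is the MEC score itself.
* VCF/BAM ingestion is upstream of this tool: inputs are already-coded
  allele matrices or fragment files.
* Quality-weighted MEC is not implemented; fragment-file quality strings
  are read and ignored (with a logged notice).
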