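# hapmec — exact diploid haplotype assembly by minimum error correction

`hapmec` phases the two haplotypes of a diploid individual from aligned SNP
fragments, **exactly**. Given a read matrix *A* over `{0, 1, -}` (rows are
reads, columns are heterozygous SNP sites, `-` is a gap), it finds a pair
of binary haplotypes (*h*, *h′*) minimising the **MEC score**

```
MEC(h, h′) = Σ_r min{ d(h, r), d(h′, r) }
```

where *d* counts the positions at which both characters are alleles and
disagree — i.e. the smallest number of sequencing-error corrections that
make every read consistent with one of the two haplotypes. Minimising MEC
is NP-hard, but practical instances decompose: `hapmec` shrinks the matrix
with a chain of score-preserving reductions (homozygous-call removal of
monotone columns, singleton-read removal, block splitting at positions no
read straddles, boundary-column duplication, and row/column merging with
multiplicities *w_i*, *c_j*), solves each small *reduced block* as an
integer linear program, and stitches the per-block optima back together.

Two ILP formulations are provided per case, with identical optima:

* **NewModelA / NewModelG** — one constraint per non-gap entry
  (e.g. `x_j + z_i − 1 ≤ t_ij`), relying on the positive objective
  coefficient of the mismatch indicator `t_ij` to pin it at its floor;
* **OldModelA / OldModelG** — the classical three-constraint product
  linearisation (`t_ij ≤ x_j`, `t_ij ≤ z_i`, `t_ij ≥ x_j + z_i − 1`),
  kept for comparison.

The *all-heterozygous* case (`A` models) constrains *h′* to be the bitwise
complement of *h*; the *general* case (`G` models) lets columns come out
homozygous, with user-supplied *intrinsically heterozygous* columns handled
like the all-heterozygous case. The new models have exactly one third as
many constraints, which is what makes them faster to solve in practice.

Audience: anyone needing provably optimal MEC phasings — as ground truth
for benchmarking heuristic phasers, or for moderate instances directly.

## Worked example

The 6-read, 6-site matrix used throughout the documentation
(`hapmec.example_matrix()`), in the native one-row-per-read format:

```
-100--
11-0--
01-101
-01---
1--01-
101--0
```

```console
$ hapmec assemble example.mat
BLOCK start=1 span=6 mec=2
1 0 1 het
2 1 0 het
3 0 1 het
4 1 0 het
5 0 1 het
6 1 0 het
TOTAL_MEC=2
```

All six sites phase into a single block with haplotypes `010101` /
`101010` and an optimal MEC score of 2: reads r1 (`-100--`) and r2
(`11-0--`) each need one correction, every other read fits one haplotype
perfectly. The brute-force oracle (exhaustive over all 2⁵ read
bipartitions) confirms the optimum, and `hapmec stats` shows the model
sizes — 20 constraints for NewModelA versus 60 for OldModelA on this
matrix:

```console
$ hapmec oracle example.mat
MEC=2
h =010101
h'=101010
```

Other subcommands: `hapmec simulate` (synthetic matrices with planted
truth, including the truncated-normal quality-degradation transform),
`hapmec compare-models` (solve all four formulations side by side), and
`hapmec assemble --mode general --het-columns ...` for the general case.
Library use mirrors the CLI: `hapmec.assemble(matrix, mode=..., model=...)`
returns the stitched `PhasedResult` and per-block solve statistics.

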