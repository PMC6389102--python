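"""Synthetic fragment-matrix generators with ground truth.

Two generators are provided:

* :func:`generate_instance` builds benchmark-style matrices from three
  parameters — haplotype length ``l``, per-haplotype coverage ``c`` and
  per-allele error rate ``e`` (the classic simulation grid uses
  ``l in {100, 350, 700}``, ``c in {3, 5, 8, 10}`` and
  ``e in {0, 0.1, 0.2, 0.3}``).  A random haplotype ``h`` of length ``l``
  is drawn, ``h'`` is its complement, and each haplotype is sequenced by
  ``c`` full-length reads whose alleles are flipped independently with
  probability ``e``; each read is then fragmented (default: split into two
  gapless fragments at a uniformly random cut).  This is an *emulation* of
  published fragmentation schemes, whose exact internals vary; the
  fragmentation policy is a parameter.

* :func:`sim95_transform` replays a quality-degradation scheme on the gap
  pattern of an existing matrix: reads are split randomly into two sets,
  one rewritten to all-0 and the other to all-1 (so the planted truth is
  the pair (00...0, 11...1)), and every allele is then flipped with
  probability ``1 - t`` where the per-bit quality ``t`` is drawn from a
  normal distribution (default mean 0.95, sd 0.05) clamped into
  ``[0.6, 1.0]``.

* :func:`random_matrix` draws small unstructured matrices (per-cell gap
  probability, per-allele error rate) used as the randomised test corpus
  for model/oracle equivalence checks.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .matrix import GAP, HaplotypePair, ReadMatrix, complement


@dataclass
class GeraciParams:
    """Parameters of the benchmark-style generator."""

    haplotype_length: int = 100
    coverage: int = 3
    error_rate: float = 0.1
    #: 1 = whole-haplotype reads; 2 = split each read at a uniform cut
    fragments_per_read: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.haplotype_length < 1 or self.coverage < 1:
            raise ValueError("haplotype_length and coverage must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.fragments_per_read not in (1, 2):
            raise ValueError("fragments_per_read must be 1 or 2")


@dataclass
class Sim95Params:
    """Truncated-normal per-bit quality model."""

    mean: float = 0.95
    sd: float = 0.05
    lower: float = 0.6
    upper: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError("need 0 <= lower < upper <= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _bits_to_str(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in bits)


def generate_instance(
    params: GeraciParams, rng: Optional[np.random.Generator] = None
) -> Tuple[ReadMatrix, HaplotypePair]:
    """Simulate a fragment matrix and return it with the true pair."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    l, c, e = params.haplotype_length, params.coverage, params.error_rate
    h_bits = rng.integers(0, 2, size=l).astype(bool)
    truth = HaplotypePair(_bits_to_str(h_bits), _bits_to_str(~h_bits))

    rows = []
    for source in (h_bits, ~h_bits):
        for _ in range(c):
            read = source ^ (rng.random(l) < e)
            s = _bits_to_str(read)
            if params.fragments_per_read == 2 and l >= 2:
                cut = int(rng.integers(1, l))
                rows.append(s[:cut] + GAP * (l - cut))
                rows.append(GAP * cut + s[cut:])
            else:
                rows.append(s)
    return ReadMatrix.from_rows(rows), truth


def sample_qualities(
    params: Sim95Params, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw n per-bit qualities: normal(mean, sd) clamped into [lower, upper]."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = rng.normal(params.mean, params.sd, size=n)
    return np.clip(t, params.lower, params.upper)


def expected_quality(params: Sim95Params) -> float:
    """E[t] for the clamped normal quality, by closed-form integration.

    Clamping puts point masses at the truncation bounds:
    E[t] = lower*P(N<lower) + upper*P(N>upper) + integral of t phi(t) dt
    between the bounds.
    """
    from scipy.stats import norm

    mu, sd, lo, hi = params.mean, params.sd, params.lower, params.upper
    if sd == 0:
        return float(min(max(mu, lo), hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    middle = mu * (norm.cdf(b) - norm.cdf(a)) - sd * (norm.pdf(b) - norm.pdf(a))
    return float(lo * norm.cdf(a) + hi * norm.sf(b) + middle)


def sim95_transform(
    matrix: ReadMatrix,
    params: Sim95Params,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ReadMatrix, HaplotypePair]:
    """Rewrite alleles onto a planted (all-0, all-1) truth with noise.

    The gap pattern of ``matrix`` is preserved exactly; only allele cells
    change.  Reads are assigned uniformly to the all-0 or the all-1 side;
    each allele is then flipped with probability ``1 - t`` for a fresh
    quality draw ``t`` per bit.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m = matrix.num_columns
    to_zero = rng.random(matrix.num_rows) < 0.5
    new_rows = []
    for row, zero_side in zip(matrix.rows, to_zero):
        base = "0" if zero_side else "1"
        covered = np.array([ch != GAP for ch in row])
        k = int(covered.sum())
        t = sample_qualities(params, k, rng)
        flips = rng.random(k) < (1.0 - t)
        chars = list(row)
        for pos, flip in zip(np.flatnonzero(covered), flips):
            chars[pos] = complement(base) if flip else base
        new_rows.append("".join(chars))
    out = ReadMatrix(
        rows=new_rows,
        num_columns=m,
        row_weights=list(matrix.row_weights),
        col_weights=list(matrix.col_weights),
        row_ids=list(matrix.row_ids),
        col_ids=list(matrix.col_ids),
        col_origin=dict(matrix.col_origin),
        het_status=list(matrix.het_status),
    )
    return out, HaplotypePair("0" * m, "1" * m)


def random_matrix(
    rng: np.random.Generator,
    num_rows: int,
    num_cols: int,
    gap_prob: float = 0.3,
    error_rate: float = 0.1,
) -> ReadMatrix:
    """Small unstructured test matrix drawn around a random true pair.

    Each cell is a gap with probability ``gap_prob``; allele cells copy the
    row's source haplotype with per-allele flip probability ``error_rate``.
    Rows that would be all-gap get one random allele cell re-opened.
    """
    h = rng.integers(0, 2, size=num_cols).astype(bool)
    rows = []
    for _ in range(num_rows):
        source = h if rng.random() < 0.5 else ~h
        cells = source ^ (rng.random(num_cols) < error_rate)
        gaps = rng.random(num_cols) < gap_prob
        if gaps.all():
            gaps[rng.integers(num_cols)] = False
        rows.append(
            "".join(GAP if g else ("1" if b else "0") for g, b in zip(gaps, cells))
        )
    return ReadMatrix.from_rows(rows)
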