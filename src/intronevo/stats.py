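"""Inferential machinery for the loss/gain analysis.

Two complementary nulls address the clustering of lost introns along genes:

* a Monte-Carlo resampling null that redraws the lost set uniformly without
  replacement from the pool of lost + extant introns and counts adjacent
  pairs in each replicate; and
* an exact independence null: per gene, the distribution of adjacent-pair
  counts when k of its n intron ordinals are removed uniformly at random
  (dynamic programming over the ordinal path), convolved across genes into
  the clade-wide distribution.

Classical tests (2x2 chi-square, Mann-Whitney U, Wilcoxon signed rank)
delegate to scipy behind the small contracts used by the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class IntronPool:
    """Pool of lost + extant introns of one species, as (gene, ordinal) pairs."""

    introns: list[tuple[str, int]]
    n_lost: int

    def __post_init__(self) -> None:
        if len(set(self.introns)) != len(self.introns):
            raise ValueError("pool entries must be unique")
        if not 0 <= self.n_lost <= len(self.introns):
            raise ValueError("n_lost exceeds pool size")


@dataclass
class ResamplingResult:
    observed_pairs: int
    replicates: int
    tail_count: int
    p_value: float  # tail / R (the convention that can report P = 0)
    p_value_shrunk: float  # (tail + 1) / (R + 1)
    seed: int


@dataclass
class AdjacencyNull:
    """Exact independence null for total adjacent-loss pair counts."""

    per_gene: list[np.ndarray] = field(repr=False)
    total: np.ndarray = field(repr=False)
    observed: int | None = None
    tail_p: float | None = None


def _pair_codes(pool: list[tuple[str, int]]) -> np.ndarray:
    """Encode (gene, ordinal) so that code+1 is the next ordinal in the gene."""
    genes = {g: i for i, g in enumerate(sorted({g for g, _ in pool}))}
    span = max(o for _, o in pool) + 2
    return np.array([genes[g] * span + o for g, o in pool], dtype=np.int64)


def count_adjacent_from_codes(chosen: np.ndarray) -> int:
    return int(np.intersect1d(chosen + 1, chosen, assume_unique=True).size)


def resample_adjacent_pairs(
    pool: IntronPool, observed: int, R: int = 10_000, seed: int = 0
) -> ResamplingResult:
    """Monte-Carlo tail probability of seeing >= ``observed`` adjacent pairs.

    Each replicate draws ``pool.n_lost`` introns uniformly without replacement
    and counts consecutive-ordinal pairs within genes (three adjacent lost
    introns count as two pairs). p = tail/R; the shrunk (tail+1)/(R+1)
    estimate is reported alongside.
    """
    if observed < 0:
        raise ValueError("observed pair count must be non-negative")
    if R < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    codes = _pair_codes(pool.introns)
    n = len(codes)
    tail = 0
    for _ in range(R):
        chosen = np.sort(rng.choice(codes, size=pool.n_lost, replace=False))
        if count_adjacent_from_codes(chosen) >= observed:
            tail += 1
    return ResamplingResult(
        observed_pairs=observed,
        replicates=R,
        tail_count=tail,
        p_value=tail / R,
        p_value_shrunk=(tail + 1) / (R + 1),
        seed=seed,
    )


def _gene_pair_distribution(n: int, k: int) -> np.ndarray:
    """P(j adjacent pairs) when k of n consecutive ordinals are chosen
    uniformly at random; DP over positions of the ordinal path."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == 0 or n == 0:
        return np.array([1.0])
    # state: (picked so far, last position picked?) -> vector over pair counts
    max_pairs = k - 1
    dp = {(0, False): np.zeros(max_pairs + 1), (1, True): np.zeros(max_pairs + 1)}
    dp[(0, False)][0] = 1.0
    dp[(1, True)][0] = 1.0  # first position picked
    for _ in range(1, n):
        new: dict[tuple[int, bool], np.ndarray] = {}

        def add(key, vec):
            if key in new:
                new[key] += vec
            else:
                new[key] = vec.copy()

        for (picked, last), vec in dp.items():
            add((picked, False), vec)  # skip this position
            if picked < k:  # pick it
                if last:
                    shifted = np.zeros_like(vec)
                    shifted[1:] = vec[:-1]
                    add((picked + 1, True), shifted)
                else:
                    add((picked + 1, True), vec)
        dp = new
    counts = np.zeros(max_pairs + 1)
    for (picked, _), vec in dp.items():
        if picked == k:
            counts += vec
    total = counts.sum()
    return counts / total


def adjacency_null_distribution(
    genes: list[tuple[int, int]], observed: int | None = None
) -> AdjacencyNull:
    """Exact clade-wide distribution of adjacent-pair totals under
    independent uniform loss placement within each gene.

    ``genes`` lists (n_introns, k_lost) per gene; the clade-wide table is the
    convolution of the per-gene tables. When ``observed`` is given the upper
    tail probability P(total >= observed) is attached.
    """
    per_gene = [_gene_pair_distribution(n, k) for n, k in genes]
    total = np.array([1.0])
    for d in per_gene:
        total = np.convolve(total, d)
    total = total / total.sum()
    null = AdjacencyNull(per_gene=per_gene, total=total)
    if observed is not None:
        null.observed = observed
        null.tail_p = float(total[observed:].sum()) if observed < len(total) else 0.0
    return null


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table, no continuity correction by
    default. A zero row/column margin yields (0, 1) with a warning."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("zero margin in 2x2 table; chi-square undefined, p = 1")
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def mann_whitney_u(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U: exact for small tie-free samples, otherwise the
    tie-corrected normal approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    positions, mu: float = 0.5, alternative: str = "two-sided"
) -> float:
    """Signed-rank test of relative positions against a median of ``mu``.

    Zeros are dropped; exact for n <= 25, normal approximation (with
    continuity correction) otherwise. All-zero input yields p = 1.
    """
    d = np.asarray(positions, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative=alternative, method=method, correction=True)
    return float(res.pvalue)
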