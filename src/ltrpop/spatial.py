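"""Association between genetic distance and position relative to the
centromere midpoint.

The positional difference between two copies is the absolute difference
of their absolute distances from the centromere midpoint (so two copies
5 Mb on either side of the midpoint have positional difference zero).
Association between the positional and the pairwise-SNP distance
matrices is assessed with a Mantel test: Spearman rank correlation over
the upper triangles, with a permutation null obtained by jointly
permuting rows and columns of one matrix (9,999 permutations, one-sided
for positive association, +1-corrected p-value).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .models import CentromereDefinition, FullLengthCopy, GenomicInterval, MantelResult

BP_PER_MB = 1e6


def positional_difference(
    pos_i: float,
    pos_j: float,
    cen: CentromereDefinition,
    chrom_i: Optional[str] = None,
    chrom_j: Optional[str] = None,
) -> float:
    """| |pos_i - midpoint| - |pos_j - midpoint| | in Mb."""
    for chrom in (chrom_i, chrom_j):
        if chrom is not None and chrom != cen.chrom:
            raise ValueError(f"position on {chrom}, centromere on {cen.chrom}")
    return abs(abs(pos_i - cen.midpoint) - abs(pos_j - cen.midpoint)) / BP_PER_MB


def positional_distance_matrix(
    positions: Sequence[float], cen: CentromereDefinition
) -> np.ndarray:
    """Pairwise positional differences (Mb) for copy midpoint positions."""
    d = np.abs(np.asarray(positions, dtype=float) - cen.midpoint)
    return np.abs(d[:, None] - d[None, :]) / BP_PER_MB


def _check_distance_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name}: not square")
    if m.shape[0] < 3:
        raise ValueError(f"{name}: need dimension >= 3")
    finite = np.isfinite(m)
    if not np.allclose(m[finite], m.T[finite.T]):
        raise ValueError(f"{name}: not symmetric")
    if not np.allclose(np.diag(m)[np.isfinite(np.diag(m))], 0):
        raise ValueError(f"{name}: nonzero diagonal")
    return m


def mantel_statistic(
    genetic: np.ndarray, positional: np.ndarray, method: str = "spearman"
) -> float:
    """Rank (or plain) correlation between the matrices' upper triangles,
    with missing entries dropped pairwise."""
    iu = np.triu_indices(genetic.shape[0], k=1)
    x, y = genetic[iu], positional[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance in a triangle")
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


def mantel_test(
    genetic: np.ndarray,
    positional: np.ndarray,
    method: str = "spearman",
    permutations: int = 9999,
    seed: Optional[int] = None,
) -> MantelResult:
    """One-sided (positive association) Mantel permutation test.

    ``p = (1 + #{r_perm >= r_obs}) / (permutations + 1)``, where each
    permutation jointly reorders the rows and columns of the positional
    matrix.  Missing entries are dropped pairwise.
    """
    genetic = _check_distance_matrix(genetic, "genetic")
    positional = _check_distance_matrix(positional, "positional")
    if genetic.shape != positional.shape:
        raise ValueError("matrix dimensions differ")
    n = genetic.shape[0]
    r_obs = mantel_statistic(genetic, positional, method)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    has_nan = not (np.isfinite(genetic[iu]).all() and np.isfinite(positional[iu]).all())

    count = 0
    if not has_nan and method == "spearman":
        # ranks of the permuted triangle are a fixed multiset: rank the
        # full matrices once and index under each permutation
        xr = rankdata(genetic[iu])
        yr_flat = rankdata(positional[iu])
        yr_mat = np.zeros((n, n))
        yr_mat[iu] = yr_flat
        yr_mat = yr_mat + yr_mat.T
        xs = xr - xr.mean()
        xs /= np.sqrt(xs @ xs)
        sy = np.sqrt(((yr_flat - yr_flat.mean()) ** 2).sum())
        my = yr_flat.mean()
        for _ in range(permutations):
            perm = rng.permutation(n)
            yp = yr_mat[np.ix_(perm, perm)][iu]
            r = xs @ (yp - my) / sy
            if r >= r_obs - 1e-12:
                count += 1
    else:
        for _ in range(permutations):
            perm = rng.permutation(n)
            pp = positional[np.ix_(perm, perm)]
            try:
                r = mantel_statistic(genetic, pp, method)
            except ValueError:
                continue
            if r >= r_obs - 1e-12:
                count += 1
    p = (1 + count) / (permutations + 1)
    return MantelResult(
        statistic=r_obs, p_value=p, permutations=permutations, method=method
    )


def filter_region_age(
    copies_with_ages: Sequence[tuple[FullLengthCopy, float]],
    region: GenomicInterval,
    max_age: float,
) -> list[tuple[FullLengthCopy, float]]:
    """Copies whose midpoint lies in the region (inclusive bounds) with
    age at most ``max_age`` — the neocentromere recent-insertion filter."""
    out = []
    for copy, age in copies_with_ages:
        mid = copy.interval.midpoint
        if (
            copy.interval.chrom == region.chrom
            and region.start <= mid <= region.end
            and age <= max_age
        ):
            out.append((copy, age))
    return out
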