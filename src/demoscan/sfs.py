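"""Folded joint site-frequency spectra and their composite likelihood.

A joint SFS for a stand pair is a matrix of SNP counts indexed by allele
counts ``(i, j)`` at fixed projected haploid sample sizes ``(n_a, n_b)``.
Because ancestral states are unknown the spectrum is folded by the pooled
minor allele: cell ``(i, j)`` is identified with ``(n_a - i, n_b - j)`` and
the pair's counts are accumulated in a single representative cell.  Sites
with missing genotypes are projected down to the target sample sizes by
hypergeometric expectation, the standard treatment for incomplete calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataset import GenotypeDataset


def fold_mask(n_a: int, n_b: int) -> np.ndarray:
    """Boolean mask of representative cells after minor-allele folding.

    A cell ``(i, j)`` is representative when ``2*(i+j) < n_a+n_b``, or on an
    exact tie when it is lexicographically no larger than its complement
    ``(n_a-i, n_b-j)``.  Folding merges each cell pair into its
    representative; the complement cells are masked.
    """
    i = np.arange(n_a + 1)[:, None]
    j = np.arange(n_b + 1)[None, :]
    tot = i + j
    comp_le = (i < n_a - i) | ((i == n_a - i) & (j <= n_b - j))
    return (2 * tot < n_a + n_b) | ((2 * tot == n_a + n_b) & comp_le)


def fold_matrix(unfolded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold an unfolded joint spectrum; returns (folded matrix, keep-mask)."""
    n_a = unfolded.shape[0] - 1
    n_b = unfolded.shape[1] - 1
    keep = fold_mask(n_a, n_b)
    flipped = unfolded[::-1, ::-1]
    folded = np.where(keep, unfolded + flipped, 0.0)
    # self-complementary cell (only when both n_a and n_b are even): do not double
    if n_a % 2 == 0 and n_b % 2 == 0:
        folded[n_a // 2, n_b // 2] = unfolded[n_a // 2, n_b // 2]
    return folded, keep


@dataclass
class Folded2DSFS:
    """Folded joint SFS for one stand pair at a fixed projection."""

    pair: tuple[str, str]
    n_proj: tuple[int, int]
    matrix: np.ndarray  # (n_a+1, n_b+1); zeros outside the kept mask
    mask: np.ndarray  # True on representative (kept) cells
    n_sites_used: int = 0
    n_sites_dropped: int = 0

    @property
    def total(self) -> float:
        return float(self.matrix[self.mask].sum())

    def proportions(self, floor: float | None = None) -> np.ndarray:
        """Kept-cell proportions, excluding the monomorphic (0, 0) cell.

        ``floor`` replaces empty cells by the given probability floor before
        renormalising (used when the spectrum serves as an expectation).
        """
        p = self.matrix.copy().astype(float)
        p[~self.mask] = 0.0
        p[0, 0] = 0.0
        s = p.sum()
        if s <= 0:
            raise ValueError(f"empty spectrum for pair {self.pair}")
        p /= s
        if floor is not None:
            poly = self.mask.copy()
            poly[0, 0] = False
            p[poly & (p <= 0)] = floor
            p /= p[poly].sum()
        return p

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(range(self.n_proj[0] + 1), name=f"{self.pair[0]}_count"),
            columns=[str(j) for j in range(self.n_proj[1] + 1)],
        )
        return df


def projection_weights(n_obs: int, k: int, n_proj: int) -> np.ndarray:
    """Hypergeometric expectation of projecting k-of-n_obs down to n_proj."""
    js = np.arange(n_proj + 1)
    return hypergeom.pmf(js, n_obs, k, n_proj)


def site_cell_weights(
    data: GenotypeDataset,
    pair: tuple[str, str],
    n_proj: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unfolded joint-cell weight vectors under projection.

    Returns ``(weights, usable)`` where ``weights`` has shape
    ``(n_sites, (n_a+1)*(n_b+1))`` (rows of sites that cannot be projected
    are zero) and ``usable`` marks sites with at least ``n_proj`` called
    chromosomes in both stands.
    """
    n_a, n_b = n_proj
    alt_a, chrom_a = data.allele_counts(pair[0])
    alt_b, chrom_b = data.allele_counts(pair[1])
    usable = (chrom_a >= n_a) & (chrom_b >= n_b)
    n_sites = data.n_sites
    weights = np.zeros((n_sites, (n_a + 1) * (n_b + 1)))
    # group identical (n_obs, k) pairs to avoid recomputing pmfs
    cache_a: dict[tuple[int, int], np.ndarray] = {}
    cache_b: dict[tuple[int, int], np.ndarray] = {}
    for s in np.flatnonzero(usable):
        key_a = (int(chrom_a[s]), int(alt_a[s]))
        key_b = (int(chrom_b[s]), int(alt_b[s]))
        wa = cache_a.get(key_a)
        if wa is None:
            wa = projection_weights(key_a[0], key_a[1], n_a)
            cache_a[key_a] = wa
        wb = cache_b.get(key_b)
        if wb is None:
            wb = projection_weights(key_b[0], key_b[1], n_b)
            cache_b[key_b] = wb
        weights[s] = np.outer(wa, wb).ravel()
    return weights, usable


def folded_joint_sfs(
    data: GenotypeDataset,
    pair: tuple[str, str],
    projection: tuple[int, int] | None = None,
) -> Folded2DSFS:
    """Folded joint SFS for a stand pair from diploid genotypes.

    ``projection`` gives target haploid sample sizes; by default the smallest
    per-stand called-chromosome count across sites (rounded down to an even
    number).  Sites with fewer called chromosomes than the projection in
    either stand are dropped and counted.
    """
    if projection is None:
        projection = default_projection(data, pair)
    n_a, n_b = projection
    weights, usable = site_cell_weights(data, pair, projection)
    unfolded = weights.sum(axis=0).reshape(n_a + 1, n_b + 1)
    folded, keep = fold_matrix(unfolded)
    return Folded2DSFS(
        pair=pair,
        n_proj=projection,
        matrix=folded,
        mask=keep,
        n_sites_used=int(usable.sum()),
        n_sites_dropped=int((~usable).sum()),
    )


def default_projection(
    data: GenotypeDataset, pair: tuple[str, str]
) -> tuple[int, int]:
    """Smallest per-stand called-chromosome count across sites, made even."""
    proj = []
    for stand in pair:
        _, chrom = data.allele_counts(stand)
        if len(chrom) == 0:
            raise ValueError("dataset has no sites")
        m = int(chrom.min())
        if m < 2:
            raise ValueError(
                f"stand {stand} has a site with fewer than 2 called chromosomes"
            )
        proj.append(m - (m % 2))
    return proj[0], proj[1]


def fold_unfolded_counts(
    unfolded: np.ndarray, pair: tuple[str, str]
) -> Folded2DSFS:
    """Wrap a raw unfolded joint count matrix into a folded spectrum."""
    folded, keep = fold_matrix(np.asarray(unfolded, dtype=float))
    n_a = unfolded.shape[0] - 1
    n_b = unfolded.shape[1] - 1
    return Folded2DSFS(
        pair=pair,
        n_proj=(n_a, n_b),
        matrix=folded,
        mask=keep,
        n_sites_used=int(np.asarray(unfolded).sum()),
    )


def composite_loglik(
    observed: Sequence[Folded2DSFS],
    expected: Sequence[Folded2DSFS],
    floor: float | None = None,
) -> float:
    """Composite log-likelihood of observed spectra under expected proportions.

    Sums ``obs_count * ln(expected proportion)`` over the unmasked polymorphic
    cells of every pair.  ``floor`` (default ``1 / (10 * total expected
    count)`` per pair) replaces empty expected cells so that observed counts
    in unvisited cells are penalised rather than undefined.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected pair lists differ in length")
    total = 0.0
    for obs, exp in zip(observed, expected):
        if obs.n_proj != exp.n_proj:
            raise ValueError(
                f"projection mismatch for pair {obs.pair}: "
                f"{obs.n_proj} vs {exp.n_proj}"
            )
        eps = floor
        if eps is None:
            denom = max(exp.total, 1.0)
            eps = 1.0 / (10.0 * denom)
        p = exp.proportions(floor=eps)
        poly = obs.mask.copy()
        poly[0, 0] = False
        counts = obs.matrix[poly]
        probs = p[poly]
        nz = counts > 0
        total += float((counts[nz] * np.log(probs[nz])).sum())
    return total
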