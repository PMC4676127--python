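"""Joint allele-frequency spectra and Poisson composite likelihood.

The two-population joint AFS is an (n1+1) x (n2+1) matrix of site tallies
indexed by derived-allele counts, with the fixed corner cells (0, 0) and
(n1, n2) masked.  The composite likelihood treats cells as independent
Poisson counts; an analytic theta rescaling (theta_hat = sum(X)/sum(M))
profiles the overall mutation rate out of every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom, hypergeom


@dataclass
class JointAFS:
    """Observed joint spectrum for two populations of n1 and n2 haploids."""

    matrix: np.ndarray
    n1: int
    n2: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match "
                             f"sample sizes ({self.n1}, {self.n2})")
        if np.any(self.matrix < 0):
            raise ValueError("spectrum entries must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """True on masked (excluded) cells: the two fixed corners."""
        m = np.zeros_like(self.matrix, dtype=bool)
        m[0, 0] = True
        m[self.n1, self.n2] = True
        return m

    def total(self) -> float:
        return float(self.matrix[~self.mask].sum())

    def fold(self) -> np.ndarray:
        """Minor-allele-count folded spectrum.

        Cell (i, j) of the folded spectrum pools (i, j) with its mirror
        (n1 - i, n2 - j); the half with smaller total derived count keeps
        the mass, and self-mirror cells are not doubled.
        """
        n1, n2 = self.n1, self.n2
        x = self.matrix
        folded = np.zeros_like(x)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                mi, mj = n1 - i, n2 - j
                tot_here = i + j
                tot_mirror = mi + mj
                if tot_here < tot_mirror:
                    folded[i, j] = x[i, j] + x[mi, mj]
                elif tot_here == tot_mirror and (i, j) <= (mi, mj):
                    folded[i, j] = x[i, j] + (x[mi, mj] if (i, j) != (mi, mj) else 0.0)
        return folded


def project_counts(derived: int, observed: int, n_target: int) -> np.ndarray:
    """Hypergeometric down-projection of one site.

    A site with ``derived`` copies among ``observed`` called alleles is
    spread over derived counts 0..n_target as the probability of drawing
    each count in a sample of ``n_target`` alleles without replacement.
    """
    if observed < n_target:
        raise ValueError("cannot project up")
    k = np.arange(n_target + 1)
    return hypergeom.pmf(k, observed, derived, n_target)


def build_joint_afs(derived1: np.ndarray, derived2: np.ndarray,
                    n1: int, n2: int,
                    observed1: np.ndarray | None = None,
                    observed2: np.ndarray | None = None,
                    on_missing: str = "project") -> JointAFS:
    """Tally the joint spectrum from per-site derived counts.

    ``derived1/derived2`` give each site's derived-allele count per
    population; ``observed1/observed2`` the number of successfully called
    alleles (defaults: all n1 / n2).  Sites with missing calls are either
    hypergeometrically projected down to (n1, n2) or dropped, per
    ``on_missing``.  Derived counts exceeding the observed alleles raise.
    """
    d1 = np.asarray(derived1, dtype=np.int64)
    d2 = np.asarray(derived2, dtype=np.int64)
    o1 = np.full_like(d1, n1) if observed1 is None else np.asarray(observed1)
    o2 = np.full_like(d2, n2) if observed2 is None else np.asarray(observed2)
    if np.any(d1 > o1) or np.any(d2 > o2):
        raise ValueError("derived count exceeds observed allele count")
    if np.any((d1 < 0) | (d2 < 0)):
        raise ValueError("negative derived count")
    x = np.zeros((n1 + 1, n2 + 1))
    complete = (o1 == n1) & (o2 == n2)
    np.add.at(x, (d1[complete], d2[complete]), 1.0)
    for i in np.flatnonzero(~complete):
        if on_missing == "drop" or o1[i] < n1 or o2[i] < n2:
            # a site cannot be projected up; fewer called alleles than the
            # target spectrum size means the site is dropped
            continue
        w1 = (project_counts(int(d1[i]), int(o1[i]), n1)
              if o1[i] != n1 else _one_hot(int(d1[i]), n1))
        w2 = (project_counts(int(d2[i]), int(o2[i]), n2)
              if o2[i] != n2 else _one_hot(int(d2[i]), n2))
        x += np.outer(w1, w2)
    return JointAFS(matrix=x, n1=n1, n2=n2)


def _one_hot(k: int, n: int) -> np.ndarray:
    v = np.zeros(n + 1)
    v[k] = 1.0
    return v


def joint_afs_from_cohort(cohort, on_missing: str = "project") -> JointAFS:
    """Joint AFS straight from a synthetic cohort (truth populations)."""
    table = cohort.variants
    idx1 = cohort.samples_in_pop(0)
    idx2 = cohort.samples_in_pop(1)
    d1 = table.derived_counts(idx1)
    d2 = table.derived_counts(idx2)
    ok = (d1 >= 0) & (d2 >= 0)
    return build_joint_afs(d1[ok], d2[ok], 2 * len(idx1), 2 * len(idx2),
                           on_missing=on_missing)


def project_afs(afs_matrix: np.ndarray, n1: int, n2: int,
                m1: int, m2: int) -> np.ndarray:
    """Project an (n1+1)x(n2+1) expected spectrum down to (m1+1)x(m2+1)."""
    P1 = np.array([[hypergeom.pmf(a, n1, i, m1) for a in range(m1 + 1)]
                   for i in range(n1 + 1)])
    P2 = np.array([[hypergeom.pmf(b, n2, j, m2) for b in range(m2 + 1)]
                   for j in range(n2 + 1)])
    return P1.T @ afs_matrix @ P2


def composite_loglik(X: JointAFS, M: np.ndarray, scale_theta: bool = True,
                     eps: float = 1e-12) -> float:
    """Poisson composite log likelihood of the observed spectrum.

    LL = sum over unmasked cells of x*ln(m) - m - ln(x!).  With
    ``scale_theta`` the expectation is first multiplied by the analytic
    optimum theta_hat = sum(X)/sum(M).  Expected cells at zero with a
    positive observation are floored at ``eps``.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape != X.matrix.shape:
        raise ValueError("shape mismatch between observed and expected AFS")
    keep = ~X.mask
    x = X.matrix[keep]
    m = M[keep].copy()
    if scale_theta:
        tot = m.sum()
        if tot <= 0:
            return -np.inf
        m *= x.sum() / tot
    m = np.maximum(m, eps)
    return float(np.sum(x * np.log(m) - m - gammaln(x + 1.0)))


def residuals_and_gof(X: JointAFS, M: np.ndarray, scale_theta: bool = True,
                      eps: float = 1e-12) -> dict:
    """Pearson residuals and goodness-of-fit statistic.

    r_ij = (x_ij - m_ij) / sqrt(m_ij) on unmasked cells (positive where the
    model predicts too few sites); the Pearson statistic is sum(r^2).
    """
    M = np.asarray(M, dtype=np.float64).copy()
    if M.shape != X.matrix.shape:
        raise ValueError("shape mismatch")
    keep = ~X.mask
    if scale_theta:
        tot = M[keep].sum()
        if tot > 0:
            M *= X.matrix[keep].sum() / tot
    M = np.maximum(M, eps)
    resid = np.full_like(M, np.nan)
    resid[keep] = (X.matrix[keep] - M[keep]) / np.sqrt(M[keep])
    return {
        "residuals": resid,
        "pearson_stat": float(np.nansum(resid[keep] ** 2)),
    }


def sample_projection_matrix(grid: int, n: int) -> np.ndarray:
    """Hypergeometric subsampling matrix from grid counts to sample counts.

    Treating grid state i as a population of ``grid`` haploids carrying i
    derived copies, entry (i, a) is the probability a sample of n haploids
    drawn without replacement carries a copies.  Hypergeometric (not
    binomial) sampling keeps the neutral spectrum exactly theta/a after
    projection (subsampling consistency of the SFS).
    """
    a = np.arange(n + 1)
    i = np.arange(grid + 1)
    return hypergeom.pmf(a[None, :], grid, i[:, None], n)
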