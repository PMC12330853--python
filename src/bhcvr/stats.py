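"""ROI-level model comparison statistics.

The six signal models are compared across subjects on ROI summary metrics
(mean F, CVR, Lag_rel) with a complete-block, rank-based toolkit: Friedman's
test for a main effect of condition, Conover's post-hoc pairwise test with
Bonferroni correction, and a paired sign-flip permutation test as a
desk-scale stand-in for voxelwise permutation inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepeatedMeasures",
    "friedman_test",
    "conover_posthoc",
    "bonferroni",
    "paired_signflip_test",
]


@dataclass(frozen=True)
class RepeatedMeasures:
    """Subjects x conditions matrix with no missing cells."""

    matrix: np.ndarray
    condition_labels: tuple[str, ...] = ()
    metric_name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("matrix must be (subjects >= 2) x (conditions >= 2)")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix must have no missing cells")
        object.__setattr__(self, "matrix", m)
        if self.condition_labels and len(self.condition_labels) != m.shape[1]:
            raise ValueError("condition_labels length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[1]


def _within_subject_ranks(m: np.ndarray) -> np.ndarray:
    return sps.rankdata(m, axis=1)


def friedman_test(data: RepeatedMeasures) -> tuple[float, float]:
    """Friedman's rank test for a condition effect in a complete block design.

    Within-subject average ranks with the standard tie correction::

        chi2 = [ 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1) ] / C

    where ``R_j`` are rank sums and ``C = 1 - sum(t^3 - t) / (n k (k^2-1))``
    over tie groups.  p comes from chi-square with k-1 df.  If every row is
    constant the statistic is 0 and p = 1.
    """
    m = data.matrix
    n, k = m.shape
    ranks = _within_subject_ranks(m)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)

    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied
        return 0.0, 1.0
    stat /= correction
    p = float(sps.chi2.sf(stat, df=k - 1))
    return float(stat), p


def conover_posthoc(data: RepeatedMeasures) -> np.ndarray:
    """Conover's pairwise post-hoc test for the Friedman design.

    Uses the squared-rank (tie-robust) form: with individual within-subject
    ranks ``r_ij``, rank sums ``R_j``, ``A = sum r_ij^2`` and
    ``B = (1/n) sum_j R_j^2``, the statistic for conditions u, v is::

        t = (R_u - R_v) / sqrt( 2 n (A - B) / ((n-1)(k-1)) )

    which is Student-t with (n-1)(k-1) df.  Returns the symmetric matrix of
    two-sided p-values (diagonal 1); identical conditions give p = 1.  When
    the within-rank variance is exhausted (A = B, i.e. every subject ranks
    the conditions identically), the statistic diverges: p = 1 for equal
    rank sums and p = 0 otherwise.
    """
    m = data.matrix
    n, k = m.shape
    ranks = _within_subject_ranks(m)
    rank_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    b = float((rank_sums**2).sum()) / n
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (a - b) / df
    p = np.ones((k, k))
    for u in range(k):
        for v in range(u + 1, k):
            if denom_sq <= 0:
                # perfectly consistent rankings: t diverges unless tied
                pv = 1.0 if rank_sums[u] == rank_sums[v] else 0.0
            else:
                t = (rank_sums[u] - rank_sums[v]) / np.sqrt(denom_sq)
                pv = float(2.0 * sps.t.sf(abs(t), df=df))
            p[u, v] = p[v, u] = min(pv, 1.0)
    return p


def bonferroni(
    p_values: np.ndarray, m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction over ``m`` comparisons.

    Returns (adjusted p = min(1, p*m), significance flags p < alpha/m).
    With alpha 0.05: m = 6 gives the 0.008 threshold, m = 3 gives 0.017.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    adjusted = np.minimum(p * m, 1.0)
    return adjusted, p < alpha / m


def paired_signflip_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Two-sided sign-flip permutation p for the paired mean difference.

    Under exchangeability of (a_i - b_i) signs, the null distribution of
    |mean(a - b)| is enumerated exactly when 2^n <= n_perm, otherwise
    sampled with ``seed`` (required then), using the add-one Monte Carlo
    estimator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1-D arrays (n >= 2)")
    d = a - b
    n = d.size
    obs = abs(d.mean())
    if 2**n <= n_perm:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 2 * bits - 1
        means = np.abs((signs * d).mean(axis=1))
        return float((means >= obs - 1e-12).mean())
    if seed is None:
        raise ValueError("seed is required for Monte-Carlo permutation")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs((signs * d).mean(axis=1))
    exceed = int((means >= obs - 1e-12).sum())
    return float((1 + exceed) / (1 + n_perm))
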