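"""Statistics layer used across the pipeline.

Implements the study's four statistical procedures for contrasting mutation
burdens between exposure groups:

* Poisson generalized estimating equations (GEE) with an exchangeable working
  correlation and cluster-robust (sandwich) variance, for per-offspring
  SNV/indel counts clustered by sire;
* one-tailed Fisher exact tests for CNV event frequencies;
* the modified-Wald (Agresti-Coull) binomial confidence interval for CNV
  frequencies and exact (chi-square inversion) Poisson intervals for SNV
  rates;
* the Holm-Sidak step-down multiple-testing adjustment. By default adjusted
  p-values are *not* monotonized across ranks (``monotonize=False``), which is
  the raw step-down formula; pass ``monotonize=True`` for the usual
  non-decreasing variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GeeResult",
    "gee_poisson",
    "fisher_one_tailed",
    "modified_wald_ci",
    "sidak_stepdown",
    "poisson_rate_ci",
]


@dataclass(frozen=True)
class GeeResult:
    """Fitted treated-vs-control contrast from a Poisson GEE."""

    rate_ratio: float
    log_rate_ratio: float
    robust_se: float
    p_value: float
    n_clusters: int


def gee_poisson(
    counts: Sequence[int],
    treated: Sequence[bool],
    clusters: Sequence,
    cov_struct: str = "exchangeable",
) -> GeeResult:
    """Poisson GEE for clustered per-offspring counts.

    Log-link Poisson estimating equations with a working correlation shared
    within clusters (sires) and sandwich variance; the returned p-value is the
    two-sided robust Wald test of the treated-vs-control log rate ratio.

    Parameters
    ----------
    counts : per-offspring mutation counts (non-negative integers)
    treated : group indicator per offspring
    clusters : cluster (sire) label per offspring
    cov_struct : "exchangeable" (default) or "independence"
    """
    y = np.asarray(counts, dtype=float)
    g = np.asarray(treated, dtype=float)
    cl = np.asarray(clusters)
    if y.ndim != 1 or len(y) != len(g) or len(y) != len(cl):
        raise ValueError("counts, treated and clusters must be equal-length 1-D")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    for grp in (0.0, 1.0):
        if y[g == grp].sum() == 0:
            raise ValueError("all-zero group: Poisson GEE contrast is degenerate")
        if len(np.unique(cl[g == grp])) < 2:
            raise ValueError("need >= 2 clusters per group")
    exog = sm.add_constant(g)
    cov = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[cov_struct]()
    model = sm.GEE(y, exog, groups=cl, family=sm.families.Poisson(), cov_struct=cov)
    res = model.fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    return GeeResult(
        rate_ratio=float(np.exp(beta)),
        log_rate_ratio=beta,
        robust_se=se,
        p_value=p,
        n_clusters=len(np.unique(cl)),
    )


def fisher_one_tailed(x1: int, n1: int, x2: int, n2: int, direction: str = "greater") -> float:
    """One-tailed Fisher exact P for event frequencies x1/n1 vs x2/n2.

    ``direction="greater"`` tests whether group 1's frequency is higher than
    group 2's (upper hypergeometric tail); ``"less"`` the reverse.
    """
    for v in (x1, n1, x2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if x1 > n1 or x2 > n2:
        raise ValueError("events cannot exceed trials")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    res = sps.fisher_exact(table, alternative=direction)
    return float(res.pvalue)


def modified_wald_ci(x: int, n: int, z: float = 1.96) -> Tuple[float, float]:
    """Modified-Wald (Agresti-Coull) 95% CI for a binomial proportion.

    Center (x + z^2/2)/(n + z^2), half-width z*sqrt(center*(1-center)/(n+z^2)),
    truncated to [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    denom = n + z * z
    center = (x + z * z / 2.0) / denom
    half = z * np.sqrt(center * (1.0 - center) / denom)
    return (max(0.0, center - half), min(1.0, center + half))


def sidak_stepdown(p_values: Sequence[float], monotonize: bool = False) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    With m tests in ascending order of p (rank i = 1..m, ties resolved by
    input order), adjusted p = 1 - (1 - p)^(m - i + 1). ``monotonize=True``
    additionally enforces non-decreasing adjusted values along the ranks
    (running maximum); the default leaves the raw step-down values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        if monotonize:
            running = max(running, a)
            a = running
        adj[idx] = a
    return adj


def poisson_rate_ci(count: int, exposure: float, conf: float = 0.95) -> Tuple[float, float]:
    """Exact Poisson CI for a rate = count / exposure (chi-square inversion)."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    alpha = 1.0 - conf
    lower = 0.0 if count == 0 else sps.chi2.ppf(alpha / 2.0, 2 * count) / 2.0
    upper = sps.chi2.ppf(1.0 - alpha / 2.0, 2 * count + 2) / 2.0
    return (lower / exposure, upper / exposure)
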