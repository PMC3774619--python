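"""Two-sample comparisons: Mann-Whitney U (asymptotic) and Cohen's d."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankTestResult", "mann_whitney", "cohens_d"]


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney result; ``u`` is min(U1, U2) (the SPSS convention)."""

    u: float
    z: float
    p_two_sided: float
    n1: int
    n2: int


def mann_whitney(a, b, exact: bool = False) -> RankTestResult:
    """Mann-Whitney U with a tie-corrected normal approximation.

    U1 counts, over all (a_i, b_j) pairs, wins for the first sample with
    half-credit for ties; the reported statistic is ``min(U1, U2)``.  The
    p-value is two-sided from the normal approximation with tie-corrected
    variance and *no* continuity correction (the convention of the
    era's statistical packages); ``exact=True`` switches to the exact
    permutation null (small samples, no ties handled by scipy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    # U1 via midranks (equivalent to pair counting with half-credit ties)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if exact:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
        return RankTestResult(u=float(u), z=float("nan"), p_two_sided=p, n1=n1, n2=n2)
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        raise ValueError("degenerate data: zero variance of U (all values tied)")
    z = (u1 - mean_u) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankTestResult(u=float(u), z=float(z), p_two_sided=p, n1=n1, n2=n2)


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (n1 + n2 - 2)-denominator SD.

    Sign follows the argument order: positive when mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("degenerate data: zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(s2))
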