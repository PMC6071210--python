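"""One-sided nonparametric comparisons used by the pipeline report.

All p-values are one-sided: conservation of MXE-flanking introns is
tested greater than controls (Mann-Whitney), delta-sigma greater than
zero and ΔΔG less than zero (Wilcoxon signed-rank, zero differences
dropped), and the exon-intron similarity relationship by a Pearson
correlation with a one-sided t-test. Rank tests use the normal
approximation with tie correction and no finite-population correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_one_sided: float
    n: int
    direction: str  # 'greater' or 'less'

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")


def mann_whitney_one_sided(
    a: list[float], b: list[float], direction: str = "greater"
) -> TestResult:
    """Rank-sum test of a vs b (normal approximation, tie-corrected).

    Degenerate all-tied input yields p = 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=a.size * b.size / 2.0, p_one_sided=0.5,
                          n=int(a.size + b.size), direction=direction)
    res = sps.mannwhitneyu(a, b, alternative=direction, method="asymptotic")
    return TestResult(statistic=float(res.statistic),
                      p_one_sided=float(res.pvalue),
                      n=int(a.size + b.size), direction=direction)


def wilcoxon_signed_rank_one_sided(
    d: list[float], direction: str = "greater"
) -> TestResult:
    """Signed-rank test of paired differences against zero.

    Zero differences are dropped; if all differences are zero the result
    is p = 0.5 with n = 0.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(statistic=0.0, p_one_sided=0.5, n=0,
                          direction=direction)
    res = sps.wilcoxon(nz, alternative=direction, method="approx",
                       correction=False, zero_method="wilcox")
    return TestResult(statistic=float(res.statistic),
                      p_one_sided=float(res.pvalue),
                      n=int(nz.size), direction=direction)


def pearson_p_from_r(r: float, n: int, direction: str = "greater") -> float:
    """One-sided p for a Pearson correlation r at sample size n,
    via t = r sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(sps.t.sf(t, df=n - 2) if direction == "greater"
                 else sps.t.cdf(t, df=n - 2))


def pearson_r_t_test(
    x: list[float], y: list[float], direction: str = "greater"
) -> TestResult:
    """Pearson correlation with a one-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0 if (r > 0) == (direction == "greater") else 1.0
        return TestResult(statistic=r, p_one_sided=p, n=int(x.size),
                          direction=direction)
    return TestResult(statistic=r,
                      p_one_sided=pearson_p_from_r(r, int(x.size), direction),
                      n=int(x.size), direction=direction)
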