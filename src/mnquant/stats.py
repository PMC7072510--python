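"""Two-sample tests used to compare micronucleus results between conditions.

Mann–Whitney compares the rank order of replicate micronucleus frequencies
between two conditions (e.g. gene-silenced vs siControl); the two-sample
Kolmogorov–Smirnov test compares cumulative distributions of micronuclear
sizes. Replicate groups in this assay are tiny (typically triplicates), so
the Mann–Whitney p-value is computed by exact enumeration whenever the
combined sample is small (n1 + n2 ≤ 16) and tie-free; ties or larger
samples fall back to the normal approximation with tie-corrected variance
and continuity correction. No multiple-testing correction is applied: each
comparison is reported against a fixed α, mirroring common practice for
per-cell-line tests (see docs for the limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney", "ks_two_sample", "EXACT_MW_LIMIT"]

#: Exact enumeration is used when n1 + n2 is at or below this limit (and the
#: pooled sample is tie-free); C(16, 8) = 12870 keeps full enumeration cheap.
EXACT_MW_LIMIT = 16

_SIDED = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``method`` is one of ``MW-exact`` (exact permutation null), ``MW-normal``
    (normal approximation with tie correction and continuity correction) or
    ``KS`` (asymptotic Kolmogorov–Smirnov). Exact Mann–Whitney p-values are
    rational with denominator dividing C(n1+n2, n1).
    """

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    sided: str = "two"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"sample {name} must be a non-empty 1-D sequence")
    return arr


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 sided: str = "two") -> TestResult:
    """Mann–Whitney U rank test between samples *x* and *y*.

    The U statistic is computed from rank sums with midranks for ties.
    When ``n1 + n2 <= 16`` and the pooled sample is tie-free, the p-value is
    exact (full enumeration of all C(n1+n2, n1) rank assignments; two-sided
    p = min(1, 2 × one-sided)); otherwise the normal approximation with
    tie-corrected variance and continuity correction is used. ``sided``
    alternatives are with respect to *x*: ``greater`` means x tends larger.
    """
    if sided not in _SIDED:
        raise ValueError(f"sided must be one of {sorted(_SIDED)}")
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (n1 + n2 <= EXACT_MW_LIMIT) and not has_ties
    res = sps.mannwhitneyu(
        xa, ya,
        alternative=_SIDED[sided],
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="MW-exact" if exact else "MW-normal",
        n1=n1,
        n2=n2,
        sided=sided,
    )


def ks_two_sample(sizes_a: Sequence[float], sizes_b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test on e.g. micronuclear size samples.

    The statistic is D = sup |ECDF_a − ECDF_b|; the p-value comes from the
    asymptotic KS distribution with the effective sample size
    n1·n2/(n1+n2).
    """
    a, b = _as_sample(sizes_a, "sizes_a"), _as_sample(sizes_b, "sizes_b")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="KS",
        n1=a.size,
        n2=b.size,
        sided="two",
    )
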