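"""Immune-phenotype classification and nonparametric group statistics.

Samples are called immune-infiltrated when their CD3+ T cell density
(or an estimated T cell abundance score) exceeds the median of the
non-leukemic controls; ties at the cutoff are conservatively called
immune-depleted.  Group comparisons use the Mann-Whitney U test,
Kruskal-Wallis with Dunn's post-hoc comparisons (Bonferroni-adjusted),
and Spearman correlation with a Fisher-z confidence interval.

Significance thresholds are configuration, not constants: alpha = 0.01
for region-level (spatial) comparisons, which corrects for measuring
multiple regions from the same biopsy, and alpha = 0.05 elsewhere.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st

from ._util import Undefined

ALPHA_SPATIAL = 0.01
ALPHA_DEFAULT = 0.05

LABEL_INFILTRATED = "IMMUNE_INFILTRATED"
LABEL_DEPLETED = "IMMUNE_DEPLETED"


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    metric: float
    cutoff: float
    label: str


@dataclass
class TestResult:
    """One statistical test, exported as one tidy table row."""

    test: str
    statistic_name: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    groups: tuple[str, ...] = ()
    adjustment: str | None = None
    pvalue_adjusted: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    estimate: float | None = None
    alpha: float = ALPHA_DEFAULT
    method_detail: str | None = None

    @property
    def significant(self) -> bool:
        p = self.pvalue_adjusted if self.pvalue_adjusted is not None else self.pvalue
        return p < self.alpha

    def row(self) -> dict:
        return {
            "test": self.test, "groups": "|".join(self.groups),
            "n": "|".join(str(k) for k in self.n),
            "statistic_name": self.statistic_name, "statistic": self.statistic,
            "estimate": self.estimate, "p": self.pvalue,
            "p_adjusted": self.pvalue_adjusted, "adjustment": self.adjustment,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "alpha_used": self.alpha, "significant": self.significant,
        }


def classify_immune_phenotype(sample_metrics: Mapping[str, float],
                              control_values: Sequence[float],
                              ) -> tuple[float, list[PhenotypeCall]]:
    """Call samples immune-infiltrated vs immune-depleted.

    The cutoff is the median of the control values (mean of the two
    middle order statistics for even n).  A sample is infiltrated iff
    its metric is strictly above the cutoff; a tie is depleted.
    Returns ``(cutoff, calls)``.
    """
    control_values = np.asarray(list(control_values), dtype=float)
    if control_values.size == 0:
        raise ValueError("need at least one control value to define the cutoff")
    cutoff = float(np.median(control_values))
    calls = [
        PhenotypeCall(sample_id=str(sid), metric=float(v), cutoff=cutoff,
                      label=LABEL_INFILTRATED if v > cutoff else LABEL_DEPLETED)
        for sid, v in sample_metrics.items()
    ]
    return cutoff, calls


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 alternative: str = "two-sided",
                 alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most 8
    observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size <= 8 and b.size <= 8 and not _has_ties(np.concatenate([a, b]))
    method = "exact" if exact else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(test="mann_whitney", statistic_name="U",
                      statistic=float(res.statistic), pvalue=float(res.pvalue),
                      n=(a.size, b.size), alpha=alpha, method_detail=method)


def _kruskal_h(groups: Sequence[np.ndarray]) -> tuple[float, float, int]:
    """Tie-corrected Kruskal-Wallis H, its p-value and N.

    All-tied input (zero rank variance) is defined as H = 0, p = 1.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if len(np.unique(pooled)) == 1:
        return 0.0, 1.0, n_total
    h, p = st.kruskal(*groups)
    return float(h), float(p), n_total


@dataclass
class KruskalDunnResult:
    omnibus: TestResult
    pairwise: list[TestResult] = field(default_factory=list)

    def rows(self) -> list[dict]:
        return [self.omnibus.row()] + [t.row() for t in self.pairwise]


def kruskal_dunn(groups: Mapping[str, Sequence[float]],
                 alpha: float = ALPHA_DEFAULT) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise comparisons.

    Dunn's z statistics are computed from pooled mean ranks with the
    tie correction ``sum(t^3 - t) / (12 (N - 1))`` subtracted from the
    rank variance ``N (N + 1) / 12``; two-sided p-values are multiplied
    by the number of pairwise comparisons (Bonferroni) and capped at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(list(groups[g]), dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")

    h, p, n_total = _kruskal_h(arrays)
    omnibus = TestResult(test="kruskal_wallis", statistic_name="H", statistic=h,
                         pvalue=p, n=tuple(a.size for a in arrays),
                         groups=tuple(names), alpha=alpha)

    pooled = np.concatenate(arrays)
    ranks = st.rankdata(pooled)
    offsets = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    if n_total > 1:
        var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    else:  # pragma: no cover - single observation total
        var_core = 0.0

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        se2 = var_core * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if se2 <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
            p_raw = 2.0 * st.norm.sf(abs(z))
        pairwise.append(TestResult(
            test="dunn", statistic_name="z", statistic=float(z), pvalue=float(p_raw),
            n=(arrays[i].size, arrays[j].size), groups=(names[i], names[j]),
            adjustment=f"bonferroni_x{m}",
            pvalue_adjusted=min(1.0, p_raw * m), alpha=alpha))
    return KruskalDunnResult(omnibus=omnibus, pairwise=pairwise)


def fisher_z_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``tanh(atanh(r) +- z_{(1+c)/2} / sqrt(n - 3))``.  For example
    r = -0.75 at n = 23 gives approximately (-0.89, -0.49).
    """
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    z = math.atanh(r)
    half = st.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for Spearman r (small n, any ties)."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    denom = math.sqrt(float(np.sum(xc ** 2)) * float(np.sum((y_ranks - y_ranks.mean()) ** 2)))
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(y_ranks):
        yc = np.asarray(perm) - y_ranks.mean()
        r = float(np.dot(xc, yc)) / denom
        if abs(r) >= abs(r_obs) - tol:
            count += 1
        total += 1
    return count / total


def spearman_ci(x: Sequence[float], y: Sequence[float],
                confidence: float = 0.95,
                alpha: float = ALPHA_DEFAULT) -> TestResult | Undefined:
    """Spearman rank correlation with a Fisher-z confidence interval.

    r uses average ranks for ties.  The p-value is an exact permutation
    enumeration for n <= 8 and the t approximation otherwise.  Constant
    input vectors make the correlation undefined.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return Undefined("constant input vector: correlation undefined")
    r, p_t = st.spearmanr(x, y)
    r = float(r)
    if n <= 8:
        xr, yr = st.rankdata(x), st.rankdata(y)
        p = _spearman_exact_p(xr, yr, r)
        detail = "exact_permutation"
    else:
        p = float(p_t)
        detail = "t_approximation"
    lo, hi = fisher_z_ci(r, n, confidence)
    return TestResult(test="spearman", statistic_name="r", statistic=r,
                      estimate=r, pvalue=p, n=(n,), ci_low=lo, ci_high=hi,
                      alpha=alpha, method_detail=detail)
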