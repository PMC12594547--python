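"""Nonparametric statistics and power framework for the longitudinal study.

Paired comparisons use the Wilcoxon signed-rank test (zeros dropped,
Wilcoxon's original treatment), between-group comparisons the
Mann-Whitney U test; p-values are Bonferroni-adjusted within one output
table.  Effect sizes are Hodges-Lehmann median differences with
rank-test-inverted confidence intervals and Hedges' bias-corrected g;
sample size and minimum detectable difference follow the two-sample
normal-approximation formulas.

Exact two-sided p-values are computed from the full null distributions
of W and U, built once per sample size by dynamic programming and
cached, which keeps 10^4-replicate calibration runs fast.  The exact
branch applies for n <= 25 (signed rank) and n1 + n2 <= 20 (U test)
when the data are tie-free; otherwise the normal approximation with tie
and continuity corrections is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bonferroni",
    "HLResult",
    "hodges_lehmann_two_sample",
    "hodges_lehmann_paired",
    "hedges_g",
    "pooled_sd",
    "sample_size_two_sample",
    "minimum_detectable_difference",
    "Comparison",
    "StudyPlan",
    "ComparisonResult",
    "run_study_analysis",
]

_EXACT_W_MAX_N = 25
_EXACT_U_MAX_N = 20


# ---------------------------------------------------------------------------
# exact null distributions (dynamic programming, cached per sample size)


@lru_cache(maxsize=64)
def _signed_rank_pmf(n: int) -> np.ndarray:
    """Counts of the signed-rank statistic W over the 2^n sign patterns."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts += shifted
    return counts / counts.sum()


@lru_cache(maxsize=64)
def _mann_whitney_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of U over the C(n1+n2, n1) rank arrangements."""
    # c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1): condition on whether
    # the largest pooled value is an x (beats all n ys) or a y.
    max_u = n1 * n2
    # table[m] = counts over u for (m, current n); build up n = 0..n2
    table = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        table[m][0] = 1.0  # n = 0: U must be 0
    for n in range(1, n2 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
        new[0][0] = 1.0
        for m in range(1, n1 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[n:] = new[m - 1][: max_u + 1 - n] if n <= max_u else 0.0
            new[m] = shifted + table[m]
        table = new
    counts = table[n1]
    return counts / counts.sum()


def _two_sided_exact_p(stat: float, pmf: np.ndarray) -> float:
    k = np.arange(len(pmf))
    lower = pmf[k <= stat + 1e-9].sum()
    upper = pmf[k >= stat - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# rank tests


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking.  Returns (W, p) with W
    the sum of positive ranks.  Exact enumeration p for tie-free samples
    with n <= 25; otherwise normal approximation with tie and continuity
    corrections.  All-zero differences give p = 1 with a warning.
    """
    d = np.asarray(differences, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_pos = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= _EXACT_W_MAX_N and not has_ties:
        return w_pos, _two_sided_exact_p(w_pos, _signed_rank_pmf(n))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return w_pos, 1.0
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return w_pos, float(min(1.0, p))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U counted for the first sample.  Exact
    enumeration for tie-free samples with n1 + n2 <= 20; otherwise
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= _EXACT_U_MAX_N and not has_ties:
        return u1, _two_sided_exact_p(u1, _mann_whitney_pmf(n1, n2))
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u1, float(min(1.0, p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``; m defaults to len(p)."""
    p = np.asarray(p_values, float)
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, m_eff * p)


# ---------------------------------------------------------------------------
# Hodges-Lehmann estimates with rank-inversion CIs


@dataclass
class HLResult:
    estimate: float
    ci_low: float
    ci_high: float
    conf: float
    achieved_conf: float


def _critical_rank(pmf: np.ndarray, alpha_half: float) -> int:
    """Largest k with P(stat <= k - 1) <= alpha/2 (k >= 1)."""
    cdf = np.cumsum(pmf)
    k = int(np.searchsorted(cdf, alpha_half, side="right"))  # P(stat <= k-1) <= a/2
    return max(k, 1)


def hodges_lehmann_two_sample(x, y, conf: float = 0.95) -> HLResult:
    """Hodges-Lehmann shift of ``y`` relative to ``x`` with a rank-inverted CI.

    The estimate is the median of all n1*n2 pairwise differences
    ``y_j - x_i``; CI bounds are order statistics of the sorted
    differences at ranks from inverting the Mann-Whitney null
    distribution (exact pmf for n1 + n2 <= 40, normal approximation
    beyond).  If the requested confidence is unattainable at these
    sample sizes the widest achievable interval is returned with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per sample")
    diffs = np.sort((y[:, None] - x[None, :]).ravel())
    m = n1 * n2
    alpha = 1.0 - conf
    if n1 + n2 <= 40:
        pmf = _mann_whitney_pmf(n1, n2)
        k = _critical_rank(pmf, alpha / 2.0)
        cdf = np.cumsum(pmf)
        # coverage of [D_(k), D_(m+1-k)] is 1 - 2 P(U <= k - 1)
        achieved = 1.0 - 2.0 * float(cdf[k - 1])
        if achieved < conf:
            warnings.warn("requested confidence unattainable; returning widest interval")
    else:
        mu = m / 2.0
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        k = int(math.floor(mu - sps.norm.ppf(1 - alpha / 2.0) * sigma))
        k = max(k, 1)
        achieved = conf
    return HLResult(
        estimate=float(np.median(diffs)),
        ci_low=float(diffs[k - 1]),
        ci_high=float(diffs[m - k]),
        conf=conf,
        achieved_conf=float(achieved),
    )


def hodges_lehmann_paired(differences, conf: float = 0.95) -> HLResult:
    """Paired Hodges-Lehmann estimate: median of Walsh averages, with the
    signed-rank-inverted CI."""
    d = np.asarray(differences, float)
    n = len(d)
    if n < 2:
        raise ValueError("need n >= 2 paired differences")
    walsh = np.sort(((d[:, None] + d[None, :]) / 2.0)[np.triu_indices(n)])
    m = len(walsh)  # n(n+1)/2
    alpha = 1.0 - conf
    if n <= _EXACT_W_MAX_N:
        pmf = _signed_rank_pmf(n)
        k = _critical_rank(pmf, alpha / 2.0)
        cdf = np.cumsum(pmf)
        achieved = 1.0 - 2.0 * float(cdf[k - 1])
        if achieved < conf:
            warnings.warn("requested confidence unattainable; returning widest interval")
    else:
        mu = m / 2.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = max(int(math.floor(mu - sps.norm.ppf(1 - alpha / 2.0) * sigma)), 1)
        achieved = conf
    return HLResult(
        estimate=float(np.median(walsh)),
        ci_low=float(walsh[k - 1]),
        ci_high=float(walsh[m - k]),
        conf=conf,
        achieved_conf=float(achieved),
    )


# ---------------------------------------------------------------------------
# effect size and power


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Pooled standard deviation of two groups."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def hedges_g(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> float:
    """Hedges' bias-corrected standardized mean difference.

    ``g = d * (1 - 3 / (4 df - 1))`` with ``d`` Cohen's d on the pooled
    SD and ``df = n1 + n2 - 2``.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    sp = pooled_sd(sd1, n1, sd2, n2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    d = (mean1 - mean2) / sp
    df = n1 + n2 - 2
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))


def sample_size_two_sample(
    effect_size_g: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "normal",
) -> int:
    """Per-group n for a two-sample comparison at the given effect size.

    The default normal-approximation formula is
    ``n = ceil(2 * ((z_{1-alpha/2} + z_{power}) / g)^2)``; ``method="nct"``
    solves the noncentral-t power equation instead (typically one animal
    more at moderate effects).
    """
    if effect_size_g <= 0:
        raise ValueError("effect size must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if method == "normal":
        z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
        return int(math.ceil(2.0 * (z / effect_size_g) ** 2))
    if method == "nct":
        for n in range(2, 10_000):
            df = 2 * n - 2
            nc = effect_size_g * math.sqrt(n / 2.0)
            crit = sps.t.ppf(1.0 - alpha / 2.0, df)
            achieved = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
            if achieved >= power:
                return n
        raise ValueError("no attainable n below 10000")
    raise ValueError("method must be 'normal' or 'nct'")


def minimum_detectable_difference(
    n_per_group: int, sd: float, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest detectable two-sample mean difference in metric units:
    ``MDD = (z_{1-alpha/2} + z_{power}) * sd * sqrt(2 / n)``."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    return float(z * sd * math.sqrt(2.0 / n_per_group))


# ---------------------------------------------------------------------------
# study-level analysis


@dataclass(frozen=True)
class Comparison:
    """One cell of a results table.

    ``kind`` is ``"paired_days"`` (within one group between two days,
    signed-rank) or ``"between_groups"`` (two groups at one day, U
    test).  ``site`` is a site name or ``"pooled"`` (per-animal mean of
    the sites before testing).
    """

    metric: str
    kind: str
    site: str = "pooled"
    group: str | None = None
    groups: tuple[str, str] | None = None
    days: tuple[int, int] | None = None
    day: int | None = None
    label: str | None = None

    def describe(self) -> str:
        if self.label:
            return self.label
        if self.kind == "paired_days":
            return f"{self.metric} {self.group} d{self.days[0]}-d{self.days[1]} ({self.site})"
        return f"{self.metric} {self.groups[0]} vs {self.groups[1]} d{self.day} ({self.site})"


@dataclass(frozen=True)
class StudyPlan:
    """A family of comparisons adjusted together (one output table)."""

    comparisons: tuple[Comparison, ...]
    conf: float = 0.95

    @staticmethod
    def within_groups(
        metric: str,
        groups,
        days: tuple[int, int] = (0, 28),
        sites=("pooled",),
    ) -> "StudyPlan":
        comps = tuple(
            Comparison(metric=metric, kind="paired_days", group=g, days=days, site=s)
            for g in groups
            for s in sites
        )
        return StudyPlan(comparisons=comps)

    @staticmethod
    def between_groups(
        metric: str,
        pairs,
        day: int = 28,
        sites=("pooled",),
    ) -> "StudyPlan":
        comps = tuple(
            Comparison(metric=metric, kind="between_groups", groups=tuple(p), day=day, site=s)
            for p in pairs
            for s in sites
        )
        return StudyPlan(comparisons=comps)


@dataclass
class ComparisonResult:
    comparison: str
    method: str
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    hl_estimate: float | None
    hl_ci_low: float | None
    hl_ci_high: float | None
    n1: int
    n2: int
    note: str = ""


def _site_values(df: pd.DataFrame, site: str) -> pd.DataFrame:
    """Per-animal values at one site (or the per-animal mean over sites)."""
    if site == "pooled":
        return (
            df.groupby(["animal_id", "group", "day", "metric"], as_index=False)["value"]
            .mean()
        )
    return df[df["site"] == site][["animal_id", "group", "day", "metric", "value"]]


def run_study_analysis(cohort: pd.DataFrame, plan: StudyPlan) -> pd.DataFrame:
    """Evaluate every comparison of a plan on a long-format cohort table.

    Returns one row per plan cell with the test statistic, raw and
    Bonferroni-adjusted p (family = the whole plan), the Hodges-Lehmann
    estimate with CI, and sample sizes; cells that cannot be evaluated
    (missing pairs) carry a note and NA values and still count toward
    the family size.
    """
    required = {"animal_id", "group", "site", "day", "metric", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    dup = cohort.duplicated(["animal_id", "group", "site", "day", "metric"])
    if dup.any():
        raise ValueError("duplicate (animal, group, site, day, metric) records")
    results: list[ComparisonResult] = []
    for comp in plan.comparisons:
        sub = _site_values(cohort[cohort["metric"] == comp.metric], comp.site)
        if comp.kind == "paired_days":
            d0, d1 = comp.days
            g = sub[sub["group"] == comp.group]
            merged = pd.merge(
                g[g["day"] == d0][["animal_id", "value"]],
                g[g["day"] == d1][["animal_id", "value"]],
                on="animal_id",
                suffixes=("_0", "_1"),
            )
            if len(merged) < 2:
                results.append(
                    ComparisonResult(
                        comp.describe(), "wilcoxon_signed_rank", None, None, None,
                        None, None, None, len(merged), len(merged), note="missing pairs",
                    )
                )
                continue
            diffs = (merged["value_1"] - merged["value_0"]).to_numpy()
            stat, p = wilcoxon_signed_rank(diffs)
            hl = hodges_lehmann_paired(diffs, conf=plan.conf)
            results.append(
                ComparisonResult(
                    comp.describe(), "wilcoxon_signed_rank", stat, p, None,
                    hl.estimate, hl.ci_low, hl.ci_high, len(diffs), len(diffs),
                )
            )
        elif comp.kind == "between_groups":
            ga, gb = comp.groups
            a = sub[(sub["group"] == ga) & (sub["day"] == comp.day)]["value"].to_numpy()
            b = sub[(sub["group"] == gb) & (sub["day"] == comp.day)]["value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                results.append(
                    ComparisonResult(
                        comp.describe(), "mann_whitney_u", None, None, None,
                        None, None, None, len(a), len(b), note="missing group data",
                    )
                )
                continue
            stat, p = mann_whitney_u(a, b)
            hl = hodges_lehmann_two_sample(a, b, conf=plan.conf)  # shift of gb vs ga
            results.append(
                ComparisonResult(
                    comp.describe(), "mann_whitney_u", stat, p, None,
                    hl.estimate, hl.ci_low, hl.ci_high, len(a), len(b),
                )
            )
        else:
            raise ValueError(f"unknown comparison kind {comp.kind!r}")
    m = len(plan.comparisons)
    for r in results:
        if r.p_raw is not None:
            r.p_adjusted = float(min(1.0, m * r.p_raw))
    return pd.DataFrame([r.__dict__ for r in results])
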