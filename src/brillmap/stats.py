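"""Small-sample nonparametric test suite with explicit effect sizes.

Implements the exact flavors needed for cohorts of 4-5 animals:

* Friedman rank test (chi-square approximation) + Dunn's post hoc +
  Kendall's W
* Kruskal-Wallis with tie correction + Dunn's post hoc + eta-squared
* Mann-Whitney U with exact enumeration p-value and continuity-corrected Z
  + effect size r = |Z| / sqrt(N)
* pooled-variance two-sample t-test
* Chen-Shapiro normality statistic with Monte-Carlo critical values
* a test-selection policy mirroring small-sample practice

All rank computations use midranks (average ranks for ties).  p-values for
Friedman and Kruskal-Wallis come from the chi-square upper tail; Dunn's
pairwise comparisons use two-sided normal p-values with Bonferroni
adjustment over all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepeatedMeasuresTable",
    "GroupSamples",
    "TestResult",
    "PairResult",
    "midrank",
    "friedman",
    "chisq_upper_tail",
    "kendalls_w",
    "dunn_friedman_posthoc",
    "kruskal_wallis",
    "kw_eta_squared",
    "dunn_kw_posthoc",
    "mann_whitney_exact",
    "effect_size_r",
    "students_t_two_sample",
    "chen_shapiro",
    "analysis_policy",
]

CHEN_SHAPIRO_SEED = 20220078
CHEN_SHAPIRO_NULL_SIZE = 10_000


@dataclass(frozen=True)
class RepeatedMeasuresTable:
    """Complete subjects x conditions matrix of values."""

    values: np.ndarray
    subjects: tuple[str, ...] = ()
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2:
            raise ValueError("values must be a 2D subjects x conditions matrix")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if not np.all(np.isfinite(arr)):
            raise ValueError("table must be complete (no missing cells)")
        if not self.subjects:
            object.__setattr__(
                self, "subjects", tuple(f"S{i + 1}" for i in range(n))
            )
        if not self.conditions:
            object.__setattr__(
                self, "conditions", tuple(f"C{j + 1}" for j in range(k))
            )
        if len(self.subjects) != n or len(self.conditions) != k:
            raise ValueError("label lengths must match the matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GroupSamples:
    """k independent groups of observations."""

    groups: tuple[np.ndarray, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = tuple(np.asarray(g, dtype=float) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if any(g.size < 1 for g in groups):
            raise ValueError("every group needs at least one observation")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"G{i + 1}" for i in range(len(groups)))
            )
        if len(self.labels) != len(groups):
            raise ValueError("one label per group required")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(g.size for g in self.groups)

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    z: float
    p_adjusted: float


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float
    df: int | None
    p_value: float
    effect_size: tuple[str, float] | None = None
    posthoc: tuple[PairResult, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic_value": self.statistic_value,
            "df": self.df,
            "p_value": self.p_value,
        }
        if self.effect_size is not None:
            d["effect_size"] = {
                "name": self.effect_size[0],
                "value": self.effect_size[1],
            }
        if self.posthoc:
            d["posthoc"] = [
                {"pair": list(pr.pair), "z": pr.z, "p_adjusted": pr.p_adjusted}
                for pr in self.posthoc
            ]
        return d


def midrank(values) -> np.ndarray:
    """Midranks: ties receive the average of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    return sps.rankdata(arr, method="average")


def chisq_upper_tail(x: float, df: int) -> float:
    """Chi-square survival function P(X >= x)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


def kendalls_w(chi2: float, N_A: int, k: int) -> float:
    """Kendall's W effect size: W = chi2 / (N_A * (k - 1))."""
    if N_A < 2 or k < 2:
        raise ValueError("need N_A >= 2 and k >= 2")
    return chi2 / (N_A * (k - 1))


def _within_subject_ranks(table: RepeatedMeasuresTable) -> np.ndarray:
    return np.apply_along_axis(midrank, 1, table.values)


def friedman(table: RepeatedMeasuresTable) -> TestResult:
    """Friedman rank test for complete repeated measures.

    chi2 = 12 / (N k (k+1)) * sum_j R_j^2 - 3 N (k+1), with within-subject
    midranks and no tie correction; p from the chi-square upper tail at
    df = k - 1 (the classical approximation).  Kendall's W is attached as
    the effect size.
    """
    n, k = table.n_subjects, table.n_conditions
    ranks = _within_subject_ranks(table)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative rounding with full ties
    p = chisq_upper_tail(chi2, k - 1)
    w = kendalls_w(chi2, n, k)
    return TestResult(
        statistic_name="friedman_chi2",
        statistic_value=chi2,
        df=k - 1,
        p_value=p,
        effect_size=("kendalls_W", w),
        posthoc=dunn_friedman_posthoc(table),
    )


def dunn_friedman_posthoc(
    table: RepeatedMeasuresTable, adjust: str = "bonferroni"
) -> tuple[PairResult, ...]:
    """Dunn's pairwise comparisons after a Friedman test.

    z_ij = |Rbar_i - Rbar_j| / sqrt(k (k+1) / (6 N_A)); two-sided normal p,
    Bonferroni-multiplied by the number of pairs, capped at 1.
    """
    if adjust != "bonferroni":
        raise ValueError("only bonferroni adjustment is supported")
    n, k = table.n_subjects, table.n_conditions
    mean_ranks = _within_subject_ranks(table).mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * float(sps.norm.sf(z)) * n_pairs)
        out.append(
            PairResult((table.conditions[i], table.conditions[j]), z, p)
        )
    return tuple(out)


def _tie_sum(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: GroupSamples) -> TestResult:
    """Kruskal-Wallis H test on pooled midranks with tie correction.

    H = [12 / (N (N+1)) * sum_i R_i^2 / n_i - 3 (N+1)] / C where
    C = 1 - sum(t^3 - t) / (N^3 - N); p from chi-square at df = k - 1.
    """
    pooled = np.concatenate(groups.groups)
    N = groups.total_n
    k = len(groups.groups)
    ranks = midrank(pooled)
    H = -3.0 * (N + 1)
    start = 0
    for g in groups.groups:
        r = ranks[start : start + g.size]
        H += 12.0 / (N * (N + 1)) * float(r.sum()) ** 2 / g.size
        start += g.size
    correction = 1.0 - _tie_sum(pooled) / (N**3 - N)
    if correction <= 0:
        raise ValueError("all pooled observations identical")
    H /= correction
    H = max(H, 0.0)
    p = chisq_upper_tail(H, k - 1)
    eta2 = kw_eta_squared(H, k, N)
    return TestResult(
        statistic_name="kruskal_wallis_H",
        statistic_value=H,
        df=k - 1,
        p_value=p,
        effect_size=("eta_squared", eta2),
        posthoc=dunn_kw_posthoc(groups),
    )


def kw_eta_squared(H: float, k: int, N: int) -> float:
    """Kruskal-Wallis effect size eta^2 = (H - k + 1) / (N - k).

    May be negative for small H; reported as computed.
    """
    if N <= k:
        raise ValueError("need N > k")
    return (H - k + 1) / (N - k)


def dunn_kw_posthoc(
    groups: GroupSamples, adjust: str = "bonferroni"
) -> tuple[PairResult, ...]:
    """Dunn's pairwise comparisons after a Kruskal-Wallis test.

    z_ij = |Rbar_i - Rbar_j| / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))] *
    (1/n_i + 1/n_j)); two-sided normal p with Bonferroni over all pairs.
    """
    if adjust != "bonferroni":
        raise ValueError("only bonferroni adjustment is supported")
    pooled = np.concatenate(groups.groups)
    N = groups.total_n
    ranks = midrank(pooled)
    mean_ranks = []
    start = 0
    for g in groups.groups:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        start += g.size
    var_base = N * (N + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (N - 1))
    if var_base <= 0:
        raise ValueError("all pooled observations identical")
    k = len(groups.groups)
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / groups.sizes[i] + 1.0 / groups.sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * float(sps.norm.sf(z)) * n_pairs)
        out.append(PairResult((groups.labels[i], groups.labels[j]), z, p))
    return tuple(out)


def _enumerated_u(pooled_ranks: np.ndarray, n_x: int) -> np.ndarray:
    """U_x over all labelings of the given (possibly tied) midranks."""
    out = []
    for combo in combinations(range(pooled_ranks.size), n_x):
        r_x = pooled_ranks[list(combo)].sum()
        out.append(r_x - n_x * (n_x + 1) / 2.0)
    return np.array(out)


def mann_whitney_exact(x, y, exact_max_n: int = 20) -> TestResult:
    """Mann-Whitney U test, exact by enumeration for small samples.

    U = min(U_x, U_y) from pooled midranks.  The exact two-sided p doubles
    the smaller one-tail probability of U_x over all C(n_x+n_y, n_x)
    labelings (capped at 1).  Beyond ``exact_max_n`` total observations a
    normal approximation with the same continuity-corrected Z is used.
    Z = (U - n_x n_y / 2 +/- 0.5) / sqrt(n_x n_y (n_x+n_y+1) / 12) with the
    0.5 correction applied toward the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    N = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = midrank(pooled)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    u_y = n_x * n_y - u_x
    U = min(u_x, u_y)

    mean_u = n_x * n_y / 2.0
    sd_u = math.sqrt(n_x * n_y * (N + 1) / 12.0)
    if U == mean_u:
        z = 0.0
    else:
        z = (U - mean_u + 0.5) / sd_u  # U = min <= mean, correct upward

    if N <= exact_max_n:
        dist = _enumerated_u(ranks, n_x)
        lower = float(np.mean(dist <= u_x))
        upper = float(np.mean(dist >= u_x))
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "normal"
    r = effect_size_r(z, N)
    return TestResult(
        statistic_name=f"mann_whitney_U_{method}",
        statistic_value=U,
        df=None,
        p_value=p,
        effect_size=("r", r),
        posthoc=(PairResult(("x", "y"), z, p),),
    )


def effect_size_r(Z: float, N: int) -> float:
    """Rank-biserial style effect size r = |Z| / sqrt(N)."""
    if N < 1:
        raise ValueError("N must be positive")
    return abs(Z) / math.sqrt(N)


def students_t_two_sample(x, y) -> TestResult:
    """Two-sided pooled-variance Student's t-test, df = n_x + n_y - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    n_x, n_y = x.size, y.size
    sp2 = ((n_x - 1) * x.var(ddof=1) + (n_y - 1) * y.var(ddof=1)) / (n_x + n_y - 2)
    if sp2 == 0:
        raise ValueError("degenerate input: zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n_x + 1.0 / n_y))
    df = n_x + n_y - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("students_t", float(t), df, min(1.0, p))


def _chen_shapiro_qh(x: np.ndarray) -> float:
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance sample")
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    m = sps.norm.ppf((i - 3.0 / 8.0) / (n + 1.0 / 4.0))  # Blom positions
    return float(np.sum(np.diff(xs) / np.diff(m)) / ((n - 1) * s))


@lru_cache(maxsize=128)
def _chen_shapiro_null(n: int) -> np.ndarray:
    """Seeded Monte-Carlo null distribution of QH for sample size n."""
    rng = np.random.default_rng(CHEN_SHAPIRO_SEED + n)
    draws = rng.standard_normal((CHEN_SHAPIRO_NULL_SIZE, n))
    return np.sort(
        np.array([_chen_shapiro_qh(row) for row in draws])
    )


def chen_shapiro(x, alpha: float = 0.05) -> tuple[float, bool]:
    """Chen-Shapiro normality statistic and lower-tail rejection flag.

    QH = 1/((n-1) s) * sum (x_(i+1) - x_(i)) / (M_(i+1) - M_i) with Blom
    plotting positions M_i = Phi^-1((i - 3/8)/(n + 1/4)).  Under normality
    QH is near 1; departures shrink it, so normality is rejected when QH
    falls below the alpha quantile of a seeded Monte-Carlo null (10^4
    standard-normal samples per n, cached).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    qh = _chen_shapiro_qh(x)
    null = _chen_shapiro_null(x.size)
    critical = float(np.quantile(null, alpha))
    return qh, qh < critical


def analysis_policy(data, alpha: float = 0.05, small_n: int = 30) -> str:
    """Choose the test family for a dataset, mirroring small-sample practice.

    Repeated measures always go to Friedman.  Independent groups go to the
    t-test only when both groups exceed ``small_n`` observations and
    neither rejects Chen-Shapiro normality; otherwise Mann-Whitney (2
    groups) or Kruskal-Wallis (>2 groups).
    """
    if isinstance(data, RepeatedMeasuresTable):
        return "friedman"
    if not isinstance(data, GroupSamples):
        raise TypeError("expected RepeatedMeasuresTable or GroupSamples")
    k = len(data.groups)
    if k > 2:
        return "kruskal_wallis"
    small = any(g.size <= small_n for g in data.groups)
    if small:
        return "mann_whitney"
    normal = all(not chen_shapiro(g, alpha)[1] for g in data.groups)
    return "t_test" if normal else "mann_whitney"
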