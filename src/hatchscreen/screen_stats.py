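"""Adaptive two-sample testing, chi-square goodness of fit, hit calling.

The screen's comparison of per-well hatch proportions selects its test
from distributional diagnostics, the convention of the source screening
protocol: Shapiro-Wilk normality on each group and Levene's test (mean-
centred, as in SPSS) for homogeneity of variance, both at a fixed 0.05
screening level.  The decision tree:

===========  ============  =======================
normal?      homogeneous?  test
===========  ============  =======================
yes          yes           Student t
yes          no            Welch t
no           yes           Mann-Whitney U
no           no            bootstrap-t (Welch statistic, resampled null)
===========  ============  =======================

Pooled egg-count comparisons (vial and mass-mating experiments) instead
use a manual chi-square goodness of fit against the control's observed
hatch rate, judged at a Bonferroni-scaled alpha (base alpha divided by
the number of data categories compared).

Hit calling maps a comparison p-value to "Yes" / "Borderline" / "No":
Yes below the borderline band, Borderline inside [0.04, 0.05), No at or
above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateExpectationError,
    DegenerateVarianceError,
    InsufficientSampleError,
)

TEST_T = "t"
TEST_WELCH = "welch-t"
TEST_MANN_WHITNEY = "mann-whitney-u"
TEST_BOOTSTRAP = "bootstrap-t"
TEST_CHI_SQUARE = "chi-square-gof"

#: Significance level of the Shapiro-Wilk / Levene screening stage.
SCREENING_ALPHA = 0.05

#: Default borderline band for hit calling: Yes below 0.04, Borderline in
#: [0.04, 0.05), No at or above 0.05.
DEFAULT_THRESHOLDS = (0.04, 0.05)

GRADE_YES = "Yes"
GRADE_BORDERLINE = "Borderline"
GRADE_NO = "No"


@dataclass(frozen=True)
class AlphaPolicy:
    """Bonferroni-scaled significance level.

    ``n_categories`` is the number of data categories compared within the
    experiment (e.g. 6 for three-cross comparisons, 4 for the treated-vial
    experiments); the adjusted level is ``alpha / n_categories``.
    """

    alpha: float = 0.05
    n_categories: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def adjusted(self) -> float:
        return self.alpha / self.n_categories


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha_used: float
    n_per_group: tuple[int, ...]
    diagnostics: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_used


@dataclass(frozen=True)
class HitCall:
    treatment: str
    grade: str
    p_value: float


def _as_groups(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientSampleError(
            f"each group needs >= 3 observations, got {a.size} and {b.size}"
        )
    return a, b


def choose_test(a, b, screening_alpha: float = SCREENING_ALPHA) -> tuple[str, dict]:
    """Select the two-sample test from normality/homogeneity diagnostics.

    Returns ``(test_name, diagnostics)`` where the diagnostics carry the
    Shapiro-Wilk p-value per group and the Levene p-value.
    """
    a, b = _as_groups(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateVarianceError(
            "a group has zero variance; distributional screening is undefined"
        )
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    lev = stats.levene(a, b, center="mean").pvalue
    normal = sw_a >= screening_alpha and sw_b >= screening_alpha
    homogeneous = lev >= screening_alpha
    if normal:
        name = TEST_T if homogeneous else TEST_WELCH
    else:
        name = TEST_MANN_WHITNEY if homogeneous else TEST_BOOTSTRAP
    return name, {"shapiro_p": (float(sw_a), float(sw_b)), "levene_p": float(lev)}


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


def bootstrap_t_test(
    a: np.ndarray,
    b: np.ndarray,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided bootstrap approximation to the Welch t-test.

    Both groups are shifted to the grand mean (imposing the null), then
    resampled with replacement within group; the p-value is the fraction
    of resampled |t| statistics at or above the observed |t|, with the
    usual +1 correction so p is never exactly zero.
    """
    rng = rng if rng is not None else np.random.default_rng()
    t_obs = _welch_t(a, b)
    grand = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + grand
    b0 = b - b.mean() + grand
    ra = rng.choice(a0, size=(n_resamples, a.size), replace=True)
    rb = rng.choice(b0, size=(n_resamples, b.size), replace=True)
    va = ra.var(axis=1, ddof=1) / a.size
    vb = rb.var(axis=1, ddof=1) / b.size
    denom = np.sqrt(va + vb)
    # Degenerate resamples (all-equal draws) carry no evidence; count as extreme
    # never (|t*| = 0) unless the observed t is itself 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(denom > 0, (ra.mean(axis=1) - rb.mean(axis=1)) / denom, 0.0)
    p = (1.0 + np.sum(np.abs(t_star) >= abs(t_obs))) / (n_resamples + 1.0)
    return float(t_obs), float(p)


def compare_conditions(
    a,
    b,
    policy: AlphaPolicy | None = None,
    boot_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Adaptive two-sided comparison of two groups of per-well proportions.

    The test is selected by :func:`choose_test`; ``seed`` (int or
    :class:`numpy.random.Generator`) only matters on the bootstrap branch.
    """
    policy = policy or AlphaPolicy()
    a, b = _as_groups(a, b)
    name, diagnostics = choose_test(a, b)
    if name == TEST_T:
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif name == TEST_WELCH:
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif name == TEST_MANN_WHITNEY:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        statistic, p = bootstrap_t_test(a, b, n_resamples=boot_reps, rng=rng)
    return TestResult(
        test_name=name,
        statistic=statistic,
        p_value=p,
        alpha_used=policy.adjusted,
        n_per_group=(a.size, b.size),
        diagnostics=diagnostics,
    )


def chi_square_gof(
    test_counts: tuple[int, int],
    reference_rate: float,
    policy: AlphaPolicy | None = None,
) -> TestResult:
    """Chi-square goodness of fit of (hatched, unhatched) counts to a rate.

    Expected counts are ``total * reference_rate`` and
    ``total * (1 - reference_rate)``; the statistic is the usual
    ``sum((O - E)^2 / E)`` with one degree of freedom.
    """
    policy = policy or AlphaPolicy()
    hatched, unhatched = test_counts
    if hatched < 0 or unhatched < 0:
        raise ValueError("counts must be non-negative")
    total = hatched + unhatched
    if total == 0:
        raise ValueError("total egg count must be positive")
    expected = np.array([total * reference_rate, total * (1.0 - reference_rate)])
    if np.any(expected == 0):
        raise DegenerateExpectationError(
            f"reference rate {reference_rate} yields a zero expected count"
        )
    observed = np.array([hatched, unhatched], dtype=float)
    statistic, p = stats.chisquare(observed, expected)
    return TestResult(
        test_name=TEST_CHI_SQUARE,
        statistic=float(statistic),
        p_value=float(p),
        alpha_used=policy.adjusted,
        n_per_group=(total,),
        diagnostics={"expected": tuple(expected), "reference_rate": reference_rate},
    )


def grade_p_value(p: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Map a p-value to Yes / Borderline / No under (borderline_low, alpha)."""
    borderline_low, alpha = thresholds
    if not 0 < borderline_low < alpha:
        raise ValueError(f"thresholds must satisfy 0 < borderline_low < alpha, got {thresholds}")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0,1], got {p}")
    if p < borderline_low:
        return GRADE_YES
    if p < alpha:
        return GRADE_BORDERLINE
    return GRADE_NO


def classify_hit(
    result: TestResult | float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    treatment: str = "",
) -> HitCall:
    """Classify a comparison as a clear hit, borderline hit, or non-hit."""
    p = result.p_value if isinstance(result, TestResult) else float(result)
    return HitCall(treatment=treatment, grade=grade_p_value(p, thresholds), p_value=p)
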