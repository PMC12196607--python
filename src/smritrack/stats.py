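"""Cohort statistics: volume regression with confidence band, paired-test
gating, effect sizes and Holm–Bonferroni family-wise control.

The comparison workflow for the two primary hypotheses (Dice and
Hausdorff, biomarker vs FLAIR) mirrors common practice in small imaging
cohorts: Shapiro–Wilk on each paired sample and Levene on the pair gate
the choice between a two-tailed paired t-test (both samples normal,
homoscedastic) and a two-tailed Wilcoxon signed-rank test; practical
importance is a paired-sample Cohen's d (mean of differences over SD of
differences); family-wise error across the two hypotheses is controlled
by the Holm–Bonferroni step-down at alpha = 0.05.

The Wilcoxon signed-rank p-value is exact (full null distribution of the
positive-rank sum by subset-sum recursion) for n <= 25 without ties in the
absolute differences, and a tie-corrected normal approximation otherwise.
Zero differences are dropped before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

ALPHA_DEFAULT = 0.05

WILCOXON_EXACT_MAX_N = 25
WILCOXON_MIN_NONZERO = 5


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares of y on x with a 95% mean-response band."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    stderr_estimate: float
    x: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_volume_regression(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> RegressionFit:
    """Simple linear regression of FLAIR volume on biomarker volume.

    Returns slope, intercept, Pearson r, two-tailed p for a non-zero
    slope, the standard error of the estimate, and the pointwise
    ``conf``-level confidence band for the mean regression line evaluated
    at the input x's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise StatisticsError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0:
        raise StatisticsError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    yhat = res.intercept + res.slope * x
    dof = n - 2
    s = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))  # SE of the estimate
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_mean = s * np.sqrt(1.0 / n + (x - x.mean()) ** 2 / sxx)
    tcrit = sps.t.ppf(0.5 + conf / 2.0, dof)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        stderr_estimate=s,
        x=x,
        ci_lower=yhat - tcrit * se_mean,
        ci_upper=yhat + tcrit * se_mean,
    )


def _check_sample(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.size < 3:
        raise StatisticsError(f"{name}: need n >= 3, got {a.size}")
    if np.ptp(a) == 0:
        raise StatisticsError(f"{name}: constant sample")
    return a


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test: (W, p)."""
    a = _check_sample(np.asarray(sample), "shapiro_wilk")
    res = sps.shapiro(a)
    return float(res.statistic), float(res.pvalue)


def levene(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Levene's test for equality of variances: (W, p)."""
    a = _check_sample(np.asarray(sample_a), "levene (a)")
    b = _check_sample(np.asarray(sample_b), "levene (b)")
    res = sps.levene(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Positive-rank sum W+ and the mid-ranks of |d| (zeros already dropped)."""
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Two-sided exact p for integer ranks 1..n via subset-sum recursion.

    counts[s] = number of sign assignments with positive-rank sum s; the
    two-sided p doubles the smaller tail, capped at 1.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    counts /= 2.0 ** n
    w = int(round(w_plus))
    lower = counts[: w + 1].sum()
    upper = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if var <= 0:
        raise StatisticsError("degenerate signed-rank variance (all ties)")
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  With no ties among |differences| and at
    most 25 non-zero pairs the p-value comes from the exact null
    distribution; otherwise from the tie-corrected normal approximation.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise StatisticsError("paired samples must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise StatisticsError("all paired differences are zero")
    if n < WILCOXON_MIN_NONZERO:
        raise StatisticsError(
            f"need >= {WILCOXON_MIN_NONZERO} non-zero differences, got {n}"
        )
    w_plus, ranks = _signed_rank_statistic(diffs)
    has_ties = np.unique(np.abs(diffs)).size < n
    if n <= WILCOXON_EXACT_MAX_N and not has_ties:
        return _exact_signed_rank_p(w_plus, n)
    return _approx_signed_rank_p(w_plus, ranks)


# ---------------------------------------------------------------------------
# Paired t and effect size


def paired_t(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Two-tailed paired t-test p-value."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise StatisticsError("paired samples must have equal length")
    if a.size < 3:
        raise StatisticsError("need at least 3 pairs")
    res = sps.ttest_rel(a, b)
    return float(res.pvalue)


def cohens_d_paired(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Paired-sample Cohen's d: mean(differences) / SD(differences)."""
    d = np.asarray(paired_a, dtype=float) - np.asarray(paired_b, dtype=float)
    if d.size < 3:
        raise StatisticsError("need at least 3 pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise StatisticsError("zero difference SD; Cohen's d undefined")
    return float(np.mean(d)) / sd


def effect_size_label(d: float) -> str:
    """Conventional qualitative cuts: 0.2 small, 0.5 medium, 0.8 large."""
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# Holm–Bonferroni and the two-hypothesis comparison


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = ALPHA_DEFAULT
) -> list[tuple[float, bool]]:
    """Step-down Holm–Bonferroni: per-hypothesis (threshold, reject).

    The i-th smallest p is compared against alpha/(m - i); rejections stop
    at the first failure.  Once the step-down stops, the effective
    threshold no longer grows (later, larger p-values are held to the
    failed step's threshold), so ``reject`` is equivalent to
    ``p <= threshold`` entry-wise.  Results are returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatisticsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    stopped_at: float | None = None
    for i, idx in enumerate(order):
        thr = alpha / (m - i) if stopped_at is None else stopped_at
        thresholds[idx] = thr
        if stopped_at is None and p[idx] <= thr:
            reject[idx] = True
        elif stopped_at is None:
            stopped_at = thr
    return [(float(thresholds[i]), bool(reject[i])) for i in range(m)]


@dataclass(frozen=True)
class PairedComparison:
    """Full record of one gated paired comparison."""

    hypothesis: str  # "DSC" | "HD"
    shapiro_a: tuple[float, float]
    shapiro_b: tuple[float, float]
    levene: tuple[float, float]
    chosen_test: str  # "WILCOXON" | "PAIRED_T"
    test_p: float
    cohens_d: float
    effect_label: str
    holm_threshold: float
    significant: bool
    n_pairs: int


def _gated_test(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[tuple, tuple, tuple, str, float]:
    sh_a = shapiro_wilk(a)
    sh_b = shapiro_wilk(b)
    lev = levene(a, b)
    normal = sh_a[1] > alpha and sh_b[1] > alpha
    homoscedastic = lev[1] > alpha
    if normal and homoscedastic:
        return sh_a, sh_b, lev, "PAIRED_T", paired_t(a, b)
    return sh_a, sh_b, lev, "WILCOXON", wilcoxon_signed_rank(a, b)


def compare_modalities(
    dsc_chonaa: Sequence[float],
    dsc_flair: Sequence[float],
    hd_chonaa: Sequence[float],
    hd_flair: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
) -> tuple[PairedComparison, PairedComparison]:
    """Gated paired comparisons of the two overlap hypotheses.

    Samples are paired by (patient, pre/post pair).  Each hypothesis is
    gated through Shapiro–Wilk (both groups) and Levene; the two resulting
    p-values are then Holm–Bonferroni-adjusted as one family.
    """
    groups = {
        "DSC": (np.asarray(dsc_chonaa, float), np.asarray(dsc_flair, float)),
        "HD": (np.asarray(hd_chonaa, float), np.asarray(hd_flair, float)),
    }
    partial = {}
    for name, (a, b) in groups.items():
        if a.shape != b.shape:
            raise StatisticsError(f"{name}: paired samples of unequal length")
        if np.all(a == b):
            # groups identical pair-for-pair: no evidence of any difference
            # (the rank/t machinery is degenerate here, not informative)
            sh_a, sh_b, lev = shapiro_wilk(a), shapiro_wilk(b), levene(a, b)
            partial[name] = (sh_a, sh_b, lev, "WILCOXON", 1.0, 0.0, a.size)
            continue
        sh_a, sh_b, lev, test, p = _gated_test(a, b, alpha)
        d = cohens_d_paired(a, b)
        partial[name] = (sh_a, sh_b, lev, test, p, d, a.size)
    holm = holm_bonferroni([partial["DSC"][4], partial["HD"][4]], alpha=alpha)
    out = []
    for (name, vals), (thr, rej) in zip(partial.items(), holm):
        sh_a, sh_b, lev, test, p, d, n = vals
        out.append(
            PairedComparison(
                hypothesis=name,
                shapiro_a=sh_a,
                shapiro_b=sh_b,
                levene=lev,
                chosen_test=test,
                test_p=p,
                cohens_d=d,
                effect_label=effect_size_label(d),
                holm_threshold=thr,
                significant=rej,
                n_pairs=n,
            )
        )
    return out[0], out[1]
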