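"""Group comparison, observer-agreement ICC and Spearman-vs-Gleason tests.

The group comparison follows a gated protocol: Shapiro–Wilk normality on
each group and Levene's test (mean-centred) for homoscedasticity, both at a
configurable alpha (default 0.05). Both normal + homoscedastic → pooled
two-sample t; normal but heteroscedastic → Welch t; otherwise the Wilcoxon
rank-sum test in its normal approximation with tie correction. The branch
taken is always recorded. No multiple-testing correction is applied by
default (a Benjamini–Hochberg helper is provided).

ICC forms are the two-way ANOVA single-measure coefficients: "agreement"
(absolute agreement; the ICC(2,1)/ICC(A,1) formula, used for both the
two-way random and two-way mixed readings) and "consistency" (ICC(3,1)).
Agreement categories: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "GroupComparisonResult",
    "ICCResult",
    "SpearmanResult",
    "LesionRecord",
    "choose_and_run_group_test",
    "t_statistic_from_summary",
    "rank_sum_test",
    "icc",
    "icc_category",
    "spearman_gs",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one two-group comparison with its gate decisions."""

    test: str  # "pooled-t" | "welch-t" | "wilcoxon"
    statistic: float
    df: float | None
    pvalue: float
    shapiro_p: tuple[float, float]
    levene_p: float
    feature: str | None = None


@dataclass(frozen=True)
class ICCResult:
    """An intraclass correlation with its form, 95% CI and category."""

    value: float
    form: str
    ci95: tuple[float, float]
    category: str
    n_targets: int = 0
    n_raters: int = 0


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: class label, Gleason score (cancer only) and one
    histogram summary per parameter (keys D, Dstar, f, K, ADC)."""

    lesion_id: int
    class_name: str
    summaries: dict
    gleason: int | None = None

    def __post_init__(self) -> None:
        is_pca = self.class_name == "PCa"
        if is_pca and self.gleason is None:
            raise ValidationError("PCa lesions require a Gleason score")
        if not is_pca and self.gleason is not None:
            raise ValidationError("non-PCa lesions must not carry a Gleason score")
        missing = {"D", "Dstar", "f", "K", "ADC"} - set(self.summaries)
        if missing:
            raise ValidationError(f"missing parameter summaries: {sorted(missing)}")


def _welch_df(va: float, vb: float, na: int, nb: int) -> float:
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    return num / den


def t_statistic_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t from summary statistics: returns (t, df, two-sided p).

    Pooled or Welch standard error per the flag. A zero standard error gives
    t = 0 (equal means) or ±inf with p = 0 (unequal means).
    """
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("SDs must be >= 0")
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("each group needs n >= 2")
    va, vb = sd_a**2, sd_b**2
    if welch:
        se = np.sqrt(va / n_a + vb / n_b)
        df = _welch_df(va, vb, n_a, n_b) if se > 0 else float(n_a + n_b - 2)
    else:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        df = float(n_a + n_b - 2)
    diff = mean_a - mean_b
    if se == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, diff)), df, 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def rank_sum_test(a, b, continuity: bool = True) -> tuple[float, float]:
    """Wilcoxon rank-sum z statistic (normal approximation, tie-corrected)
    and its two-sided p. The z is signed: positive when group A ranks higher."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    d = u - mu
    if continuity:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    if var <= 0:
        return 0.0, 1.0
    z = d / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def choose_and_run_group_test(
    group_a, group_b, alpha_gate: float = 0.05, feature: str | None = None
) -> GroupComparisonResult:
    """Gated two-group comparison (see module docstring for the protocol)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 values")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # constant sample: trivially non-normal gate
            return 0.0
        return float(stats.shapiro(x).pvalue)

    sh_a, sh_b = _shapiro_p(a), _shapiro_p(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        lev_p = 1.0
    else:
        lev_p = float(stats.levene(a, b, center="mean").pvalue)

    normal = sh_a > alpha_gate and sh_b > alpha_gate
    if normal:
        homoscedastic = lev_p > alpha_gate
        welch = not homoscedastic
        t, df, p = t_statistic_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, welch=welch
        )
        test = "welch-t" if welch else "pooled-t"
        return GroupComparisonResult(test, t, df, p, (sh_a, sh_b), lev_p, feature)
    z, p = rank_sum_test(a, b)
    return GroupComparisonResult("wilcoxon", z, None, p, (sh_a, sh_b), lev_p, feature)


def icc_category(value: float) -> str:
    """Agreement category: poor (<0.40), fair (0.40–0.59), good (0.60–0.74),
    excellent (0.75–1.00); boundaries belong to the upper category."""
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(ratings, form: str = "agreement", confidence: float = 0.95) -> ICCResult:
    """Single-measure two-way ICC from a targets × raters matrix.

    ``form="agreement"`` uses the absolute-agreement ICC(2,1)/ICC(A,1)
    formula (the same computational form under the random- and mixed-effects
    readings); ``form="consistency"`` uses ICC(3,1). Confidence intervals
    follow the standard F-based (consistency) and Satterthwaite (agreement)
    constructions. Missing cells are rejected — no imputation.
    """
    x = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        x = ratings.to_numpy(dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D targets × raters matrix")
    if np.any(~np.isfinite(x)):
        raise ValidationError("missing or non-finite cells are not allowed")
    n, k = x.shape
    if k < 2:
        raise InsufficientDataError("need at least 2 raters/occasions")
    if n < 5:
        raise InsufficientDataError("need at least 5 targets")
    if form not in ("agreement", "consistency"):
        raise ValidationError(f"unknown ICC form {form!r}")

    msr, msc, mse, n, k = _anova_mean_squares(x)
    alpha = 1.0 - confidence
    if msr == 0 and mse == 0:
        raise ValidationError("ratings have no target variance; ICC undefined")

    if form == "consistency":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0:
            ci = (value, value)
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0 and msc == 0:
            ci = (value, value)
        else:
            icc_v = value
            with np.errstate(divide="ignore", invalid="ignore"):
                a_coef = k * icc_v / (n * (1 - icc_v)) if icc_v < 1 else np.inf
                b_coef = 1 + k * icc_v * (n - 1) / (n * (1 - icc_v)) if icc_v < 1 else np.inf
            if not np.isfinite(a_coef):
                ci = (value, value)
            else:
                v_num = (a_coef * msc + b_coef * mse) ** 2
                v_den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
                v = v_num / v_den if v_den > 0 else 1.0
                f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lower = (
                    n * (msr - f_star_l * mse)
                    / (f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                upper = (
                    n * (f_star_u * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
                )
                ci = (lower, upper)
    ci = (float(np.clip(ci[0], -1.0, 1.0)), float(np.clip(ci[1], -1.0, 1.0)))
    value = float(value)
    return ICCResult(value, form, ci, icc_category(value), n_targets=n, n_raters=k)


def spearman_gs(values, gs) -> SpearmanResult:
    """Spearman rank correlation (average ranks for ties; two-sided p via the
    t approximation) between a per-lesion feature and Gleason scores."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(gs, dtype=float)
    if v.size != g.size:
        raise ValidationError("values and scores must align")
    if v.size < 5:
        raise InsufficientDataError("need at least 5 pairs")
    if np.ptp(v) == 0 or np.ptp(g) == 0:
        raise ValidationError("correlation undefined for a constant input")
    rho, p = stats.spearmanr(v, g)
    return SpearmanResult(float(rho), float(p), int(v.size))


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing correction (off by default in all reports)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]
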