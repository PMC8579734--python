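"""ROC analysis, exact binomial CIs, logistic combined models and the
DeLong comparison of correlated AUCs.

The empirical ROC is evaluated over all observed cutoffs; the orientation
("≤" — positives score lower — versus ">") is chosen so that AUC ≥ 0.5 and
is reported as the association criterion. The operating point maximizes the
Youden index (ties resolved toward higher specificity). The AUC confidence
interval uses the DeLong placement-value variance; the degenerate AUC = 1
case (zero DeLong variance) falls back to an exact binomial bound on the
n₁+n₂ correctly ordered subjects so a non-trivial CI is always reported.
Sensitivity and specificity carry Clopper–Pearson exact CIs.

Combined diagnostic models are unregularized maximum-likelihood logistic
regressions on internally standardized features; their scores are fitted
event probabilities, and their ROC uses the ">" orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .exceptions import DomainError, SeparationWarning, ValidationError

__all__ = [
    "ROCResult",
    "ROCComparisonResult",
    "CombinedModelSpec",
    "roc_analysis",
    "exact_binomial_ci",
    "delong_compare",
    "fit_combined_model",
    "auc_mann_whitney",
]


@dataclass(frozen=True)
class ROCResult:
    """AUC with CI, Youden-optimal cutoff and exact-CI operating point."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    direction: str  # "<=" (positives score lower) or ">"
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden: float
    n_pos: int
    n_neg: int
    degenerate_ci: bool = False

    @property
    def criterion(self) -> str:
        """Printed association criterion, e.g. '≤1.190' or '>0.480'."""
        sym = "≤" if self.direction == "<=" else ">"
        return f"{sym}{self.cutoff:g}"


@dataclass(frozen=True)
class ROCComparisonResult:
    """Paired DeLong comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    diff: float
    z: float
    pvalue: float
    degenerate: bool = False


@dataclass
class CombinedModelSpec:
    """A named logistic combination of member features."""

    name: str
    features: tuple[str, ...]
    coefficients: dict[str, float] | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        if len(self.features) < 1:
            raise ValidationError("a combined model needs at least one member feature")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    labels = labels.astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong placement values with the ½-tie rule; returns (AUC, V10, V01)."""
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann–Whitney U statistic divided by n₁·n₂ (">" orientation)."""
    pos, neg = _split(scores, labels)
    auc, _, _ = _placements(pos, neg)
    return auc


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact CI for a binomial proportion, via beta quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise DomainError(f"invalid successes/trials: {k}/{n}")
    if not 0 < level < 1:
        raise DomainError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def roc_analysis(scores, labels, direction: str | None = None, level: float = 0.95) -> ROCResult:
    """Empirical ROC of one per-lesion feature against binary class labels.

    ``direction`` forces an orientation ("<=" or ">"); by default it is
    chosen so that AUC ≥ 0.5. Requires at least 3 lesions per class.
    """
    pos, neg = _split(scores, labels)
    if pos.size < 3 or neg.size < 3:
        raise ValidationError("need at least 3 lesions per class")
    auc_gt, _, _ = _placements(pos, neg)
    if direction is None:
        direction = ">" if auc_gt >= 0.5 else "<="
    if direction not in (">", "<="):
        raise ValidationError(f"unknown direction {direction!r}")

    if direction == ">":
        o_pos, o_neg = pos, neg
    else:
        o_pos, o_neg = -pos, -neg
    auc, v10, v01 = _placements(o_pos, o_neg)

    # Youden scan over observed cutoffs (original scale).
    cand = np.unique(np.concatenate([pos, neg]))
    best = None
    for c in cand:
        if direction == ">":
            sens = float(np.mean(pos > c))
            spec = float(np.mean(neg <= c))
        else:
            sens = float(np.mean(pos <= c))
            spec = float(np.mean(neg > c))
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cutoff, sens, spec = best

    m, n = pos.size, neg.size
    se = np.sqrt(v10.var(ddof=1) / m + v01.var(ddof=1) / n) if m > 1 and n > 1 else 0.0
    degenerate = False
    if se == 0:
        if auc >= 1.0:
            lo, _ = exact_binomial_ci(m + n, m + n, level)
            auc_ci = (lo, 1.0)
        else:
            auc_ci = (auc, auc)
        degenerate = True
    else:
        zq = stats.norm.ppf(1 - (1 - level) / 2)
        auc_ci = (max(0.0, auc - zq * se), min(1.0, auc + zq * se))

    k_sens = int(round(sens * m))
    k_spec = int(round(spec * n))
    return ROCResult(
        auc=auc,
        auc_ci=auc_ci,
        cutoff=cutoff,
        direction=direction,
        sensitivity=sens,
        sensitivity_ci=exact_binomial_ci(k_sens, m, level),
        specificity=spec,
        specificity_ci=exact_binomial_ci(k_spec, n, level),
        youden=sens + spec - 1.0,
        n_pos=m,
        n_neg=n,
        degenerate_ci=degenerate,
    )


def delong_compare(scores_a, scores_b, labels) -> ROCComparisonResult:
    """Paired DeLong z test for two correlated ROC curves on the same lesions.

    z = ΔAUC / se(ΔAUC) with the placement-value covariance; two-sided normal
    p. A degenerate (zero) variance — e.g. both models perfect — yields
    z = 0, p = 1 with the degeneracy flag set.
    """
    labels = np.asarray(labels).astype(bool)
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return ROCComparisonResult(auc_a, auc_b, diff, 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ROCComparisonResult(auc_a, auc_b, float(diff), float(z), float(p))


def fit_combined_model(
    features: pd.DataFrame, labels, spec: CombinedModelSpec
) -> tuple[np.ndarray, ROCResult, CombinedModelSpec]:
    """Fit one combined diagnostic model and score its ROC.

    ``features`` holds one row per lesion; the spec's member columns are
    standardized (zero-variance members dropped with a warning) and entered
    into an unregularized logistic regression of class on features.
    Perfect separation proceeds with a warning under capped iterations —
    fitted probabilities still rank the classes. The ROC of the probability
    scores uses the ">" orientation (higher probability → positive).
    """
    missing = [c for c in spec.features if c not in features.columns]
    if missing:
        raise ValidationError(f"missing member features: {missing}")
    y = np.asarray(labels).astype(bool)
    X_raw = features.loc[:, list(spec.features)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X_raw)):
        raise ValidationError("member features contain missing values")
    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(spec.features, keep) if not k]
        warnings.warn(f"dropping constant features {dropped}", UserWarning, stacklevel=2)
    if not keep.any():
        raise ValidationError("all member features are constant")
    X = (X_raw[:, keep] - mu[keep]) / sd[keep]

    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter under separation
        clf.fit(X, y)
    scores = clf.predict_proba(X)[:, 1]
    if scores[y].min() > scores[~y].max():
        warnings.warn(
            f"model {spec.name!r}: classes perfectly separated; coefficients "
            "capped at the iteration limit",
            SeparationWarning,
            stacklevel=2,
        )
    coefs = {
        c: float(w) for c, w in zip(np.asarray(spec.features)[keep], clf.coef_.ravel())
    }
    fitted = replace(
        spec if isinstance(spec, CombinedModelSpec) else CombinedModelSpec(**spec),
        coefficients=coefs,
        intercept=float(clf.intercept_[0]),
    )
    roc = roc_analysis(scores, y, direction=">")
    return scores, roc, fitted
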