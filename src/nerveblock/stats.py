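"""Discrimination statistics: ROC curves, AUC contrasts, two-sample t-tests.

%MPE values pooled over the observation horizon are used as scores for
telling treatments or neuropathy conditions apart.  The ROC curve sweeps a
threshold over the distinct scores (ties grouped); the area under it is the
trapezoidal integral, which equals the tie-corrected Mann-Whitney
concordance probability.  Standard errors use the Hanley-McNeil formula by
default, with a stratified bootstrap as an alternative.  Two independent
areas are contrasted with a one-degree-of-freedom chi-square statistic,

    chi2 = (A1 - A2)^2 / (SE1^2 + SE2^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "AUCComparison",
    "TTestResult",
    "roc_from_scores",
    "compare_auc",
    "t_test_from_summary",
    "t_test_from_raw",
]

_TINY_P = 5e-324  # smallest positive subnormal double; keeps p in (0, 1]


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), from (0,0) to (1,1)
    thresholds: tuple[float, ...]
    auc: float
    se: float
    n_pos: int
    n_neg: int
    positive_label: str


@dataclass(frozen=True)
class AUCComparison:
    auc_1: float
    auc_2: float
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    variant: str  # "pooled" | "welch"


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_from_scores(
    scores: Iterable[tuple[float, str]],
    positive_label: str,
    se_method: str = "hanley",
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
) -> ROCResult:
    """ROC curve of a score against a binary class label.

    Thresholds sweep the distinct score values with ties grouped, so the AUC
    (trapezoidal) equals the tie-corrected pairwise concordance probability
    U / (n_pos * n_neg).  ``se_method`` selects the Hanley-McNeil closed form
    ("hanley") or a stratified bootstrap ("bootstrap").
    """
    pairs = [(float(s), str(l)) for s, l in scores]
    if not pairs:
        raise ValueError("degenerate ROC: no scores supplied")
    y = np.array([l == positive_label for _, l in pairs], dtype=bool)
    x = np.array([s for s, _ in pairs], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate ROC: both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, x, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if se_method == "hanley":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif se_method == "bootstrap":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        pos, neg = x[y], x[~y]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            ps = gen.choice(pos, n_pos, replace=True)
            ns = gen.choice(neg, n_neg, replace=True)
            # tie-corrected concordance without rebuilding the full curve
            gt = ps[:, None] > ns[None, :]
            eq = ps[:, None] == ns[None, :]
            reps[b] = (gt.sum() + 0.5 * eq.sum()) / (n_pos * n_neg)
        se = float(reps.std(ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return ROCResult(
        points=tuple((float(f), float(t)) for f, t in zip(fpr, tpr)),
        thresholds=tuple(float(t) for t in thr),
        auc=auc,
        se=float(se),
        n_pos=n_pos,
        n_neg=n_neg,
        positive_label=positive_label,
    )


def compare_auc(r1: ROCResult, r2: ROCResult) -> AUCComparison:
    """Chi-square contrast of two AUCs from independent samples (df = 1)."""
    diff = r1.auc - r2.auc
    var = r1.se**2 + r2.se**2
    if var == 0:
        if diff == 0:
            return AUCComparison(r1.auc, r2.auc, 0.0, 1, 1.0)
        warnings.warn(
            "both standard errors are zero with unequal AUCs; p below machine floor",
            stacklevel=2,
        )
        return AUCComparison(r1.auc, r2.auc, math.inf, 1, _TINY_P)
    chi2 = diff**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return AUCComparison(r1.auc, r2.auc, float(chi2), 1, max(p, _TINY_P))


def t_test_from_summary(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-sided independent two-sample t-test from summary statistics.

    The pooled-variance (classical) test is the default; ``variant="welch"``
    drops the equal-variance assumption.  Degenerate inputs with both SDs
    zero return p = 1 for equal means and a below-floor p (with a warning)
    otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if sd1 == 0 and sd2 == 0:
        df = float(n1 + n2 - 2)
        if m1 == m2:
            return TTestResult(0.0, df, 1.0, (m1, m2), (sd1, sd2), (n1, n2), variant)
        warnings.warn("zero variance with unequal means; p below machine floor", stacklevel=2)
        t = math.inf if m1 > m2 else -math.inf
        return TTestResult(t, df, _TINY_P, (m1, m2), (sd1, sd2), (n1, n2), variant)
    res = sps.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p_value=max(float(res.pvalue), _TINY_P),
        group_means=(float(m1), float(m2)),
        group_sds=(float(sd1), float(sd2)),
        group_ns=(int(n1), int(n2)),
        variant=variant,
    )


def t_test_from_raw(
    sample1: Sequence[float], sample2: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Raw-data twin of :func:`t_test_from_summary` (exactly consistent)."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs length >= 2")
    return t_test_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, variant=variant
    )
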