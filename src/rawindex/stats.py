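"""Normality-gated group comparisons, correlations, and ROC/AUC.

The validation statistics follow common biomedical practice: Shapiro-Wilk
decides between parametric and rank-based procedures (unpaired t-test vs
Mann-Whitney U for two groups, ANOVA vs Kruskal-Wallis for more, Pearson vs
Spearman for correlation), all two-tailed at alpha = 0.05 with no
multiple-testing correction. Classifier performance is summarised by the
AUC via the Mann-Whitney pairwise identity (ties count one half) with a
seeded stratified percentile bootstrap for the confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test_used: str            # 't_test' | 'mann_whitney'
    p_value: float
    normality_p: tuple[float, float]
    statistic: float
    log_transformed: bool = False


@dataclass
class CorrelationResult:
    method: str               # 'pearson' | 'spearman'
    coefficient: float
    p_value: float


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def _shapiro_p(x: np.ndarray) -> float:
    return float(ss.shapiro(x).pvalue)


def compare_groups(a, b, alpha_normality: float = ALPHA_NORMALITY,
                   allow_log_transform: bool = True) -> GroupComparison:
    """Two-group comparison with a Shapiro-Wilk gate.

    If both groups pass normality the unpaired two-tailed t-test is used;
    otherwise, when all values are positive, a log transform is attempted
    and, if it restores normality, the t-test runs on the transformed data;
    failing that, the Mann-Whitney U test is used. Summary means/SDs are
    always reported on the original scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    use_t, logged, ta, tb = pa > alpha_normality and pb > alpha_normality, False, a, b
    if not use_t and allow_log_transform and a.min() > 0 and b.min() > 0:
        la, lb = np.log(a), np.log(b)
        if _shapiro_p(la) > alpha_normality and _shapiro_p(lb) > alpha_normality:
            use_t, logged, ta, tb = True, True, la, lb
    if use_t:
        res = ss.ttest_ind(ta, tb)
        test = "t_test"
    else:
        res = ss.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        test_used=test, p_value=float(res.pvalue),
        normality_p=(pa, pb), statistic=float(res.statistic),
        log_transformed=logged)


def compare_multiple(groups, alpha_normality: float = ALPHA_NORMALITY,
                     allow_log_transform: bool = True) -> dict:
    """ANOVA across >2 groups, falling back to Kruskal-Wallis when any group
    fails Shapiro-Wilk even after an attempted log transform."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise ValueError("need >= 2 groups of n >= 3")
    ps = [_shapiro_p(g) for g in groups]
    normal, logged, use = all(p > alpha_normality for p in ps), False, groups
    if not normal and allow_log_transform and all(g.min() > 0 for g in groups):
        lg = [np.log(g) for g in groups]
        if all(_shapiro_p(g) > alpha_normality for g in lg):
            normal, logged, use = True, True, lg
    if normal:
        res = ss.f_oneway(*use)
        test = "anova"
    else:
        res = ss.kruskal(*groups)
        test = "kruskal_wallis"
    return {"test_used": test, "p_value": float(res.pvalue),
            "statistic": float(res.statistic), "normality_p": ps,
            "log_transformed": logged}


def correlate(x, y, force: str | None = None,
              alpha_normality: float = ALPHA_NORMALITY) -> CorrelationResult:
    """Pearson correlation when both marginals pass Shapiro-Wilk, Spearman
    rank correlation otherwise; ``force='pearson'|'spearman'`` overrides."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length samples of n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if force is None:
        pearson = _shapiro_p(x) > alpha_normality and _shapiro_p(y) > alpha_normality
    elif force in ("pearson", "spearman"):
        pearson = force == "pearson"
    else:
        raise ValueError(f"unknown method {force!r}")
    if pearson:
        r = ss.pearsonr(x, y)
        return CorrelationResult("pearson", float(r.statistic), float(r.pvalue))
    r = ss.spearmanr(x, y)
    return CorrelationResult("spearman", float(r.statistic), float(r.pvalue))


def auc_mann_whitney(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) identity; tied scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = ss.rankdata(scores)  # average ranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0,
            ci_level: float = 0.95) -> RocResult:
    """AUC with a stratified percentile-bootstrap confidence interval.

    Positives and negatives are resampled within class so every replicate
    retains both labels; the CI is the percentile interval of the replicate
    AUCs at ``ci_level``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    point = auc_mann_whitney(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    reps = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        reps[i] = auc_mann_whitney(np.concatenate([bp, bn]),
                                   np.concatenate([np.ones(len(bp), bool),
                                                   np.zeros(len(bn), bool)]))
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(reps, [tail, 1.0 - tail])
    return RocResult(auc=point, ci95=(float(lo), float(hi)),
                     n_pos=int(labels.sum()), n_neg=int((~labels).sum()))
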