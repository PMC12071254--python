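"""Classification metrics, ROC/AUC with DeLong machinery, and the
per-motif differential scan.

AUC is the Mann-Whitney statistic with half credit for ties; its
confidence interval comes from the DeLong structural-components variance
(default) or a seeded percentile bootstrap. Two correlated AUCs on the
same samples are compared with DeLong's paired z-test. The motif scan
runs a two-sided Wilcoxon rank-sum test per motif (256 tests), assigns
direction by the median difference, and adjusts p-values by Bonferroni
(default) or Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .motifs import MOTIFS, ProfileMatrix


@dataclass
class MetricsReport:
    """Sensitivity/specificity/accuracy/F1 (with 95% CIs) and AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    threshold: float
    auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary {0, 1}")
    return y


def confusion_metrics(
    y: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Threshold the scores and compute SEN, SPE, ACC and F1.

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/n and
    F1 = 2*SEN*PPV/(SEN+PPV) with PPV = TP/(TP+FP); F1 is set to 0 with a
    warning when PPV or SEN is undefined. 95% CIs for the three
    proportions are exact binomial (Clopper-Pearson).
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    sen = tp / n_pos if n_pos else 0.0
    spe = tn / n_neg if n_neg else 0.0
    acc = (tp + tn) / y.size
    if tp + fp == 0 or n_pos == 0 or tp == 0:
        if tp + fp == 0 or n_pos == 0:
            warnings.warn("F1 undefined (no predicted or true positives); "
                          "reporting 0", stacklevel=2)
        f1 = 0.0
    else:
        ppv = tp / (tp + fp)
        f1 = 2 * sen * ppv / (sen + ppv)
    ci = {}
    for name, k, m in (("sensitivity", tp, n_pos), ("specificity", tn, n_neg),
                       ("accuracy", tp + tn, y.size)):
        if m:
            lo, hi = proportion_confint(k, m, alpha=0.05, method="beta")
            ci[name] = (float(lo), float(hi))
    return MetricsReport(
        sensitivity=sen, specificity=spe, accuracy=acc, f1=f1,
        threshold=threshold, ci=ci,
    )


def auc_mann_whitney(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U with 0.5 credit for ties."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _delong_components(y: np.ndarray, scores: np.ndarray):
    """DeLong structural components (V10, V01) via midranks."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auc_ci(
    y: np.ndarray,
    scores: np.ndarray,
    method: str = "delong",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% CI by DeLong variance or percentile bootstrap."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(y, scores)
    if method == "delong":
        a, v10, v01 = _delong_components(y, scores)
        var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + (
            np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0
        )
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    elif method == "bootstrap":
        rng = np.random.RandomState(seed)
        pos_idx = np.where(y == 1)[0]
        neg_idx = np.where(y == 0)[0]
        vals = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, pos_idx.size, replace=True),
                    rng.choice(neg_idx, neg_idx.size, replace=True),
                ]
            )
            vals.append(auc_mann_whitney(y[idx], scores[idx]))
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return auc, (float(lo), float(hi))


def delong_test(y: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Two-sided DeLong test comparing two correlated AUCs.

    Returns 1.0 when the variance of the AUC difference degenerates to
    zero with equal AUCs (e.g. identical score vectors).
    """
    y = _check_binary(y)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != y.shape or scores_b.shape != y.shape:
        raise ValueError("score vectors must match y in length")
    auc_a, v10_a, v01_a = _delong_components(y, scores_a)
    auc_b, v10_b, v01_b = _delong_components(y, scores_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def adjust_pvalues(ps: np.ndarray, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg or Bonferroni)."""
    ps = np.asarray(ps, dtype=float)
    if ((ps < 0) | (ps > 1)).any() or not np.isfinite(ps).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "benjamini_hochberg":
        return multipletests(ps, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(ps, method="bonferroni")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass
class MotifScanResult:
    """Per-motif differential test table plus significance counts."""

    table: pd.DataFrame  # index motif; direction, p_raw, p_adjusted
    n_up: int
    n_down: int
    alpha: float
    method: str

    @property
    def significant_up(self) -> list[str]:
        t = self.table
        return list(t.index[(t.p_adjusted < self.alpha) & (t.direction == "up")])

    @property
    def significant_down(self) -> list[str]:
        t = self.table
        return list(t.index[(t.p_adjusted < self.alpha) & (t.direction == "down")])


def motif_scan(
    pm: ProfileMatrix,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> MotifScanResult:
    """Per-motif two-sided Wilcoxon rank-sum scan of cancer vs control.

    Direction is "up" when the cancer-group median frequency exceeds the
    control median. Small groups (n < 10 per side, no ties) use the exact
    null distribution; otherwise the normal approximation with continuity
    correction is applied.
    """
    if pm.labels is None:
        raise ValueError("profile matrix has no labels")
    cancer = pm.values[pm.labels == 1]
    control = pm.values[pm.labels == 0]
    if cancer.shape[0] < 3 or control.shape[0] < 3:
        raise ValueError("need at least 3 samples per group")
    res = stats.mannwhitneyu(
        cancer, control, axis=0, alternative="two-sided", method="auto",
        use_continuity=True,
    )
    p_raw = np.asarray(res.pvalue, dtype=float)
    p_adj = adjust_pvalues(p_raw, method=adjust)
    med_diff = np.median(cancer, axis=0) - np.median(control, axis=0)
    direction = np.where(med_diff > 0, "up", np.where(med_diff < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "direction": direction,
            "median_diff": med_diff,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        },
        index=list(MOTIFS),
    )
    table.index.name = "motif"
    sig = table.p_adjusted < alpha
    n_up = int(np.sum(sig & (table.direction == "up")))
    n_down = int(np.sum(sig & (table.direction == "down")))
    return MotifScanResult(table=table, n_up=n_up, n_down=n_down,
                           alpha=alpha, method=adjust)
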