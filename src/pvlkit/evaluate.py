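"""Discrimination, calibration, utility, and cohort-table statistics.

Everything operates on pooled out-of-fold predictions or on per-fold metric
lists. Two fold-aggregation confidence-interval conventions are provided:
``normal_sd`` (mean ± 1.96·SD across folds) and ``t_sem``
(mean ± t₀.₀₂₅,k₋₁·SD/√k); both are truncated to [0, 1].
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .training import PredictionSet, binarize

__all__ = [
    "roc_auc", "confusion_metrics", "aggregate_folds", "MetricSummary",
    "delong_test", "brier_and_calibration", "CalibrationResult",
    "decision_curve", "DecisionCurve", "cohort_table_tests",
    "per_fold_metrics", "summarize_prediction_set",
]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")


# --------------------------------------------------------------- discrimination

def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("labels and scores must have equal length")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def confusion_metrics(labels: np.ndarray, predicted: np.ndarray,
                      ) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV; NaN where undefined."""
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if len(labels) != len(predicted):
        raise ValueError("length mismatch")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, len(labels)),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


@dataclasses.dataclass
class MetricSummary:
    name: str
    per_fold: list[float]
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    convention: str

    def __post_init__(self):
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must contain the mean")


def aggregate_folds(per_fold: list[float], name: str = "",
                    convention: str = "t_sem") -> MetricSummary:
    """Aggregate per-fold metric values into mean ± SD with a 95% CI.

    convention = 'normal_sd': mean ± 1.96·SD  (SD across folds, k-1 denom)
    convention = 't_sem':     mean ± t₀.₀₂₅,k₋₁·SD/√k
    CIs are truncated to [0, 1]. NaN fold values (undefined ratios) are
    dropped before aggregation.
    """
    vals = np.asarray([v for v in per_fold if not math.isnan(v)], dtype=float)
    k = len(vals)
    if k < 2:
        raise ValueError("need at least two folds to aggregate")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if convention == "normal_sd":
        half = 1.959963984540054 * sd
    elif convention == "t_sem":
        half = float(stats.t.ppf(0.975, k - 1)) * sd / math.sqrt(k)
    else:
        raise ValueError(f"unknown CI convention {convention!r}")
    return MetricSummary(name=name, per_fold=list(per_fold), mean=mean, sd=sd,
                         ci_low=max(mean - half, 0.0),
                         ci_high=min(mean + half, 1.0),
                         convention=convention)


def per_fold_metrics(pred: PredictionSet, threshold: float = 0.5,
                     ) -> dict[str, list[float]]:
    """Per-validation-fold AUC and confusion metrics at `threshold`."""
    out: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    hard = binarize(pred, threshold)
    for fold in np.unique(pred.fold):
        sel = pred.fold == fold
        out["auc"].append(roc_auc(pred.y[sel], pred.p[sel]))
        cm = confusion_metrics(pred.y[sel], hard[sel])
        for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            out[m].append(cm[m])
    return out


def summarize_prediction_set(pred: PredictionSet, threshold: float = 0.5,
                             convention: str = "t_sem",
                             ) -> dict[str, MetricSummary]:
    folds = per_fold_metrics(pred, threshold)
    return {m: aggregate_folds(v, name=m, convention=convention)
            for m, v in folds.items()}


# --------------------------------------------------------------------- DeLong

def _structural_components(labels: np.ndarray, scores: np.ndarray,
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong V10/V01 placement components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    auc = cmp.mean()
    v10 = cmp.mean(axis=1)   # per positive
    v01 = cmp.mean(axis=0)   # per negative
    return float(auc), v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> dict[str, float]:
    """Two-sided DeLong test for paired (same-patient) correlated AUCs."""
    labels = np.asarray(labels).astype(int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (len(labels) == len(scores_a) == len(scores_b)):
        raise ValueError("paired scores must share the label vector")
    if labels.sum() in (0, len(labels)):
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _structural_components(labels, scores_a)
    auc_b, v10_b, v01_b = _structural_components(labels, scores_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if diff == 0:
        z, p = 0.0, 1.0
    elif var_diff <= 0:
        z, p = math.copysign(math.inf, diff), 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": diff,
            "variance": float(var_diff), "z": float(z), "p_value": p}


# ---------------------------------------------------------------- calibration

@dataclasses.dataclass
class CalibrationResult:
    bin_edges: np.ndarray
    bin_mean_predicted: np.ndarray      # NaN for empty bins
    bin_observed_rate: np.ndarray       # NaN for empty bins
    bin_counts: np.ndarray
    brier: float


def brier_and_calibration(pred: PredictionSet, n_bins: int = 10,
                          ) -> CalibrationResult:
    """Brier score and a uniform-bin reliability curve on pooled OOF
    predictions. Empty bins keep count 0 and NaN curve values."""
    p = np.asarray(pred.p, dtype=float)
    y = np.asarray(pred.y, dtype=float)
    brier = float(np.mean((p - y) ** 2))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean_pred[b] = float(p[sel].mean())
            obs[b] = float(y[sel].mean())
    return CalibrationResult(edges, mean_pred, obs, counts, brier)


# ------------------------------------------------------------- decision curve

@dataclasses.dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "model": self.net_benefit_model,
            "treat_all": self.net_benefit_all,
            "treat_none": self.net_benefit_none,
        })


def decision_curve(pred: PredictionSet,
                   thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit NB(t) = TP/n − FP/n · t/(1−t) with classification p ≥ t."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.801, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y = np.asarray(pred.y).astype(int)
    p = np.asarray(pred.p, dtype=float)
    n = len(y)
    pi = y.mean()
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pos = p >= t
        tp = int(np.sum(pos & (y == 1)))
        fp = int(np.sum(pos & (y == 0)))
        nb_model[i] = tp / n - fp / n * (t / (1 - t))
    nb_all = pi - (1 - pi) * thresholds / (1 - thresholds)
    return DecisionCurve(thresholds, nb_model, nb_all,
                         np.zeros_like(thresholds))


# -------------------------------------------------------------- cohort tables

def _categorical_test(a_pos: int, a_tot: int, b_pos: int, b_tot: int,
                      ) -> tuple[str, float]:
    """Chi-square with Yates continuity correction when all expected counts
    are >= 5, otherwise Fisher's exact test (two-sided)."""
    table = np.array([[a_pos, a_tot - a_pos], [b_pos, b_tot - b_pos]])
    if table.min() < 0 or min(table.sum(axis=1)) <= 0:
        raise ValueError("contingency table margins must be positive")
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        res = stats.chi2_contingency(table, correction=True)
        return "chi2_yates", float(res.pvalue)
    res = stats.fisher_exact(table, alternative="two-sided")
    return "fisher", float(res.pvalue)


def chi2_yates_p(table: np.ndarray) -> float:
    """Two-sided p of the df=1 chi-square test with continuity correction."""
    res = stats.chi2_contingency(np.asarray(table), correction=True)
    return float(res.pvalue)


def cohort_table_tests(records: pd.DataFrame, outcome_col: str,
                       continuous: list[str], categorical: list[str],
                       ) -> pd.DataFrame:
    """Per-variable two-group comparisons: Wilcoxon rank-sum for continuous
    variables, chi-square (Yates) or Fisher's exact for categorical ones."""
    y = records[outcome_col].astype(int)
    g1 = records[y == 1]
    g0 = records[y == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for col in continuous:
        stat = stats.mannwhitneyu(g1[col], g0[col], alternative="two-sided",
                                  method="asymptotic")
        med1, med0 = float(g1[col].median()), float(g0[col].median())
        rows.append({"variable": col, "test": "wilcoxon_rank_sum",
                     "group1_summary": med1, "group0_summary": med0,
                     "p_value": float(stat.pvalue)})
    for col in categorical:
        test, p = _categorical_test(int(g1[col].sum()), len(g1),
                                    int(g0[col].sum()), len(g0))
        rows.append({"variable": col, "test": test,
                     "group1_summary": float(g1[col].mean()),
                     "group0_summary": float(g0[col].mean()),
                     "p_value": p})
    return pd.DataFrame(rows)
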