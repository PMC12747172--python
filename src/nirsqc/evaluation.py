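"""Confusion-matrix metrics, index baselines and the statistical suite.

The low-quality class is the positive class throughout. Undefined
ratios (zero denominators) are reported as NaN with a warning so
degenerate test sets surface instead of silently scoring 0.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from nirsqc import quality_indices
from nirsqc.signal_io import Recording, SegmentRef

POSITIVE = "low"
NEGATIVE = "high"


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    method: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else _undefined("accuracy")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else _undefined("precision")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else _undefined("recall")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else _undefined("specificity")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return _undefined("f1")
        return 2.0 * p * r / (p + r)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
        }


def _undefined(name: str) -> float:
    warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
    return math.nan


@dataclass
class PairedComparison:
    b: int  # method A wrong, B right
    c: int  # method A right, B wrong
    chi2: float
    p: float


@dataclass
class FoldComparison:
    methods: list[str]
    metric_matrix: np.ndarray  # folds x methods
    friedman_chi2: float
    friedman_p: float
    pairs: list[tuple[str, str]] = field(default_factory=list)
    wilcoxon_p_raw: list[float] = field(default_factory=list)
    wilcoxon_p_adjusted: list[float] = field(default_factory=list)
    cliffs_delta: dict[tuple[str, str], float] = field(default_factory=dict)


def confusion_metrics(
    y_true: list[str] | np.ndarray, y_pred: list[str] | np.ndarray, method: str = ""
) -> EvalReport:
    """Counts and percent metrics with 'low' as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"labels must be high/low, got extra {sorted(bad)}")
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, method=method)


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """F1 (percent) from precision and recall given in percent."""
    if precision_pct + recall_pct == 0:
        return math.nan
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def mcnemar(b: int, c: int) -> PairedComparison:
    """McNemar's test with continuity correction on discordant counts."""
    if b < 0 or c < 0:
        raise ValueError("counts must be nonnegative")
    if b + c == 0:
        raise ValueError("no discordant pairs")
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return PairedComparison(b=b, c=c, chi2=float(chi2), p=p)


def mcnemar_from_predictions(y_true, pred_a, pred_b) -> PairedComparison:
    y_true = np.asarray(y_true)
    a_right = np.asarray(pred_a) == y_true
    b_right = np.asarray(pred_b) == y_true
    b_count = int(np.sum(~a_right & b_right))
    c_count = int(np.sum(a_right & ~b_right))
    return mcnemar(b_count, c_count)


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a blocks x treatments matrix.

    Mid-ranks for ties, chi-square reference with k-1 df. A fully
    degenerate matrix (every block constant) returns (0, 1).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    if np.all(matrix == matrix[:, :1]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*matrix.T)
    return float(stat), float(p)


def wilcoxon_signed_rank(differences: np.ndarray, alternative: str = "two-sided",
                         exact_max_n: int = 12) -> float:
    """Signed-rank p-value on paired differences.

    Zero differences are dropped; the remaining |d| are mid-ranked. For
    n <= ``exact_max_n`` the exact null distribution is enumerated over
    all sign assignments; above that a normal approximation with
    continuity correction (and tie correction) is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        totals = np.fromiter(
            (
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product((False, True), repeat=n)
            ),
            dtype=float,
            count=2**n,
        )
        eps = 1e-9
        p_ge = float(np.mean(totals >= w_plus - eps))
        p_le = float(np.mean(totals <= w_plus + eps))
        if alternative == "greater":
            return p_ge
        if alternative == "less":
            return p_le
        return min(1.0, 2.0 * min(p_ge, p_le))

    mean = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        return float(stats.norm.sf(z))
    if alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        return float(stats.norm.cdf(z))
    z = (abs(w_plus - mean) - 0.5) / sd
    return float(2.0 * stats.norm.sf(z))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(1.0, running_min)
    return adjusted.tolist()


def wilcoxon_bh(
    difference_sets: list[np.ndarray], alternative: str = "two-sided"
) -> tuple[list[float], list[float]]:
    """Pairwise signed-rank tests with BH adjustment across the family."""
    raw = [wilcoxon_signed_rank(d, alternative=alternative) for d in difference_sets]
    return raw, bh_adjust(raw)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    greater = np.sum(x[:, None] > y[None, :])
    less = np.sum(x[:, None] < y[None, :])
    return float((greater - less) / (x.size * y.size))


def compare_folds(metric_matrix: np.ndarray, methods: list[str]) -> FoldComparison:
    """Friedman omnibus plus pairwise Wilcoxon/BH and Cliff's delta."""
    metric_matrix = np.asarray(metric_matrix, dtype=float)
    chi2, p = friedman(metric_matrix)
    pairs = list(itertools.combinations(range(len(methods)), 2))
    diff_sets = [metric_matrix[:, i] - metric_matrix[:, j] for i, j in pairs]
    raw, adjusted = [], []
    for d in diff_sets:
        try:
            raw.append(wilcoxon_signed_rank(d))
        except ValueError:
            raw.append(1.0)
    adjusted = bh_adjust(raw)
    deltas = {
        (methods[i], methods[j]): cliffs_delta(metric_matrix[:, i], metric_matrix[:, j])
        for i, j in pairs
    }
    return FoldComparison(
        methods=list(methods),
        metric_matrix=metric_matrix,
        friedman_chi2=chi2,
        friedman_p=p,
        pairs=[(methods[i], methods[j]) for i, j in pairs],
        wilcoxon_p_raw=raw,
        wilcoxon_p_adjusted=adjusted,
        cliffs_delta=deltas,
    )


# ---------------------------------------------------------------------------
# index baselines
# ---------------------------------------------------------------------------


def baseline_predictions(
    rec: Recording,
    segments: list[SegmentRef],
    cv_threshold: float = quality_indices.CV_THRESHOLD_DEFAULT,
    sci_threshold: float = quality_indices.SCI_THRESHOLD_DEFAULT,
) -> dict[str, list[str]]:
    """Segment-wise CV and SCI labels for one recording.

    CV uses the worse of the two wavelengths' raw-intensity values; SCI
    uses the two wavelength series of the segment.
    """
    preds: dict[str, list[str]] = {"CV": [], "SCI": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ref in segments:
            block = rec.intensity[ref.start_sample : ref.end_sample, ref.channel_index, :]
            cv_val = max(
                quality_indices.coefficient_of_variation(block[:, 0]),
                quality_indices.coefficient_of_variation(block[:, 1]),
            )
            preds["CV"].append(POSITIVE if cv_val > cv_threshold else NEGATIVE)
            sci_val = quality_indices.sci(block[:, 0], block[:, 1], rec.fs)
            preds["SCI"].append(POSITIVE if sci_val < sci_threshold else NEGATIVE)
    return preds


def run_baselines(
    rec: Recording,
    segments: list[SegmentRef],
    true_labels: list[str],
    cv_threshold: float = quality_indices.CV_THRESHOLD_DEFAULT,
    sci_threshold: float = quality_indices.SCI_THRESHOLD_DEFAULT,
) -> dict[str, EvalReport]:
    """EvalReport per baseline method, measured against provided labels."""
    preds = baseline_predictions(rec, segments, cv_threshold, sci_threshold)
    return {
        name: confusion_metrics(true_labels, pred, method=name)
        for name, pred in preds.items()
    }
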