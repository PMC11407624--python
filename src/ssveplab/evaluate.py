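"""Detection performance summaries and condition comparisons.

Accuracy is tabulated per analysis-window length with dispersion across
blocks (one block = one presentation of every target), the confusion matrix
counts (true, detected) pairs, and the information transfer rate converts
accuracy, target count and selection time into bits per minute:

    ITR = 60/T [log2 N + p log2 p + (1 - p) log2((1 - p) / (N - 1))].

Paired condition comparisons test the differences for normality
(Shapiro-Wilk) and use a paired t-test when normal, a Wilcoxon signed-rank
test otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionResult

__all__ = [
    "EvaluationSummary",
    "ConditionComparison",
    "accuracy_over_time",
    "itr",
    "compare_conditions",
    "confusion_matrix",
]

#: Window-length grid in seconds used when sweeping analysis duration.
DEFAULT_WINDOW_GRID = tuple(np.round(np.arange(0.5, 5.01, 0.5), 2))


def confusion_matrix(results: list[DetectionResult]) -> pd.DataFrame:
    """Counts of (true frequency, detected frequency) pairs.

    Rows are true frequencies, columns detected; row sums equal the number
    of trials per true frequency.
    """
    if not results:
        raise ValueError("no detection results")
    freqs = sorted({r.true_frequency for r in results}
                   | {r.detected_frequency for r in results})
    true = pd.Categorical([r.true_frequency for r in results],
                          categories=freqs)
    det = pd.Categorical([r.detected_frequency for r in results],
                         categories=freqs)
    return pd.crosstab(true, det, rownames=["true"], colnames=["detected"],
                       dropna=False)


def _accuracy_pct(results: list[DetectionResult]) -> float:
    return 100.0 * sum(r.correct for r in results) / len(results)


def _block_accuracies(results: list[DetectionResult]) -> np.ndarray:
    """Per-block accuracies; a block is one run through all targets.

    Trials are assigned to blocks by ``trial_id`` order in groups of
    ``n_targets`` consecutive trials, matching how a cued session presents
    each target once per repetition.
    """
    n_targets = len({r.true_frequency for r in results})
    ordered = sorted(results, key=lambda r: r.trial_id)
    accs = []
    for i in range(0, len(ordered) - n_targets + 1, n_targets):
        block = ordered[i:i + n_targets]
        accs.append(100.0 * sum(r.correct for r in block) / len(block))
    return np.array(accs if accs else [_accuracy_pct(results)])


@dataclass(frozen=True)
class EvaluationSummary:
    """Accuracy/ITR per window length plus the confusion matrix."""

    window_lengths_s: tuple[float, ...]
    accuracy_pct: tuple[float, ...]
    accuracy_sd_pct: tuple[float, ...]
    itr_bits_per_min: tuple[float, ...]
    confusion: pd.DataFrame = field(repr=False)
    n_targets: int = 0
    condition: str = ""
    method: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_s": self.window_lengths_s,
            "accuracy_pct": self.accuracy_pct,
            "accuracy_sd_pct": self.accuracy_sd_pct,
            "itr_bits_per_min": self.itr_bits_per_min,
        })

    def accuracy_at(self, window_s: float) -> float:
        return self.accuracy_pct[self.window_lengths_s.index(window_s)]


def accuracy_over_time(results_by_window: dict[float, list[DetectionResult]],
                       condition: str = "", method: str = "",
                       selection_time_from_window: bool = True
                       ) -> EvaluationSummary:
    """Summarize detection results across analysis-window lengths.

    ``results_by_window`` maps window length (s) to that window's per-trial
    results.  ITR uses the window length as the selection time T unless
    ``selection_time_from_window`` is disabled (then T must be folded in by
    the caller).  The confusion matrix is taken at the longest window.
    """
    if not results_by_window:
        raise ValueError("no results to evaluate")
    windows = tuple(sorted(results_by_window))
    accs, sds, itrs = [], [], []
    n_targets = 0
    for w in windows:
        res = results_by_window[w]
        if not res:
            raise ValueError(f"no results for window {w} s")
        n_targets = max(n_targets, len({r.true_frequency for r in res}))
        p = _accuracy_pct(res)
        accs.append(p)
        sds.append(float(_block_accuracies(res).std(ddof=0)))
        t = w if selection_time_from_window else 1.0
        itrs.append(itr(n_targets, p / 100.0, t) if n_targets >= 2 else 0.0)
    confusion = confusion_matrix(results_by_window[windows[-1]])
    return EvaluationSummary(
        window_lengths_s=windows, accuracy_pct=tuple(accs),
        accuracy_sd_pct=tuple(sds), itr_bits_per_min=tuple(itrs),
        confusion=confusion, n_targets=n_targets,
        condition=condition, method=method)


def itr(n_targets: int, accuracy: float, selection_time_s: float) -> float:
    """Information transfer rate in bits per minute.

    The p log2 p terms are continuous limits at p = 0 and p = 1.  The bit
    rate is minimized (exactly 0) at chance accuracy p = 1/N; systematically
    wrong selections (p below chance) again carry information under the
    symmetric-channel model, so the value rises on both sides of chance.
    """
    if n_targets < 2:
        raise ValueError("ITR needs at least two targets")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    if selection_time_s <= 0:
        raise ValueError("selection time must be positive")
    p, n = accuracy, n_targets

    def plog2(x: float) -> float:
        return x * math.log2(x) if x > 0 else 0.0

    bits = math.log2(n) + plog2(p) + ((1 - p) * math.log2((1 - p) / (n - 1))
                                      if p < 1 else 0.0)
    return 60.0 / selection_time_s * bits


@dataclass(frozen=True)
class ConditionComparison:
    """Paired two-condition test with automatic parametric/rank choice."""

    label_a: str
    label_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    normal_differences: bool
    test_used: str               # "paired-t" or "wilcoxon"
    statistic: float
    p_value: float
    stars: str                   # "*" p<0.01, "**" p<0.05, "" otherwise


def _star_level(p: float) -> str:
    # Star convention of the source analyses: * marks p < 0.01, ** p < 0.05.
    if p < 0.01:
        return "*"
    if p < 0.05:
        return "**"
    return ""


def compare_conditions(values_a, values_b, label_a: str = "A",
                       label_b: str = "B",
                       normality_alpha: float = 0.05) -> ConditionComparison:
    """Compare paired per-block/per-subject values between two conditions.

    Shapiro-Wilk on the paired differences decides between the paired
    t-test (normal) and the Wilcoxon signed-rank test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("conditions must be equal-length paired vectors")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    diff = b - a
    if np.allclose(diff, diff[0]) and np.allclose(diff.std(), 0.0):
        raise ValueError("paired differences have zero variance; "
                         "the tests are degenerate")
    sw_p = stats.shapiro(diff).pvalue
    normal = bool(sw_p > normality_alpha)
    if normal:
        res = stats.ttest_rel(a, b)
        test = "paired-t"
    else:
        res = stats.wilcoxon(a, b)
        test = "wilcoxon"
    p = float(res.pvalue)
    return ConditionComparison(
        label_a=label_a, label_b=label_b,
        values_a=tuple(a), values_b=tuple(b),
        normal_differences=normal, test_used=test,
        statistic=float(res.statistic), p_value=p, stars=_star_level(p))
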