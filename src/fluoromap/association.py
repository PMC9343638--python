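"""Binned-prevalence association between a parameter and guideline exceedance.

Observations are rank-ordered and split into equal-count bins (Rice rule
count by default); within each bin the exceedance prevalence and the median
parameter value are computed, and a Kendall rank correlation (tau-b) is
taken between the k (median, prevalence) pairs. The construction is
invariant under strictly monotone transformations of the parameter axis.
Class-conditional boxplot statistics use Tukey hinges at the 25th/75th
percentiles (linear interpolation) with whiskers at the most extreme
observation within 1.5 IQR of the hinge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def rice_bin_count(n: int) -> int:
    """Rice rule: k = ceil(2 * n^(1/3)), clamped to at most n."""
    if n < 1:
        raise ValueError("need at least one observation")
    return min(int(np.ceil(2.0 * n ** (1.0 / 3.0))), n)


def equal_count_bins(values: np.ndarray, k: int) -> np.ndarray:
    """Contiguous rank-based bin assignment with sizes floor(n/k) or ceil(n/k).

    Ties in value are broken stably by input order, so tied values may
    straddle a bin boundary. Returns an integer bin index per observation,
    in the original order of `values`.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError("cannot form more bins than observations")
    order = np.argsort(values, kind="stable")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1  # larger bins first; sizes differ by at most 1
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.repeat(np.arange(k), sizes)
    return assignment


@dataclass
class BinnedAssociation:
    """Per-bin prevalence summary with its Kendall correlation."""

    parameter_name: str
    n: int
    k: int
    bin_median: np.ndarray
    bin_prevalence: np.ndarray
    bin_size: np.ndarray
    tau: float | None = None
    p_value: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_median": self.bin_median,
                "bin_prevalence": self.bin_prevalence,
                "bin_size": self.bin_size,
            }
        )


def binned_prevalence(
    values: np.ndarray, labels: np.ndarray, k: int, name: str = "parameter"
) -> BinnedAssociation:
    """Per-bin exceedance prevalence and median parameter value."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    assignment = equal_count_bins(values, k)
    med = np.empty(k)
    prev = np.empty(k)
    size = np.empty(k, dtype=int)
    for b in range(k):
        sel = assignment == b
        med[b] = np.median(values[sel])
        prev[b] = labels[sel].mean()
        size[b] = int(sel.sum())
    return BinnedAssociation(name, int(values.size), k, med, prev, size)


def kendall_tau_binned(
    bin_medians: np.ndarray, bin_prevalences: np.ndarray
) -> tuple[float, float]:
    """Kendall tau-b between bin medians and bin prevalences.

    Exact p-value when there are at most 10 bins and no ties; normal
    approximation otherwise.
    """
    m = np.asarray(bin_medians, dtype=float)
    p = np.asarray(bin_prevalences, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two bins")
    no_ties = np.unique(m).size == m.size and np.unique(p).size == p.size
    method = "exact" if (m.size <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(m, p, method=method)
    return float(res.statistic), float(res.pvalue)


def associate(
    values: np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
    name: str = "parameter",
) -> BinnedAssociation:
    """Full chain: drop missing values, Rice bin count, binned prevalence, tau."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    if k is None:
        k = rice_bin_count(values.size)
    out = binned_prevalence(values, labels, k, name)
    out.tau, out.p_value = kendall_tau_binned(out.bin_median, out.bin_prevalence)
    return out


def associate_table(
    table: pd.DataFrame, parameters: list[str], label_col: str = "label"
) -> pd.DataFrame:
    """Summary (parameter, n, k, tau, p) for each named column of a table."""
    rows = []
    for param in parameters:
        a = associate(table[param].to_numpy(float), table[label_col].to_numpy(), name=param)
        rows.append({"parameter": param, "n": a.n, "k": a.k, "tau": a.tau, "p_value": a.p_value})
    return pd.DataFrame(rows)


@dataclass
class ClassBoxplot:
    """Tukey five-number summaries of a parameter in the two exceedance classes."""

    parameter_name: str
    stats: dict[str, dict[str, float]]  # class label -> summary
    single_class: bool = False

    CLASSES = ("le_guideline", "gt_guideline")


def _box_stats(x: np.ndarray) -> dict[str, float]:
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(((x < lo_fence) | (x > hi_fence)).sum()),
    }


def class_boxplots(
    values: np.ndarray, labels: np.ndarray, name: str = "parameter"
) -> ClassBoxplot:
    """Boxplot statistics in the low (label 0) and high (label 1) classes."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    if values.size == 0:
        raise ValueError("empty input")
    out: dict[str, dict[str, float]] = {}
    for cls, tag in zip((0, 1), ClassBoxplot.CLASSES):
        x = values[labels == cls]
        if x.size:
            out[tag] = _box_stats(x)
    return ClassBoxplot(name, out, single_class=len(out) < 2)
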