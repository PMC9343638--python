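"""Repeated stratified cross-validation and the balanced-kappa evaluation scheme.

"Cross-validation" here is Monte-Carlo: repeated random 80/20 splits, each
stratified so the exceedance proportion of the pooled data is maintained
exactly (up to rounding) in both halves. Per repetition the forest is
refitted on the training split and scored on the held-out split with:

* sensitivity, specificity and balanced accuracy at the 0.5 vote cutoff
  (the natural operating point after balanced training);
* rank-based (Mann-Whitney) AUC with tie correction;
* kappa = (acc - NIR) / (1 - NIR) computed on class-balanced test subsets
  obtained by down-sampling the majority class (NIR = 0.5 there, so
  kappa = 2 acc - 1), averaged over ten seeded draws;
* the sensitivity-specificity crossover cutoff, located on the pooled
  held-out predictions of all repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .forest import BalancedForestModel, ForestConfig


def stratified_split(
    y: np.ndarray, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split with exact per-class counts.

    Each class contributes round(train_fraction * n_class) rows to the
    training half, so the class proportions show no binomial spread across
    repeated draws.
    """
    y = np.asarray(y)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows; cannot stratify")
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    missing_class: bool = False


def confusion_metrics(labels: np.ndarray, predicted: np.ndarray) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), and their mean.

    If a class is absent from the labels its rate is NaN and the result is
    flagged rather than silently averaged.
    """
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    pos, neg = labels == 1, labels == 0
    sens = float((predicted[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((predicted[neg] == 0).mean()) if neg.any() else np.nan
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2,
        missing_class=not (pos.any() and neg.any()),
    )


def kappa_from_accuracy(acc: float, nir: float) -> float:
    """kappa = (acc - NIR) / (1 - NIR): accuracy rescaled so the
    no-information rate maps to 0 and perfect accuracy to 1."""
    if not 0 <= acc <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    if not 0 <= nir < 1:
        raise ValueError("no-information rate must lie in [0, 1)")
    return (acc - nir) / (1.0 - nir)


def balanced_kappa(
    labels: np.ndarray,
    predicted: np.ndarray,
    n_downsamples: int = 10,
    seed: int = 0,
) -> float:
    """Kappa on class-balanced test subsets, averaged over seeded draws.

    The majority class is down-sampled without replacement to the minority
    size; on the balanced subset the no-information rate is 0.5, so each
    draw's kappa is 2 * accuracy - 1.
    """
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    if idx1.size == 0 or idx0.size == 0:
        raise ValueError("both classes must be present in the test labels")
    minority, majority = (idx1, idx0) if idx1.size <= idx0.size else (idx0, idx1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    kappas = []
    for _ in range(n_downsamples):
        down = rng.choice(majority, size=minority.size, replace=False)
        sel = np.concatenate([minority, down])
        acc = float((predicted[sel] == labels[sel]).mean())
        kappas.append(kappa_from_accuracy(acc, nir=0.5))
    return float(np.mean(kappas))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def crossover_cutoff(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability threshold at which sensitivity and specificity meet.

    Candidate thresholds are the unique score values; the threshold
    minimizing |sensitivity - specificity| wins, ties resolved as the
    midpoint of the tied thresholds.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    # classify positive when score > t: sens = P(pos > t), spec = P(neg <= t)
    sens = 1.0 - np.searchsorted(pos_scores, thresholds, side="right") / pos_scores.size
    spec = np.searchsorted(neg_scores, thresholds, side="right") / neg_scores.size
    gap = np.abs(sens - spec)
    tied = thresholds[np.isclose(gap, gap.min())]
    return float((tied.min() + tied.max()) / 2.0)


def stratified_metrics(
    labels: np.ndarray,
    predicted: np.ndarray,
    strata: np.ndarray,
    bin_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Confusion metrics within each stratum of a grouping variable.

    Numeric strata can be binned with explicit edges (right-open intervals,
    labelled "lo-hi"). Strata where a class is absent are flagged.
    """
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    strata = np.asarray(strata)
    ok = ~pd.isna(strata)
    if not ok.any():
        raise ValueError("no stratum values present")
    labels, predicted, strata = labels[ok], predicted[ok], strata[ok]
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
        names = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(edges.size - 1)]
        codes = np.digitize(strata.astype(float), edges[1:-1], right=False)
        in_range = (strata.astype(float) >= edges[0]) & (strata.astype(float) <= edges[-1])
        strata = np.where(in_range, np.asarray(names, dtype=object)[codes], None)
        keep = strata != None  # noqa: E711
        labels, predicted, strata = labels[keep], predicted[keep], strata[keep]
    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        m = confusion_metrics(labels[sel], predicted[sel])
        rows.append(
            {"stratum": s, "n": int(sel.sum()), "sensitivity": m.sensitivity,
             "specificity": m.specificity, "balanced_accuracy": m.balanced_accuracy,
             "missing_class": m.missing_class}
        )
    return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Per-repetition and averaged verification statistics."""

    per_repetition: pd.DataFrame
    crossover: float
    pooled_labels: np.ndarray = field(repr=False, default=None)
    pooled_scores: np.ndarray = field(repr=False, default=None)

    @property
    def means(self) -> pd.Series:
        return self.per_repetition.mean(numeric_only=True)

    @property
    def sds(self) -> pd.Series:
        return self.per_repetition.std(numeric_only=True, ddof=1)

    def to_dict(self) -> dict:
        return {
            "n_repetitions": int(len(self.per_repetition)),
            "mean": {k: float(v) for k, v in self.means.items()},
            "sd": {k: (None if np.isnan(v) else float(v)) for k, v in self.sds.items()},
            "crossover_cutoff": float(self.crossover),
        }


def cross_validate(
    table: pd.DataFrame,
    feature_names: list[str],
    config: ForestConfig,
    n_repetitions: int = 100,
    train_fraction: float = 0.8,
    n_downsamples: int = 10,
    label_col: str = "label",
    cutoff: float = 0.5,
) -> CVReport:
    """Monte-Carlo cross-validation of the balanced forest.

    Down-sampling seeds are derived from the repetition index, so a report
    is reproducible from (table, config, n_repetitions) alone.
    """
    X = table[feature_names].to_numpy(float)
    y = table[label_col].to_numpy(int)
    rows = []
    pooled_y, pooled_p = [], []
    for rep in range(n_repetitions):
        tr, te = stratified_split(y, train_fraction, seed=config.seed * 100003 + rep)
        model = BalancedForestModel(
            feature_names, replace(config, seed=config.seed * 100003 + rep)
        )
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])
        pred = (proba > cutoff).astype(int)
        m = confusion_metrics(y[te], pred)
        rows.append(
            {
                "repetition": rep,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "balanced_accuracy": m.balanced_accuracy,
                "auc": auc(y[te], proba),
                "kappa": balanced_kappa(y[te], pred, n_downsamples, seed=rep),
            }
        )
        pooled_y.append(y[te])
        pooled_p.append(proba)
    pooled_y = np.concatenate(pooled_y)
    pooled_p = np.concatenate(pooled_p)
    return CVReport(
        per_repetition=pd.DataFrame(rows),
        crossover=crossover_cutoff(pooled_y, pooled_p),
        pooled_labels=pooled_y,
        pooled_scores=pooled_p,
    )
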