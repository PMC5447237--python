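"""Metrics for comparing automated and reference annotations.

Population-frequency agreement is measured by three histogram distances
(maximum error, Canberra, intersection), single-cell agreement by
per-class precision/recall/F1, cluster tightness by the silhouette
coefficient, and replicate tracking by per-class Pearson correlation of
estimated versus reference frequencies across samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class FrequencyHistogram:
    """Normalized class frequencies over an explicit class order."""

    classes: list[str]
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.classes),):
            raise ParameterError("one frequency per class required")
        if (self.freqs < 0).any():
            raise ParameterError("frequencies must be nonnegative")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"frequencies must sum to 1, got {self.freqs.sum():.12f}"
            )

    @classmethod
    def from_labels(cls, labels, classes: list[str]) -> "FrequencyHistogram":
        labels = np.asarray(labels, dtype=object)
        counts = np.array([(labels == c).sum() for c in classes], dtype=float)
        if counts.sum() == 0:
            raise ParameterError("no labels fall in the declared class order")
        return cls(classes=list(classes), freqs=counts / counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=self.classes)


def _check_aligned(h1: FrequencyHistogram, h2: FrequencyHistogram) -> None:
    if h1.classes != h2.classes:
        raise ParameterError(
            f"histogram class orders differ: {h1.classes} vs {h2.classes}"
        )


def max_error(h1: FrequencyHistogram, h2: FrequencyHistogram) -> float:
    """Largest absolute per-class frequency discrepancy, in [0, 1]."""
    _check_aligned(h1, h2)
    return float(np.abs(h1.freqs - h2.freqs).max())


def canberra(h1: FrequencyHistogram, h2: FrequencyHistogram) -> float:
    """Canberra distance ``sum |h1-h2| / (h1+h2)`` with 0/0 = 0.

    Each class contributes at most 1, so rare populations are weighted as
    heavily as abundant ones — this is the rare-population-sensitive
    metric.
    """
    _check_aligned(h1, h2)
    num = np.abs(h1.freqs - h2.freqs)
    den = h1.freqs + h2.freqs
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(terms.sum())


def intersection_distance(h1: FrequencyHistogram, h2: FrequencyHistogram) -> float:
    """One minus the histograms' common area; equals half the L1 distance."""
    _check_aligned(h1, h2)
    return float(max(0.0, 1.0 - np.minimum(h1.freqs, h2.freqs).sum()))


@dataclass
class ConfusionMatrix:
    """Counts ``C[i, j]`` = events predicted class i whose reference is j."""

    classes: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ParameterError("square counts matrix required")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ParameterError("counts must be nonnegative integers")

    @classmethod
    def from_labels(cls, predicted, reference, classes=None) -> "ConfusionMatrix":
        predicted = np.asarray(predicted, dtype=object)
        reference = np.asarray(reference, dtype=object)
        if predicted.shape != reference.shape:
            raise ParameterError("label vectors must have equal length")
        if classes is None:
            classes = sorted(set(map(str, predicted)) | set(map(str, reference)))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for p, r in zip(predicted, reference):
            counts[index[str(p)], index[str(r)]] += 1
        return cls(classes=list(classes), counts=counts)


def f1_scores(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision (purity), recall (yield) and F1.

    A class never predicted or never present in the reference gets F1 = 0
    and is flagged in the ``degenerate`` column.
    """
    counts = cm.counts.astype(float)
    predicted_totals = counts.sum(axis=1)
    reference_totals = counts.sum(axis=0)
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted_totals > 0, diag / predicted_totals, 0.0)
        recall = np.where(reference_totals > 0, diag / reference_totals, 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    degenerate = (predicted_totals == 0) | (reference_totals == 0)
    if degenerate.any():
        logger.info(
            "classes with no predictions or no members: %s",
            [c for c, d in zip(cm.classes, degenerate) if d],
        )
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "degenerate": degenerate,
        },
        index=cm.classes,
    )


def accuracy(predicted, reference) -> float:
    """Fraction of events whose predicted label equals the reference."""
    predicted = np.asarray(predicted, dtype=object).astype(str)
    reference = np.asarray(reference, dtype=object).astype(str)
    if predicted.shape != reference.shape:
        raise ParameterError("label vectors must have equal length")
    return float(np.mean(predicted == reference))


def collapse_unknown(labels, known_classes=None) -> np.ndarray:
    """Map every unknown sub-cluster label (``unknown:<i>``) to ``unknown``.

    If ``known_classes`` is given, any label outside it also maps to
    ``unknown`` — references often mark events left out of manual gating
    with labels of their own ("ungated", a novel population name, ...),
    and for metric purposes those are the unknown class.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    out = labels.copy()
    out[np.char.startswith(labels.astype(str), "unknown")] = "unknown"
    if known_classes is not None:
        known = set(known_classes) | {"unknown"}
        out[~np.isin(out, list(known))] = "unknown"
    return out.astype(object)


def silhouette(
    points: np.ndarray,
    labels,
    subsample: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-point silhouette coefficients (Euclidean).

    ``s_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean distance
    to the point's own class (self excluded) and ``b_i`` the smallest mean
    distance to another class.  Values lie in [-1, 1]; negative means the
    point sits closer to another class than its own.  Singleton classes
    get coefficient 0 and are flagged in the log.  ``subsample`` draws a
    uniform subset (seeded) before computing, for large inputs.

    Raises
    ------
    ParameterError
        If fewer than 2 distinct classes are present.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(points) != len(labels):
        raise ParameterError("one label per point required")
    if subsample is not None and subsample < len(points):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(points), size=subsample, replace=False)
        points, labels = points[keep], labels[keep]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("silhouette requires at least 2 classes")
    singletons = classes[counts == 1]
    if len(singletons):
        logger.info("singleton classes get silhouette 0: %s", list(singletons))
    return silhouette_samples(points, labels, metric="euclidean")


def per_type_correlation(
    estimated: dict[str, FrequencyHistogram],
    reference: dict[str, FrequencyHistogram],
) -> pd.Series:
    """Pearson r between estimated and reference frequencies, per class.

    Correlations run across samples (>= 3 required, matching keys).  A
    class whose estimated or reference series has zero variance has an
    undefined correlation and is reported as NaN (never imputed as 0,
    which would bias any average over classes).
    """
    if set(estimated) != set(reference):
        raise ParameterError(
            f"sample sets differ: {sorted(estimated)} vs {sorted(reference)}"
        )
    sample_ids = sorted(estimated)
    if len(sample_ids) < 3:
        raise ParameterError("need at least 3 samples for per-type correlation")
    classes = estimated[sample_ids[0]].classes
    for sid in sample_ids:
        if estimated[sid].classes != classes or reference[sid].classes != classes:
            raise ParameterError("all histograms must share one class order")
    est = np.array([estimated[sid].freqs for sid in sample_ids])
    ref = np.array([reference[sid].freqs for sid in sample_ids])
    out = {}
    for i, cls_name in enumerate(classes):
        if est[:, i].std() == 0 or ref[:, i].std() == 0:
            logger.info("zero-variance frequency series for %r; r undefined", cls_name)
            out[cls_name] = np.nan
        else:
            out[cls_name] = pearsonr(est[:, i], ref[:, i]).statistic
    return pd.Series(out)


def stratified_folds(labels, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment preserving per-class proportions.

    Classes with fewer than ``n_folds`` members cannot be stratified; they
    are spread round-robin over folds and flagged in the log.  Folds are
    disjoint, cover every event, and are deterministic given ``seed``.

    Raises
    ------
    ParameterError
        If ``n_folds < 2``.
    """
    if n_folds < 2:
        raise ParameterError(f"n_folds must be >= 2, got {n_folds}")
    labels = np.asarray(labels, dtype=object).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    small = set(classes[counts < n_folds])
    if small:
        logger.info(
            "classes with < %d members assigned round-robin: %s", n_folds, sorted(small)
        )
    assignment = np.full(len(labels), -1, dtype=int)
    big_mask = ~np.isin(labels, list(small))
    if big_mask.sum():
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        big_idx = np.flatnonzero(big_mask)
        for fold, (_, test) in enumerate(
            splitter.split(np.zeros(big_mask.sum()), labels[big_mask])
        ):
            assignment[big_idx[test]] = fold
    rng = np.random.default_rng(seed)
    for cls_name in sorted(small):
        members = np.flatnonzero(labels == cls_name)
        start = int(rng.integers(n_folds))
        for offset, idx in enumerate(members):
            assignment[idx] = (start + offset) % n_folds
    assert (assignment >= 0).all()
    return assignment
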