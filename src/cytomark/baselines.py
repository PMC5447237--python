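"""The two reference baselines and the three-way comparison report.

(i) score-based classification: every event to its argmax score class
(needs no reference labels); (ii) cluster-plus-majority-vote: community
detection on the full data, every event inheriting its community's most
frequent *reference* label (needs reference labels).  ``run_baselines``
evaluates both — and optionally the full walker pipeline — with the same
metric suite so methods can be compared side by side.
"""
from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .errors import ParameterError
from .evaluation import (
    ConfusionMatrix,
    FrequencyHistogram,
    accuracy,
    canberra,
    collapse_unknown,
    f1_scores,
    intersection_distance,
    max_error,
)
from .landmarks import cluster_majority_baseline
from .marker_table import MarkerTable
from .preprocessing import EventMatrix
from .scoring import classify_by_score, fit_marker_models, score_events

logger = logging.getLogger(__name__)


def _evaluate_method(predicted, reference, classes) -> dict:
    predicted = collapse_unknown(predicted, known_classes=classes)
    reference = collapse_unknown(reference, known_classes=classes)
    universe = list(classes) + ["unknown"]
    cm = ConfusionMatrix.from_labels(predicted, reference, classes=universe)
    per_class = f1_scores(cm)
    h_pred = FrequencyHistogram.from_labels(predicted, universe)
    h_ref = FrequencyHistogram.from_labels(reference, universe)
    return {
        "accuracy": accuracy(predicted, reference),
        "f1": per_class["f1"].to_dict(),
        "median_f1": float(per_class["f1"].median()),
        "max_error": max_error(h_pred, h_ref),
        "canberra": canberra(h_pred, h_ref),
        "intersection": intersection_distance(h_pred, h_ref),
    }


def run_baselines(
    events: EventMatrix,
    table: MarkerTable,
    reference_labels=None,
    config: RunConfig | None = None,
    extra_predictions: dict[str, np.ndarray] | None = None,
) -> dict:
    """Run both baselines and (when references exist) score everything.

    Returns a dict with per-method label arrays under ``"labels"`` and,
    when ``reference_labels`` is given, a per-method metric report under
    ``"report"``.  ``extra_predictions`` lets callers slot in additional
    methods (e.g. the walker pipeline's labels) for a uniform report.

    Raises
    ------
    ParameterError
        If the cluster-majority baseline is requested without references.
    """
    cfg = config or RunConfig()
    models = fit_marker_models(events, seed=cfg.seed)
    scores = score_events(events, table, models)
    labels: dict[str, np.ndarray] = {"score_based": classify_by_score(scores)}

    if reference_labels is not None:
        reference_labels = np.asarray(reference_labels, dtype=object)
        if len(reference_labels) != events.n_events:
            raise ParameterError("one reference label per event required")
        labels["cluster_majority"] = cluster_majority_baseline(
            events, reference_labels, k=cfg.jaccard_knn, seed=cfg.seed
        )
    if extra_predictions:
        labels.update(extra_predictions)

    out: dict = {"labels": labels}
    if reference_labels is not None:
        out["report"] = {
            method: _evaluate_method(pred, reference_labels, table.cell_types)
            for method, pred in labels.items()
        }
    else:
        logger.info("no reference labels: baseline run without metric report")
    return out
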