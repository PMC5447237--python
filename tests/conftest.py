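"""Shared fixtures.

The expensive full-scale benchmark pipeline is computed once per session
and shared by the end-to-end and robustness tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import cytomark as cm
from cytomark.synthetic import NOVEL_TYPE_NAME

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TABLE_CSV = """cell_type,CD3,CD4,CD8,CD19
CD4 T cells,+,+1,-,
CD8 T cells,+1,-1,+,0
B cells,-,,0,+1
"""


@pytest.fixture
def small_table() -> cm.MarkerTable:
    return cm.parse_marker_table(TABLE_CSV)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_events(values, markers, sample_id="s0") -> cm.EventMatrix:
    values = np.asarray(values, dtype=float)
    return cm.EventMatrix(
        values=values,
        marker_names=list(markers),
        sample_ids=np.full(len(values), sample_id, dtype=object),
    )


@pytest.fixture(scope="session")
def benchmark_run():
    """Full-scale canonical benchmark plus a complete pipeline run."""
    samples, table, labels, freqs, spec = cm.standard_benchmark(seed=7)
    result = cm.run_pipeline(samples, table)
    return {
        "samples": samples,
        "table": table,
        "labels": labels,
        "freqs": freqs,
        "spec": spec,
        "result": result,
    }


def benchmark_accuracy(run, predictions=None) -> float:
    """Overall accuracy with unknown sub-clusters and the novel type collapsed."""
    table = run["table"]
    ref = cm.collapse_unknown(
        np.concatenate(run["labels"]), known_classes=table.cell_types
    )
    if predictions is None:
        predictions = np.concatenate(
            [run["result"].labels[s.sample_ids[0]] for s in run["samples"]]
        )
    pred = cm.collapse_unknown(predictions, known_classes=table.cell_types)
    return cm.accuracy(pred, ref)


@pytest.fixture(scope="session")
def novel_mask(benchmark_run):
    return np.concatenate(benchmark_run["labels"]) == NOVEL_TYPE_NAME
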