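"""Event-matrix I/O, the arcsinh transform and replicate pooling.

Mass cytometry intensities are heavy-tailed counts; the standard
variance-stabilizing transform is ``asinh((x - shift) / cofactor)`` with
``shift = 1`` and ``cofactor = 5``.  All downstream modelling assumes the
transformed scale, so the transform is applied exactly once, explicitly.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class EventMatrix:
    """``n_events x n_markers`` intensity matrix with per-event provenance.

    Attributes
    ----------
    values : numpy.ndarray
        Float matrix, one row per event (cell), one column per marker.
    marker_names : list of str
        Column names, in column order.
    sample_ids : numpy.ndarray of str
        Per-event replicate/sample identifier (length ``n_events``), so
        pooled matrices can be split back exactly.
    """

    values: np.ndarray = field(repr=False)
    marker_names: list[str]
    sample_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("event values must be a 2-D matrix")
        if len(self.marker_names) != self.values.shape[1]:
            raise FormatError(
                f"{len(self.marker_names)} marker names for "
                f"{self.values.shape[1]} columns"
            )
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.sample_ids.shape != (self.values.shape[0],):
            raise FormatError("sample_ids length must equal the event count")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite intensity at event {bad[0]}, marker "
                f"{self.marker_names[bad[1]]!r}"
            )

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_names.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.marker_names)


def read_events(source, format: str = "csv", sample_id: str = "sample") -> EventMatrix:
    """Read raw (untransformed) event data.

    Parameters
    ----------
    source : path, file-like or CSV text
        CSV with a marker-named header row; every other cell numeric.
    format : str
        Only ``"csv"`` is supported.
    sample_id : str
        Identifier attached to every event of this file.

    Raises
    ------
    FormatError
        Missing header, non-numeric cells (the error names the row), or an
        unsupported format.
    """
    if format != "csv":
        raise FormatError(f"unsupported event format {format!r}; expected 'csv'")
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        source = Path(source)
    try:
        frame = pd.read_csv(source, header=0)
    except Exception as exc:
        raise FormatError(f"cannot read event CSV: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError("event CSV has no columns")
    markers = [str(c).strip() for c in frame.columns]
    if any(m == "" or m.startswith("Unnamed:") for m in markers):
        raise FormatError("event CSV header is missing marker names")

    def _is_number(token: str) -> bool:
        try:
            float(token)
            return True
        except ValueError:
            return False

    if all(_is_number(m) for m in markers):
        raise FormatError("event CSV has no header row (first line is numeric)")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.any().any() or frame.isna().any().any():
        mask = (numeric.isna()).any(axis=1)
        row = int(np.argmax(mask.to_numpy()))
        raise FormatError(f"non-numeric value in event CSV at data row {row}")
    values = numeric.to_numpy(dtype=float)
    ids = np.full(values.shape[0], sample_id, dtype=object)
    return EventMatrix(values=values, marker_names=markers, sample_ids=ids)


def write_events(events: EventMatrix, path) -> None:
    """Write the numeric content as a marker-named-header CSV."""
    events.to_frame().to_csv(path, index=False)


def arcsinh_transform(
    raw: EventMatrix, cofactor: float = 5.0, shift: float = 1.0
) -> EventMatrix:
    """Apply ``x -> asinh((x - shift) / cofactor)`` elementwise.

    Strictly monotone per marker, so column order statistics are preserved;
    invertible via ``x = sinh(y) * cofactor + shift``.

    Raises
    ------
    ParameterError
        If ``cofactor <= 0``.
    """
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    values = np.arcsinh((raw.values - shift) / cofactor)
    return EventMatrix(
        values=values,
        marker_names=list(raw.marker_names),
        sample_ids=raw.sample_ids.copy(),
    )


def inverse_arcsinh_transform(
    transformed: EventMatrix, cofactor: float = 5.0, shift: float = 1.0
) -> EventMatrix:
    """Inverse of :func:`arcsinh_transform` (``sinh(y) * cofactor + shift``)."""
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    values = np.sinh(transformed.values) * cofactor + shift
    return EventMatrix(
        values=values,
        marker_names=list(transformed.marker_names),
        sample_ids=transformed.sample_ids.copy(),
    )


def pool_replicates(samples: list[EventMatrix]) -> EventMatrix:
    """Row-concatenate replicates that share an identical marker panel.

    The per-event ``sample_ids`` record the origin so :func:`unpool`
    recovers the inputs exactly.

    Raises
    ------
    AlignmentError
        If any two samples disagree on marker names or their order.
    """
    if not samples:
        raise AlignmentError("no samples to pool")
    reference = samples[0].marker_names
    for idx, sample in enumerate(samples[1:], start=1):
        if sample.marker_names != reference:
            diff = set(sample.marker_names) ^ set(reference)
            detail = f"symmetric difference {sorted(diff)}" if diff else "column order"
            raise AlignmentError(
                f"sample {idx} marker panel mismatch with sample 0: {detail}"
            )
    values = np.vstack([s.values for s in samples])
    ids = np.concatenate([s.sample_ids for s in samples])
    return EventMatrix(values=values, marker_names=list(reference), sample_ids=ids)


def unpool(pooled: EventMatrix) -> dict[str, EventMatrix]:
    """Split a pooled matrix back into per-sample matrices by ``sample_ids``.

    Sample order follows first appearance in the pooled matrix.
    """
    out: dict[str, EventMatrix] = {}
    ids = pooled.sample_ids
    seen: list[str] = []
    for sid in ids:
        if sid not in seen:
            seen.append(sid)
    for sid in seen:
        mask = ids == sid
        out[sid] = EventMatrix(
            values=pooled.values[mask],
            marker_names=list(pooled.marker_names),
            sample_ids=ids[mask].copy(),
        )
    return out
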