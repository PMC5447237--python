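"""Cell-type/marker sign tables.

A marker table is the prior-knowledge input of the pipeline: one row per
canonical cell type, one column per marker, entries in {+1, -1, 0} meaning
"marker must be high", "marker must be low" and "do not consider".  A CD4
T cell, for instance, is the row CD3:+1, CD4:+1, CD8:-1 with every other
marker 0.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableError

logger = logging.getLogger(__name__)

#: accepted spellings for each sign (ASCII and Unicode minus, blank = 0)
_SIGN_VOCAB = {
    "+1": 1, "1": 1, "+": 1,
    "-1": -1, "−1": -1, "-": -1, "−": -1,
    "0": 0, "": 0,
}


@dataclass(frozen=True)
class MarkerTable:
    """Validated sign matrix linking cell types to marker requirements.

    Attributes
    ----------
    cell_types : list of str
        Ordered cell-type names (unique, case-sensitive).
    markers : list of str
        Ordered marker names (unique, case-sensitive).
    signs : numpy.ndarray
        Integer matrix of shape ``(n_types, n_markers)`` with entries in
        ``{+1, -1, 0}``.
    """

    cell_types: list[str]
    markers: list[str]
    signs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs, dtype=int)
        object.__setattr__(self, "signs", signs)
        if signs.shape != (len(self.cell_types), len(self.markers)):
            raise TableError(
                f"sign matrix shape {signs.shape} does not match "
                f"{len(self.cell_types)} types x {len(self.markers)} markers"
            )
        if not np.isin(signs, (-1, 0, 1)).all():
            raise TableError("sign matrix entries must be +1, -1 or 0")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise TableError("duplicate cell-type names")
        if len(set(self.markers)) != len(self.markers):
            raise TableError("duplicate marker names")
        empty = [t for t, row in zip(self.cell_types, signs) if not row.any()]
        if empty:
            raise TableError(f"cell types with no marker requirement: {empty}")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sign(self, cell_type: str, marker: str) -> int:
        return int(
            self.signs[self.cell_types.index(cell_type), self.markers.index(marker)]
        )

    def specified_markers(self, cell_type: str) -> list[str]:
        """Markers with a nonzero requirement for ``cell_type``."""
        row = self.signs[self.cell_types.index(cell_type)]
        return [m for m, s in zip(self.markers, row) if s != 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signs, index=self.cell_types, columns=self.markers)

    def to_csv(self, path=None) -> str | None:
        """Serialize to the canonical CSV shape (first column = cell_type)."""
        frame = self.to_frame()
        frame.index.name = "cell_type"
        return frame.to_csv(path)


def parse_marker_table(source) -> MarkerTable:
    """Parse a cell-type/marker table from CSV.

    Parameters
    ----------
    source : path, file-like or str
        CSV whose first column holds cell-type names and whose remaining
        columns are markers.  Cells may contain ``+1/1/+``, ``-1/-`` (ASCII
        or Unicode minus), ``0`` or be blank (blank means 0, "do not
        consider").  A multi-line string is treated as CSV text.

    Returns
    -------
    MarkerTable

    Raises
    ------
    TableError
        On duplicate names, an entry outside the sign vocabulary (the error
        names the offending row and column), or an all-zero row.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        source = Path(source)
    try:
        raw = pd.read_csv(source, dtype=str, keep_default_na=False, index_col=0,
                          header=None, skiprows=1)
        if isinstance(source, io.StringIO):
            source.seek(0)
        header = pd.read_csv(source, dtype=str, keep_default_na=False,
                             header=None, nrows=1)
    except Exception as exc:  # pandas raises many flavours; unify
        raise TableError(f"cannot read marker table: {exc}") from exc

    # header parsed separately: pandas would silently rename duplicates
    markers = [str(m).strip() for m in header.iloc[0, 1:]]
    cell_types = [str(t).strip() for t in raw.index]
    if raw.shape[1] != len(markers):
        raise TableError("marker table rows do not match the header width")
    signs = np.zeros((len(cell_types), len(markers)), dtype=int)
    for i, ctype in enumerate(cell_types):
        for j, marker in enumerate(markers):
            token = str(raw.iat[i, j]).strip()
            if token not in _SIGN_VOCAB:
                raise TableError(
                    f"invalid entry {token!r} at row {ctype!r}, column {marker!r}; "
                    "expected +1, -1, 0 or blank"
                )
            signs[i, j] = _SIGN_VOCAB[token]
    return MarkerTable(cell_types=cell_types, markers=markers, signs=signs)


@dataclass
class PanelValidationReport:
    """Outcome of checking a table against an event-data marker panel."""

    missing_markers: list[str]   # fatal: table needs them, panel lacks them
    unused_markers: list[str]    # informational: measured but never consulted
    empty_types: list[str]       # fatal: all-zero rows (unreachable via parse)

    @property
    def fatal(self) -> bool:
        return bool(self.missing_markers or self.empty_types)


def validate_against_panel(
    table: MarkerTable, panel_markers: list[str], strict: bool = True
) -> PanelValidationReport:
    """Check that every table marker is measured in the panel.

    Marker matching is exact string equality after whitespace trimming; no
    fuzzy matching is attempted, a silent mis-mapping being worse than a
    hard error.

    Raises
    ------
    TableError
        If ``strict`` and a fatal finding exists (a table marker missing
        from the panel, or an all-zero type row).  Informational findings
        (panel markers the table ignores) are only logged.
    """
    panel = [str(m).strip() for m in panel_markers]
    panel_set = set(panel)
    missing = [m for m in table.markers if m not in panel_set]
    unused = [m for m in panel if m not in set(table.markers)]
    empty = [t for t, row in zip(table.cell_types, table.signs) if not row.any()]
    report = PanelValidationReport(missing, unused, empty)
    if unused:
        logger.info("panel markers unused by the table: %s", unused)
    if strict and report.fatal:
        parts = []
        if missing:
            parts.append(f"table markers not in panel: {missing}")
        if empty:
            parts.append(f"cell types with all-zero rows: {empty}")
        raise TableError("; ".join(parts))
    return report
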