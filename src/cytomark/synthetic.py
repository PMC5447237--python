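"""Synthetic cytometry data with known ground truth.

The generator emulates the structure the annotation method assumes: every
marker's transformed (arcsinh-scale) intensity is bimodal — a "low" and a
"high" Gaussian mode — and each cell type is a fixed binary on/off profile
over the markers.  An event of type ``t`` draws marker ``k`` from
``N(mu_high, sigma^2)`` if the type's profile is high there, else from
``N(mu_low, sigma^2)``.  Markers a type's table row ignores ("don't
care", sign 0) still have a definite state in the cells themselves: the
state is fixed once per (type, marker) — resampling per event would smear
a type into an incoherent cloud, which real populations are not.

Replicates share the type profiles but may vary their composition: with a
finite ``freq_concentration`` each replicate's type frequencies are drawn
from a Dirichlet centred on the base frequencies, mimicking biological
sample-to-sample variation.

``standard_benchmark`` is the package's canonical fixture: 8 canonical
immune populations over a 12-marker panel (nested T-cell subsets, B, NK,
two monocyte subsets, a rare pDC population at 0.5% and basophils) plus a
CD3+CD19+ "novel" population deliberately absent from the table, so the
unknown-discovery path is exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .marker_table import MarkerTable
from .preprocessing import EventMatrix

NOVEL_TYPE_NAME = "novel:B/T-mixed"


@dataclass
class SyntheticSpec:
    """Full description of a synthetic experiment.

    Attributes
    ----------
    table : MarkerTable
        The prior-knowledge table given to the classifier (novel types are
        *not* in it).
    type_frequencies : dict
        Base frequency per generated type, including novel types; must sum
        to 1.
    n_events, n_replicates : int
        Events per replicate and replicate count.
    mu_low, mu_high, sigma : float
        Shared two-mode parameters on the transformed scale;
        ``(mu_high - mu_low) / sigma`` is the mode separation.
    dontcare_high_prob : float
        Probability that a marker with table sign 0 is in the high state
        for a given type (drawn once per type/marker when ``profiles`` is
        not given).
    novel_profiles : dict
        ``name -> {marker: 0|1}`` full binary profiles for populations not
        in the table.
    profiles : dict or None
        Optional explicit full profiles for table types; if None they are
        derived from the table signs plus don't-care coin flips.
    freq_concentration : float or None
        Dirichlet concentration for per-replicate frequency perturbation
        (None = identical frequencies every replicate).
    seed : int
        Seed for every random choice.
    """

    table: MarkerTable
    type_frequencies: dict[str, float]
    n_events: int = 20000
    n_replicates: int = 3
    mu_low: float = 0.0
    mu_high: float = 4.0
    sigma: float = 1.0
    dontcare_high_prob: float = 0.2
    novel_profiles: dict[str, dict[str, int]] = field(default_factory=dict)
    profiles: dict[str, dict[str, int]] | None = None
    freq_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array(list(self.type_frequencies.values()), dtype=float)
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ParameterError("type frequencies must be nonnegative and sum to 1")
        expected = set(self.table.cell_types) | set(self.novel_profiles)
        if set(self.type_frequencies) != expected:
            raise ParameterError(
                "type_frequencies keys must be table types plus novel types"
            )
        if self.mu_high <= self.mu_low:
            raise ParameterError("mu_high must exceed mu_low")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if not (0 <= self.dontcare_high_prob <= 1):
            raise ParameterError("dontcare_high_prob must be in [0, 1]")
        if self.n_events < 1 or self.n_replicates < 1:
            raise ParameterError("n_events and n_replicates must be >= 1")

    @property
    def type_names(self) -> list[str]:
        return list(self.type_frequencies)

    def resolve_profiles(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Full binary (0/1 = low/high) profile per generated type."""
        markers = self.table.markers
        out: dict[str, np.ndarray] = {}
        for j, ctype in enumerate(self.table.cell_types):
            if self.profiles is not None and ctype in self.profiles:
                given = self.profiles[ctype]
                state = np.array([int(given[m]) for m in markers])
                signs = self.table.signs[j]
                implied = np.where(signs == 1, 1, np.where(signs == -1, 0, state))
                if not np.array_equal(state, implied):
                    raise ParameterError(
                        f"profile for {ctype!r} contradicts its table row"
                    )
            else:
                signs = self.table.signs[j]
                coin = (rng.random(len(markers)) < self.dontcare_high_prob).astype(int)
                state = np.where(signs == 1, 1, np.where(signs == -1, 0, coin))
            out[ctype] = state
        for name, given in self.novel_profiles.items():
            out[name] = np.array([int(given[m]) for m in markers])
        return out


def simulate_events(
    spec: SyntheticSpec,
) -> tuple[list[EventMatrix], list[np.ndarray], list[np.ndarray]]:
    """Draw the replicates described by ``spec``.

    Returns
    -------
    (samples, labels, true_frequencies)
        Per replicate: an :class:`EventMatrix` on the transformed scale
        (sample ids ``rep1``, ``rep2``, ...), the per-event true type
        names, and the realized (empirical) type frequency vector in
        ``spec.type_names`` order.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = spec.resolve_profiles(rng)
    type_names = spec.type_names
    base = np.array([spec.type_frequencies[t] for t in type_names])

    samples: list[EventMatrix] = []
    labels_out: list[np.ndarray] = []
    freqs_out: list[np.ndarray] = []
    for rep in range(spec.n_replicates):
        if spec.freq_concentration is not None:
            alpha = np.maximum(spec.freq_concentration * base, 1e-6)
            freqs = rng.dirichlet(alpha)
        else:
            freqs = base
        counts = rng.multinomial(spec.n_events, freqs)
        blocks, label_blocks = [], []
        for t, count in zip(type_names, counts):
            if count == 0:
                continue
            means = np.where(profiles[t] == 1, spec.mu_high, spec.mu_low)
            blocks.append(rng.normal(means, spec.sigma, size=(count, len(means))))
            label_blocks.append(np.full(count, t, dtype=object))
        values = np.vstack(blocks)
        labels = np.concatenate(label_blocks)
        order = rng.permutation(len(labels))
        values, labels = values[order], labels[order]
        sid = f"rep{rep + 1}"
        samples.append(
            EventMatrix(
                values=values,
                marker_names=list(spec.table.markers),
                sample_ids=np.full(len(labels), sid, dtype=object),
            )
        )
        labels_out.append(labels)
        freqs_out.append(counts / counts.sum())
    return samples, labels_out, freqs_out


_BENCHMARK_MARKERS = [
    "CD3", "CD4", "CD8", "CD7", "CD19", "CD20",
    "CD56", "CD14", "CD16", "CD33", "HLA-DR", "CD123",
]

# table rows: marker -> sign; only the gating-relevant requirements
_BENCHMARK_TABLE_ROWS: dict[str, dict[str, int]] = {
    "CD4 T cells": {"CD3": 1, "CD4": 1, "CD8": -1, "CD19": -1},
    "CD8 T cells": {"CD3": 1, "CD8": 1, "CD4": -1, "CD19": -1},
    "B cells": {"CD19": 1, "CD20": 1, "CD3": -1},
    "NK cells": {"CD56": 1, "CD16": 1, "CD7": 1, "CD3": -1, "CD19": -1},
    "Classical monocytes": {"CD14": 1, "CD33": 1, "HLA-DR": 1, "CD3": -1, "CD19": -1},
    "Nonclassical monocytes": {"CD16": 1, "CD14": -1, "CD33": 1, "HLA-DR": 1, "CD3": -1},
    "pDC": {"CD123": 1, "HLA-DR": 1, "CD14": -1, "CD3": -1, "CD19": -1},
    "Basophils": {"CD123": 1, "HLA-DR": -1, "CD3": -1, "CD19": -1, "CD14": -1},
}

# full generating profiles (high markers listed; everything else low)
_BENCHMARK_PROFILES_HIGH: dict[str, list[str]] = {
    "CD4 T cells": ["CD3", "CD4", "CD7"],
    "CD8 T cells": ["CD3", "CD8", "CD7"],
    "B cells": ["CD19", "CD20", "HLA-DR"],
    "NK cells": ["CD56", "CD16", "CD7"],
    "Classical monocytes": ["CD14", "CD33", "HLA-DR"],
    "Nonclassical monocytes": ["CD16", "CD33", "HLA-DR"],
    "pDC": ["CD123", "HLA-DR"],
    "Basophils": ["CD123"],
}

#: base composition; pDC is the deliberately rare population and the novel
#: B/T-mixed population is absent from the table
_BENCHMARK_FREQUENCIES: dict[str, float] = {
    "CD4 T cells": 0.25,
    "CD8 T cells": 0.15,
    "B cells": 0.12,
    "NK cells": 0.08,
    "Classical monocytes": 0.20,
    "Nonclassical monocytes": 0.06,
    "pDC": 0.005,
    "Basophils": 0.105,
    NOVEL_TYPE_NAME: 0.03,
}

_NOVEL_PROFILE_HIGH = ["CD3", "CD4", "CD19", "CD20"]


def benchmark_table() -> MarkerTable:
    """The 8-type, 12-marker prior-knowledge table of the benchmark."""
    signs = np.zeros((len(_BENCHMARK_TABLE_ROWS), len(_BENCHMARK_MARKERS)), dtype=int)
    for i, (ctype, row) in enumerate(_BENCHMARK_TABLE_ROWS.items()):
        for marker, sign in row.items():
            signs[i, _BENCHMARK_MARKERS.index(marker)] = sign
    return MarkerTable(
        cell_types=list(_BENCHMARK_TABLE_ROWS),
        markers=list(_BENCHMARK_MARKERS),
        signs=signs,
    )


def benchmark_spec(
    seed: int = 0,
    n_events: int = 20000,
    n_replicates: int = 3,
    hard: bool = False,
    freq_concentration: float | None = None,
) -> SyntheticSpec:
    """The canonical benchmark spec (4-sigma mode separation by default).

    ``hard=True`` halves the separation to 2 sigma for stress testing.
    """

    def as_profile(high: list[str]) -> dict[str, int]:
        return {m: int(m in high) for m in _BENCHMARK_MARKERS}

    return SyntheticSpec(
        table=benchmark_table(),
        type_frequencies=dict(_BENCHMARK_FREQUENCIES),
        n_events=n_events,
        n_replicates=n_replicates,
        mu_low=0.0,
        mu_high=4.0,
        sigma=2.0 if hard else 1.0,
        profiles={t: as_profile(h) for t, h in _BENCHMARK_PROFILES_HIGH.items()},
        novel_profiles={NOVEL_TYPE_NAME: as_profile(_NOVEL_PROFILE_HIGH)},
        freq_concentration=freq_concentration,
        seed=seed,
    )


def standard_benchmark(
    seed: int = 0,
    n_events: int = 20000,
    n_replicates: int = 3,
    hard: bool = False,
    freq_concentration: float | None = None,
):
    """Generate the canonical benchmark.

    Returns
    -------
    (samples, table, labels, true_frequencies, spec)
        Replicate event matrices (transformed scale), the prior-knowledge
        table (8 types; the ninth, novel population is not in it), the
        per-replicate true labels, the per-replicate realized frequency
        vectors (in ``spec.type_names`` order) and the spec itself.
    """
    spec = benchmark_spec(
        seed=seed,
        n_events=n_events,
        n_replicates=n_replicates,
        hard=hard,
        freq_concentration=freq_concentration,
    )
    samples, labels, freqs = simulate_events(spec)
    return samples, spec.table, labels, freqs, spec
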