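"""Marker positivity models and the cell-type score function.

Each marker's transformed intensity is modelled as a two-component Gaussian
mixture; the component with the larger mean is the "high" (activated)
state.  The posterior probability of the high state is then replaced by a
logistic approximation

    P~(high | w) = 1 / (1 + exp(-b (w - a)))

where ``a`` is the critical intensity at which the two weighted component
densities are equal (so the exact posterior is 1/2) and ``b`` makes the
logistic's slope at ``a`` equal the exact posterior's slope there.  The
approximation is used because the exact mixture posterior is not monotone
in ``w`` when the two components have unequal variances, whereas marker
positivity should be: more signal, more positive.

The score of an event ``w`` for a cell type ``c`` with sign row ``s(c, .)``
is the *minimum* of the state posteriors over the markers the table
specifies (every requirement must hold):

    f(w, c) = min over {k : s(c, m_k) != 0} of P~_k(s(c, m_k) | w_k)

and an "unknown" score ``f(w, unknown) = 1 - max_c f(w, c)`` captures
events matching no specified type.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import DegenerateFitError, ParameterError, TableError
from .marker_table import MarkerTable, validate_against_panel
from .preprocessing import EventMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerModel:
    """Fitted two-component mixture for one marker, plus (a, b).

    Component order is fixed: ``mu_low <= mu_high``; the high-mean
    component is the activated state.  ``a`` and ``b`` parameterize the
    logistic posterior approximation (see module docstring).
    """

    marker: str
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    pi_low: float
    pi_high: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.mu_low > self.mu_high:
            raise DegenerateFitError(f"{self.marker}: components out of order")
        if not (self.sigma_low > 0 and self.sigma_high > 0):
            raise DegenerateFitError(f"{self.marker}: non-positive sigma")
        if abs(self.pi_low + self.pi_high - 1.0) > 1e-9:
            raise DegenerateFitError(f"{self.marker}: weights do not sum to 1")
        if not (0 < self.pi_low < 1):
            raise DegenerateFitError(f"{self.marker}: weight outside (0,1)")

    def exact_posterior_high(self, w) -> np.ndarray:
        """Exact Bayes posterior of the high state under the mixture."""
        w = np.asarray(w, dtype=float)
        log_hi = np.log(self.pi_high) + norm.logpdf(w, self.mu_high, self.sigma_high)
        log_lo = np.log(self.pi_low) + norm.logpdf(w, self.mu_low, self.sigma_low)
        return expit(log_hi - log_lo)


def derive_logistic(
    pi_low: float,
    pi_high: float,
    mu_low: float,
    mu_high: float,
    sigma_low: float,
    sigma_high: float,
) -> tuple[float, float]:
    """Critical point ``a`` and logistic rate ``b`` of a fitted mixture.

    ``a`` solves ``pi_high N(a; mu_high, sigma_high^2) =
    pi_low N(a; mu_low, sigma_low^2)`` on ``[mu_low, mu_high]`` (found by
    root-bracketing on the log-density difference, tolerance 1e-12).
    The exact posterior's derivative at ``a`` is

        slope = ((a - mu_low)/sigma_low^2 - (a - mu_high)/sigma_high^2) / 4

    and a logistic with rate ``r`` has slope ``r/4`` at its midpoint, so
    ``b = 4 * slope`` matches the approximation to the exact posterior in
    both value and derivative at ``a``.  For equal component variances the
    exact posterior *is* logistic and the approximation is exact, with
    ``b = (mu_high - mu_low) / sigma^2`` when the weights are also equal.

    Raises
    ------
    DegenerateFitError
        If the log-density difference has no sign change on
        ``[mu_low, mu_high]``.
    """

    def log_density_diff(w: float) -> float:
        return (
            np.log(pi_high)
            + norm.logpdf(w, mu_high, sigma_high)
            - np.log(pi_low)
            - norm.logpdf(w, mu_low, sigma_low)
        )

    lo, hi = log_density_diff(mu_low), log_density_diff(mu_high)
    if lo == 0.0:
        a = mu_low
    elif hi == 0.0:
        a = mu_high
    elif lo * hi > 0:
        raise DegenerateFitError(
            "no posterior crossover between component means "
            f"(means {mu_low:.4g}, {mu_high:.4g})"
        )
    else:
        a = brentq(log_density_diff, mu_low, mu_high, xtol=1e-12, rtol=8.9e-16)
    b = (a - mu_low) / sigma_low**2 - (a - mu_high) / sigma_high**2
    return float(a), float(b)


@dataclass
class MarkerModels:
    """Per-marker models, plus diagnostics for markers that failed to fit."""

    models: dict[str, MarkerModel]
    flagged: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, marker: str) -> MarkerModel:
        if marker in self.flagged:
            raise DegenerateFitError(
                f"marker {marker!r} has a degenerate fit: {self.flagged[marker]}"
            )
        return self.models[marker]

    def to_json(self, path=None) -> str:
        payload = {
            "models": {m: vars(model) for m, model in self.models.items()},
            "flagged": self.flagged,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MarkerModels":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        models = {m: MarkerModel(**kw) for m, kw in payload["models"].items()}
        return cls(models=models, flagged=dict(payload.get("flagged", {})))


def fit_marker_models(
    events: EventMatrix,
    min_events: int = 50,
    seed: int = 0,
    weight_floor: float = 1e-3,
    separation_floor: float = 1e-6,
    bimodality_floor: float = 1.9,
) -> MarkerModels:
    """Fit a two-component univariate Gaussian mixture to every marker.

    EM is initialized by k-means with 10 restarts at a fixed seed, so the
    fit is deterministic given ``seed``.  A marker is *flagged* (not
    fitted) when a component weight falls below ``weight_floor``, the
    component means are closer than ``separation_floor``, or Ashman's
    bimodality index ``D = sqrt(2) |mu_high - mu_low| /
    sqrt(sigma_low^2 + sigma_high^2)`` falls below ``bimodality_floor`` —
    all indicate the column is effectively unimodal (EM fit to a single
    Gaussian settles around D ~ 1.5-1.7, a true two-sigma-separated
    mixture above 2), so the high/low dichotomy is meaningless.  Scoring
    with a flagged marker raises; pass ``bimodality_floor=0`` to disable
    the index check.

    Raises
    ------
    ParameterError
        If fewer than ``min_events`` events are available.
    """
    if events.n_events < min_events:
        raise ParameterError(
            f"need at least {min_events} events to fit marker models, "
            f"got {events.n_events}"
        )
    models: dict[str, MarkerModel] = {}
    flagged: dict[str, str] = {}
    for idx, marker in enumerate(events.marker_names):
        column = events.values[:, idx].reshape(-1, 1)
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="diag",
            n_init=10,
            init_params="kmeans",
            random_state=seed,
            max_iter=1000,
            tol=1e-7,  # the default 1e-3 stops EM far from the optimum
            # when one mode is rare, biasing the high-mode mean
            reg_covar=1e-10,
        )
        try:
            gmm.fit(column)
        except Exception as exc:  # EM blow-up on pathological columns
            flagged[marker] = f"EM failure: {exc}"
            continue
        means = gmm.means_.ravel()
        sigmas = np.sqrt(gmm.covariances_.ravel())
        weights = gmm.weights_.ravel()
        order = np.argsort(means)  # low mean first
        means, sigmas, weights = means[order], sigmas[order], weights[order]
        if weights.min() < weight_floor:
            flagged[marker] = f"component weight {weights.min():.2e} below floor"
            continue
        if means[1] - means[0] < separation_floor:
            flagged[marker] = (
                f"component means separated by {means[1] - means[0]:.2e}"
            )
            continue
        ashman_d = np.sqrt(2.0) * (means[1] - means[0]) / np.sqrt((sigmas**2).sum())
        if ashman_d < bimodality_floor:
            flagged[marker] = (
                f"bimodality index {ashman_d:.2f} below {bimodality_floor} "
                "(column is effectively unimodal)"
            )
            continue
        try:
            a, b = derive_logistic(
                weights[0], weights[1], means[0], means[1], sigmas[0], sigmas[1]
            )
        except DegenerateFitError as exc:
            flagged[marker] = str(exc)
            continue
        models[marker] = MarkerModel(
            marker=marker,
            mu_low=float(means[0]),
            mu_high=float(means[1]),
            sigma_low=float(sigmas[0]),
            sigma_high=float(sigmas[1]),
            pi_low=float(weights[0]),
            pi_high=float(weights[1]),
            a=a,
            b=b,
        )
    if flagged:
        logger.warning("flagged markers (degenerate fits): %s", flagged)
    return MarkerModels(models=models, flagged=flagged)


def logistic_posterior(model: MarkerModel, w, state: int) -> np.ndarray:
    """Approximate posterior ``P~(state | w)`` for ``state`` in ``{+1, -1}``.

    Overflow-safe (evaluated through ``expit``); strictly increasing in
    ``w`` for the high state, with value exactly 1/2 at ``w = a``.
    """
    if state not in (1, -1):
        raise ParameterError(f"state must be +1 or -1, got {state}")
    w = np.asarray(w, dtype=float)
    z = model.b * (w - model.a)
    return expit(z) if state == 1 else expit(-z)


@dataclass
class ScoreMatrix:
    """Event-by-class score matrix; last column is the "unknown" score."""

    values: np.ndarray = field(repr=False)
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.cell_types) + 1:
            raise ValueError("score matrix needs one column per type plus unknown")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def class_names(self) -> list[str]:
        return list(self.cell_types) + ["unknown"]

    @property
    def type_scores(self) -> np.ndarray:
        return self.values[:, :-1]

    @property
    def unknown_scores(self) -> np.ndarray:
        return self.values[:, -1]


def score_events(
    events: EventMatrix, table: MarkerTable, models: MarkerModels
) -> ScoreMatrix:
    """Compute ``f(w, c)`` for every event and table type, plus unknown.

    Raises
    ------
    TableError
        If the table references a marker absent from the event panel.
    DegenerateFitError
        If the table references a flagged marker.
    """
    validate_against_panel(table, events.marker_names, strict=True)
    # per-marker high-state posterior, computed once
    posterior_high = {
        marker: logistic_posterior(models[marker], events.column(marker), +1)
        for marker in table.markers
        if np.any(table.signs[:, table.markers.index(marker)] != 0)
    }
    n = events.n_events
    type_scores = np.empty((n, table.n_types))
    for j, ctype in enumerate(table.cell_types):
        row = table.signs[j]
        stacked = [
            posterior_high[m] if s == 1 else 1.0 - posterior_high[m]
            for m, s in zip(table.markers, row)
            if s != 0
        ]
        if not stacked:  # unreachable through a validated table
            raise TableError(f"cell type {ctype!r} specifies no markers")
        type_scores[:, j] = np.min(stacked, axis=0)
    unknown = 1.0 - type_scores.max(axis=1) if table.n_types else np.ones(n)
    values = np.column_stack([type_scores, unknown])
    return ScoreMatrix(values=values, cell_types=list(table.cell_types))


def classify_by_score(scores: ScoreMatrix) -> np.ndarray:
    """Max-score baseline: each event gets the argmax class (incl. unknown).

    Exact ties resolve to the lowest class index; the number of tied rows
    is logged.
    """
    winners = np.argmax(scores.values, axis=1)
    n_tied = int(
        np.sum((scores.values == scores.values.max(axis=1, keepdims=True)).sum(1) > 1)
    )
    if n_tied:
        logger.info("classify_by_score: %d exact ties broken by class order", n_tied)
    names = np.asarray(scores.class_names, dtype=object)
    return names[winners]
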