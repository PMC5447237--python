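"""Run configuration: every tunable, validated, with provenance output."""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ParameterError


@dataclass
class RunConfig:
    """All pipeline tunables.

    walk_knn
        Neighbours of the classification (walk) graph.
    jaccard_knn
        Neighbours of the clustering graph used for landmark generation.
    threshold
        Score above which an event joins a type subset (default 1/2).
    cofactor, shift
        arcsinh transform parameters ``asinh((x - shift) / cofactor)``.
    min_cluster_size
        Communities smaller than this emit no landmark.
    seed
        Seed for EM restarts and community detection.
    weighted_walk
        Gaussian-kernel walk-graph edge weights (False = unweighted).
    """

    walk_knn: int = 10
    jaccard_knn: int = 30
    threshold: float = 0.5
    cofactor: float = 5.0
    shift: float = 1.0
    min_cluster_size: int = 10
    seed: int = 0
    weighted_walk: bool = True

    def __post_init__(self) -> None:
        if self.walk_knn < 1:
            raise ParameterError(f"walk_knn must be >= 1, got {self.walk_knn}")
        if self.jaccard_knn < 1:
            raise ParameterError(f"jaccard_knn must be >= 1, got {self.jaccard_knn}")
        if not (0 < self.threshold < 1):
            raise ParameterError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.cofactor <= 0:
            raise ParameterError(f"cofactor must be positive, got {self.cofactor}")
        if self.min_cluster_size < 1:
            raise ParameterError(
                f"min_cluster_size must be >= 1, got {self.min_cluster_size}"
            )
        if self.seed < 0:
            raise ParameterError(f"seed must be nonnegative, got {self.seed}")

    def to_text(self, path=None) -> str:
        """Plain ``key = value`` serialization (the provenance file)."""
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_text(cls, source, **overrides) -> "RunConfig":
        """Parse a ``key = value`` config file; keyword overrides win."""
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        values: dict = {}
        casts = {f: t for f, t in cls.__annotations__.items()}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"config line {lineno} is not 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in casts:
                raise ParameterError(f"unknown config key {key!r} (line {lineno})")
            kind = casts[key]
            if kind == "bool":
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif kind == "int":
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        values.update(overrides)
        return cls(**values)
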