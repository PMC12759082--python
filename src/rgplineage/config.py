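"""Run configuration: one validated object mirrored by a YAML/JSON file."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import json

import yaml

from .simulator import DEFAULT_TRANSITION_MATRIX, CloneSizeModel, TransitionMatrix
from .synthetic import NoiseModel, SpatialModel

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    ``seed`` drives every stochastic stage; batches get independent
    substreams.  Simulator, noise and spatial parameters mirror the model
    objects; clustering settings cover the feature stage.
    """

    seed: int = 0
    # simulator
    mixture_weights: tuple[float, float] = (0.35, 0.65)
    mixture_rates: tuple[float, float] = (4.09, 7.62)
    transition_matrix: Optional[list[list[float]]] = None
    batch_size: int = 258
    n_batches: int = 100
    max_clone_size: Optional[int] = None
    # synthetic observation model
    daughter_fraction_sd: float = 0.03
    fraction_bounds: tuple[float, float] = (0.1, 0.9)
    background_level: float = 5e-4
    detection_factor: float = 2.0
    dropout_rate: float = 0.07
    sibling_cluster_scale: float = 15.0
    clone_column_scale: float = 60.0
    # reconstruction
    similar_rel_tol: float = 0.15
    max_working_set: int = 12
    # features / clustering
    n_clusters: int = 5

    def __post_init__(self) -> None:
        self.size_model  # validates weights/rates
        self.matrix      # validates stochasticity
        self.noise_model  # validates rates/bounds
        self.spatial_model

    @property
    def size_model(self) -> CloneSizeModel:
        return CloneSizeModel(
            weights=tuple(self.mixture_weights), rates=tuple(self.mixture_rates)
        )

    @property
    def matrix(self) -> TransitionMatrix:
        if self.transition_matrix is None:
            return DEFAULT_TRANSITION_MATRIX
        return TransitionMatrix(self.transition_matrix)

    @property
    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            daughter_fraction_sd=self.daughter_fraction_sd,
            fraction_bounds=tuple(self.fraction_bounds),
            background_level=self.background_level,
            detection_factor=self.detection_factor,
            dropout_rate=self.dropout_rate,
        )

    @property
    def spatial_model(self) -> SpatialModel:
        return SpatialModel(
            sibling_cluster_scale=self.sibling_cluster_scale,
            clone_column_scale=self.clone_column_scale,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonable(self.to_dict())), encoding="utf-8"
        )


def _jsonable(d):
    if isinstance(d, dict):
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(d, (list, tuple)):
        return [_jsonable(v) for v in d]
    return d


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""

    text = Path(path).read_text(encoding="utf-8")
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    ) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("mixture_weights", "mixture_rates", "fraction_bounds"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
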