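"""Run configuration: everything a full pipeline run needs, serialisable to
YAML so each run can archive its own configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Either ``datasets_dir`` points at pre-exported delimited matrices, or
    ``synthetic`` describes a generated suite (keys mirror the synthetic
    generator's parameters plus ``n_datasets`` and ``regimes``).
    """

    out_dir: str = "results"
    datasets_dir: str | None = None
    orientation: str = "samples_by_variables"
    synthetic: dict | None = None
    n_train_values: list[int] = field(default_factory=lambda: [25, 75, 150])
    replicates: int = 100
    cv_routines: list[int] = field(default_factory=lambda: [5, 10])
    n_predictors: int = 500
    alpha: float = 0.05
    subspace_k: int = 1000
    subspace_threshold_p: int = 5000
    qr_rel_tol: float = 1e-9
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.datasets_dir is None and self.synthetic is None:
            raise ValueError("config needs either datasets_dir or a synthetic block")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.n_train_values or not self.cv_routines:
            raise ValueError("n_train_values and cv_routines must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: expected a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
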