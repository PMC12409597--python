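"""Run configuration: one YAML file describing an end-to-end analysis."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .rcca import HyperGrid


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    cohort_dir: str
    output_dir: str
    scheme: str = "kfold"
    K: int = 10
    seed: int = 0
    n_perm: int = 1000
    n_boot: int = 1000
    outcome: str = "difference"          # difference | percent_change | as-is
    fisher_z: bool = True
    grid_reg_values: tuple = ()          # empty -> default grid
    grid_k_values: tuple = ()
    scan_network_sizes: tuple = ()
    scan_metric_sizes: tuple = ()
    scan_seeds: tuple = (0,)

    def grid(self) -> HyperGrid | None:
        if self.grid_reg_values and self.grid_k_values:
            return HyperGrid(tuple(self.grid_reg_values), tuple(self.grid_k_values))
        return None

    def content_hash(self) -> str:
        """Stable hash identifying the configuration (stamped into artifacts)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    def validate_paths(self) -> None:
        cohort = Path(self.cohort_dir)
        if not cohort.is_dir():
            raise FileNotFoundError(f"cohort directory not found: {cohort}")
        for name in ("atlas.tsv", "edges.tsv", "phenotype.tsv"):
            if not (cohort / name).is_file():
                raise FileNotFoundError(f"missing cohort file: {cohort / name}")
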