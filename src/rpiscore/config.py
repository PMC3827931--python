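"""Run configuration: defaults, TOML overrides, and resolved-config dumps.

Every artifact-producing CLI command resolves its configuration from
defaults < config file < command-line flags and writes the resolved values
as JSON next to its outputs, so any run is reproducible from the emitted
config plus its seed.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    # dataset construction
    distance_cutoff: float = 5.0
    min_rna_len: int = 100
    max_rna_len: int = 4095
    protein_identity_cutoff: float = 0.9
    rna_identity_cutoff: float = 0.9
    heavy_atoms_only: bool = False
    # encoding
    n_struct: int = 6
    n_terms: int = 10
    long_rna_policy: str = "error"
    # model
    ridge: float = 1e-6
    fusion_weights: list[float] | None = None
    threshold: float = 50.0
    # evaluation
    cv_folds: int = 4
    # reproducibility
    seed: int = 0
    log_level: str = "INFO"

    def merged(self, overrides: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None}
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Defaults, optionally overridden by a TOML key/value file."""
    config = RunConfig()
    if path is None:
        return config
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config.merged(data)


def dump_resolved(config: RunConfig, out_prefix: str | Path) -> Path:
    """Write the resolved config next to the outputs it produced."""
    path = Path(f"{out_prefix}.config.json")
    path.write_text(json.dumps(config.to_dict(), indent=1))
    return path
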