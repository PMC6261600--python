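"""Run configuration: construct definitions, horizons, bootstrap settings."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

DEFAULT_CONSTRUCTS = {"VA": [], "GC": [], "GP": []}  # empty = all columns in the file


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the data itself.

    ``constructs`` maps each construct label to the CSV column names that
    feed its composite; an empty list means "use every column in the
    construct's file".  ``ordering`` is the Wold causal order.
    """

    constructs: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CONSTRUCTS.items()})
    ordering: tuple = ("VA", "GC", "GP")
    horizons: tuple = (1, 2, 3, 6, 12)
    irf_horizon: int = 12
    n_boot: int = 1000
    seed: int = 0
    log_offset: float = 1.0
    out_dir: str = "results"

    def __post_init__(self):
        if not isinstance(self.constructs, dict) or not self.constructs:
            raise ConfigError("constructs", "must be a nonempty mapping")
        self.ordering = tuple(self.ordering)
        if sorted(self.ordering) != sorted(self.constructs):
            raise ConfigError("ordering", "must be a permutation of the construct labels")
        self.horizons = tuple(int(h) for h in self.horizons)
        if any(h <= 0 for h in self.horizons) or list(self.horizons) != sorted(self.horizons):
            raise ConfigError("horizons", "must be positive and ascending")
        if self.irf_horizon < 0:
            raise ConfigError("irf_horizon", "must be >= 0")
        if self.n_boot < 100:
            raise ConfigError("n_boot", "must be >= 100")
        if self.log_offset <= 0:
            raise ConfigError("log_offset", "must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError("path", f"no such config file: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError("path", f"unparseable YAML: {exc}") from None
        if not isinstance(raw, dict):
            raise ConfigError("path", "config root must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown field")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError("path", str(exc)) from None

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
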