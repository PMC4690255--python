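"""Run configuration: documented defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """All paths and parameters of one screening run.

    Parameters
    ----------
    evalue_max:
        Acceptance threshold; hits with E-value above it are discarded as
        false positives (default 1e-3).
    score_high:
        Best-vs-next score margin (orders of magnitude of E-value
        separation) at or above which an assignment is high confidence.
    pseudocount:
        Dirichlet-style pseudocount weight in profile columns.
    n_null / null_length_multiplier:
        Null sample size and null-sequence length (as a multiple of the
        profile length) for Gumbel E-value calibration.
    pts2_window_rule:
        'containment' (whole match within residues 1-100) or
        'start_only' (match start <= 100).
    enext_default_rule:
        What Enext falls back to when only one family survives the
        filter: 'evalue_max' or a literal float.
    log_base:
        Base of the logs in the best-vs-next score (any base preserves
        the sign law; 10 makes the score read as orders of magnitude).
    """

    # paths
    proteome_dir: str = ""
    family_dir: str = ""
    panel_file: str = ""
    domtbl_dir: str = ""
    nterm_dir: str = ""
    vetting_file: str = ""
    output_dir: str = ""
    # parameters
    evalue_max: float = 1e-3
    score_high: float = 2.0
    pseudocount: float = 1.0
    n_null: int = 300
    null_length_multiplier: int = 2
    rng_seed: int = 0
    pts2_window_rule: str = "containment"
    enext_default_rule: str | float = "evalue_max"
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be positive")
        if self.pts2_window_rule not in ("containment", "start_only"):
            raise ConfigError(
                f"pts2_window_rule must be containment/start_only, "
                f"got {self.pts2_window_rule!r}"
            )
        if self.n_null < 200:
            raise ConfigError("n_null must be >= 200")
        if self.log_base <= 1:
            raise ConfigError("log_base must exceed 1")

    @property
    def enext_default(self) -> float:
        if self.enext_default_rule == "evalue_max":
            return self.evalue_max
        try:
            return float(self.enext_default_rule)
        except (TypeError, ValueError):
            raise ConfigError(
                f"enext_default_rule must be 'evalue_max' or a number, "
                f"got {self.enext_default_rule!r}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()
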