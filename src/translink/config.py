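"""Run-level configuration aggregating every stage threshold.

Defaults are the toolkit's published operating point: homolog searches
at E <= 1e-20, annotation at E <= 1e-15 with a 70% identity floor and
similarity tiers at 1e-20 / 1e-50, clustering at 95% overlap identity,
a 100 bp minimum sequence length, a +/-2 kb genomic reverse-query
window, three homolog pairs to call a synteny block, five hits for the
forward map query and a +/-5 cM candidate window for the reverse query.
Overrides are echoed to the log so a run's provenance is explicit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToolkitConfig:
    e_max: float = 1e-20
    annot_e: float = 1e-15
    tier_very_e: float = 1e-20
    tier_high_e: float = 1e-50
    min_identity_pct: float = 70.0
    cluster_identity: float = 0.95
    min_overlap_len: int = 40
    min_length: int = 100
    polyA_min_run: int = 12
    window_bp: int = 2000
    min_pairs: int = 3
    max_intruders: int = 2
    top_k: int = 5
    window_cm: float = 5.0
    log_level: str = "INFO"
    output_dir: str = "translink_out"

    @classmethod
    def from_yaml(cls, path) -> "ToolkitConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_overrides(**data)

    @classmethod
    def from_overrides(cls, **overrides) -> "ToolkitConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for key, value in overrides.items():
            if getattr(defaults, key) != value:
                logger.info("config override: %s = %r", key, value)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
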