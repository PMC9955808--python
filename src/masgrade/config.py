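"""Pipeline configuration: one JSON document, hashed into every artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path


@dataclasses.dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    Defaults match the module-level defaults throughout the package; a JSON
    config file may override any subset, and CLI flags override the file.
    """

    filter_order: int = 5
    baseline_window_s: float = 0.1
    semg_cutoff_hz: float = 10.0
    min_prominence: float | str = "auto"
    min_separation_s: float = 0.5
    expected_stretches: int = 6
    guard_frac: float = 0.05
    init_frac: float = 0.05
    test_frac: float = 0.1
    grouped_split: bool = False
    rom_threshold_deg: float = 10.0
    upsampler: str = "ros"
    noise_scale: float = 1.0

    @classmethod
    def load(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
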