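"""Run configuration: every threshold carries its documented default.

Precedence when building an effective configuration: explicit flag values
override file values, which override defaults.  Validation happens before
any stage runs; unknown keys, weight vectors that do not sum to 1, and
negative cutoffs are configuration errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

from .docking_geometry import DEFAULT_PADDING, DEFAULT_REDOCK_THRESHOLD
from .druglikeness import GRADE_BOUNDS, WeightVector
from .interactions import DEFAULT_CUTOFFS
from .network_rank import (
    DEFAULT_CENTRALITY_WEIGHTS,
    DEFAULT_SCORE_THRESHOLD,
    DEFAULT_TOP_K,
)


@dataclass(frozen=True)
class RunConfig:
    druglikeness_weights: dict[str, float] = field(
        default_factory=lambda: {
            "lipinski": 0.15, "veber": 0.10, "ghose": 0.10, "qed": 0.20,
            "sa": 0.15, "admet": 0.20, "pains": 0.10,
        }
    )
    grade_bounds: dict[str, float] = field(default_factory=lambda: dict(GRADE_BOUNDS))
    centrality_weights: tuple[float, ...] = DEFAULT_CENTRALITY_WEIGHTS
    string_score_threshold: float = DEFAULT_SCORE_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    box_padding: float = DEFAULT_PADDING
    redock_threshold: float = DEFAULT_REDOCK_THRESHOLD
    interaction_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )
    seed: int = 0
    verbosity: str = "info"

    def weight_vector(self) -> WeightVector:
        return WeightVector(**self.druglikeness_weights)

    def validate(self) -> None:
        self.weight_vector().validate()
        if any(w < 0 for w in self.centrality_weights):
            raise ValueError("centrality weights must be non-negative")
        if abs(sum(self.centrality_weights) - 1.0) > 1e-9:
            raise ValueError("centrality weights must sum to 1")
        for kind, cut in self.interaction_cutoffs.items():
            if cut < 0:
                raise ValueError(f"negative cutoff for {kind}: {cut}")
        if self.box_padding < 0 or self.redock_threshold < 0:
            raise ValueError("padding and redock threshold must be non-negative")
        bounds = [self.grade_bounds[g] for g in ("A", "B", "C", "D")]
        if sorted(bounds, reverse=True) != bounds:
            raise ValueError(f"grade bounds must decrease A→D, got {bounds}")


def load_config(
    path: Optional[str | Path] = None, overrides: Optional[dict[str, Any]] = None
) -> RunConfig:
    """Merge defaults, an optional JSON config file, and explicit overrides."""
    cfg = RunConfig()
    known = set(asdict(cfg))
    for source in (_read_file(path) if path else {}, overrides or {}):
        unknown = set(source) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        clean = {
            k: tuple(v) if k == "centrality_weights" else v for k, v in source.items()
        }
        cfg = replace(cfg, **clean)
    cfg.validate()
    return cfg


def _read_file(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text()
    data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a JSON object")
    return data


def config_to_json(cfg: RunConfig) -> str:
    return json.dumps(asdict(cfg), indent=2, sort_keys=True)
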