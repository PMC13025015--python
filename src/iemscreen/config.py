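"""Run configuration: every pipeline constant in one serializable place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline stage parameters with the method's default constants.

    Keeping the constants here means sensitivity analyses need no code
    edits; the defaults are the published procedure.
    """

    panel_path: str = "default"
    signatures_path: str = "default"
    marker_groups_path: str = "default"
    out_dir: str = "."

    n_reference: int = 296          # reference (non-IEM) cohort size
    n_screen_controls: int = 341    # control profiles in classification runs
    cases_per_disease: int = 10

    k_outlier: float = 2.81         # outlier exclusion, transformed-scale SD
    z_limit_mult: float = 1.96      # central-95% limit multiplier
    below_lod_report_threshold: float = 0.025
    n_valid_threshold: int = 100
    lod_area_impute: float = 2000.0
    l2_penalty: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "k_outlier",
            "z_limit_mult",
            "below_lod_report_threshold",
            "n_valid_threshold",
            "lod_area_impute",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(asdict(self)))
        else:
            path.write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)
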