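"""Analysis configuration with validated load from YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["AnalysisConfig", "load_config"]


class AnalysisConfig(BaseModel):
    """Everything tunable about an analysis, in one validated object.

    Defaults reproduce the package's reference behaviour: hybrid RALS/LALS
    light scattering, peak detection at 2% of the RI maximum with 0.3 mL
    minimum separation, automatic edge blank windows, and the IgG/HRP
    reference masses for conjugate QC.
    """

    model_config = ConfigDict(extra="forbid")

    # dn/dc handling: a fixed value, or None to estimate from injected mass
    dndc: Optional[float] = Field(default=None, gt=0)
    ls_mode: Literal["hybrid", "rals", "lals"] = "hybrid"

    # peak detection / integration
    min_height_frac: float = Field(default=0.02, gt=0, lt=1)
    min_separation: float = Field(default=0.3, gt=0)  # mL
    edge_floor_frac: float = Field(default=0.005, gt=0, lt=1)
    slice_floor_frac: float = Field(default=0.01, gt=0, lt=1)
    noise_floor_factor: float = Field(default=3.0, ge=0)

    # baseline / alignment
    blank_windows: Optional[list[tuple[float, float]]] = None  # mL; None = auto
    detector_offsets: dict[str, float] = Field(default_factory=dict)  # mL

    # conjugate QC references
    antibody_mw: float = Field(default=152.5, gt=0)  # kDa
    enzyme_mw: float = Field(default=43.1, gt=0)  # kDa
    tolerance_frac: float = Field(default=0.10, gt=0, lt=0.5)
    aggregate_pd_threshold: float = Field(default=1.15, gt=1)
    aggregate_alert_threshold: float = Field(default=5.0, gt=0)  # share points

    @field_validator("blank_windows")
    @classmethod
    def _windows_ordered(cls, v):
        if v is not None:
            for lo, hi in v:
                if not lo < hi:
                    raise ValueError(f"blank window ({lo}, {hi}) has start >= end")
        return v


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return AnalysisConfig.model_validate(data)
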