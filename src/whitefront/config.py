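"""Run configuration: validated JSON in, reproducible metadata out.

A run config bundles everything a tracking / R-curve run needs besides
the raw inputs: specimen geometry, pixel calibration (direct mm/px or
support points plus span), notch tip, ROI and tracking parameters.  The
``scenario.json`` written by the synthetic generator is a valid config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fracture import SpecimenGeometry
from .io_sync import Calibration, calibrate
from .tracking import TrackConfig


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="ignore")
    B: float
    W: float
    a0: float
    S: float
    nu: float = 0.33

    def to_geometry(self) -> SpecimenGeometry:
        return SpecimenGeometry(B=self.B, W=self.W, a0=self.a0, S=self.S, nu=self.nu)


class RunConfig(BaseModel):
    """Validated configuration for the CLI commands."""

    model_config = ConfigDict(extra="ignore")

    geometry: GeometryConfig
    stride: int = Field(default=15, ge=1)
    fps: float = Field(default=60.0, gt=0)
    # preprocessing (off by default: differencing needs radiometric consistency)
    gamma: Optional[float] = None
    window_percentiles: Optional[tuple[float, float]] = None
    # calibration: either direct pixel size or support points + span
    mm_per_pixel: Optional[float] = None
    supports_px: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    span_mm: Optional[float] = None
    notch_tip_px: tuple[int, int]
    roi: Optional[tuple[int, int, int, int]] = None
    reg_window: Optional[tuple[int, int, int, int]] = None
    # tracking
    upsample_factor: int = Field(default=100, ge=1)
    threshold: Union[float, Literal["otsu"]] = "otsu"
    element_diameter_px: int = Field(default=2, ge=1)
    join_operator: Literal["closing", "opening"] = "closing"
    min_area_px: int = Field(default=5, ge=0)
    smooth_sigma: Union[float, tuple[float, float]] = (0.7, 1.4)
    displacement_mode: Literal["vertical", "euclidean"] = "vertical"
    # fracture
    eta: float = 1.9
    E_MPa: Optional[float] = None
    correction_model: Optional[str] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check_calibration(self) -> "RunConfig":
        if self.mm_per_pixel is None and (self.supports_px is None or self.span_mm is None):
            raise ValueError(
                "config needs either mm_per_pixel or supports_px plus span_mm"
            )
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def calibration(self) -> Calibration:
        if self.mm_per_pixel is not None:
            return Calibration(mm_per_pixel=self.mm_per_pixel)
        return calibrate(self.supports_px[0], self.supports_px[1], self.span_mm)

    def track_config(self) -> TrackConfig:
        return TrackConfig(
            upsample_factor=self.upsample_factor,
            threshold=self.threshold,
            element_diameter_px=self.element_diameter_px,
            join_operator=self.join_operator,
            min_area_px=self.min_area_px,
            smooth_sigma=self.smooth_sigma,
            displacement_mode=self.displacement_mode,
            roi=tuple(self.roi) if self.roi else None,
            reg_window=tuple(self.reg_window) if self.reg_window else None,
        )

    def metadata(self) -> dict:
        return json.loads(self.model_dump_json())
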