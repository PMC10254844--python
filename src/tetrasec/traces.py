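"""Detector traces and multi-detector runs.

All positions are retention volumes in mL; signals are detector outputs in
mV. A :class:`MultiDetectorRun` bundles up to five detector traces that share
one uniform volume grid, plus the injection metadata needed to turn detector
areas into physical quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

#: Canonical detector order used throughout the package.
DETECTORS = ("RI", "UV", "RALS", "LALS", "VISC")

#: Detectors that measure static light scattering.
LS_DETECTORS = ("RALS", "LALS")

_GRID_TOL = 1e-9  # mL; uniformity tolerance for the volume grid


@dataclass(frozen=True)
class DetectorTrace:
    """A single detector channel: signal (mV) versus retention volume (mL)."""

    detector: str
    volumes: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(
                f"unknown detector {self.detector!r}; expected one of {DETECTORS}"
            )
        volumes = np.asarray(self.volumes, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if volumes.ndim != 1 or signal.ndim != 1:
            raise ValueError("volumes and signal must be 1-D")
        if volumes.size != signal.size:
            raise ValueError(
                f"volumes ({volumes.size}) and signal ({signal.size}) differ in length"
            )
        if volumes.size < 2:
            raise ValueError("a trace needs at least two points")
        steps = np.diff(volumes)
        if np.any(steps <= 0):
            raise ValueError("volumes must be strictly increasing")
        if np.ptp(steps) > _GRID_TOL:
            raise ValueError("volume grid must be uniform (within 1e-9 mL)")
        object.__setattr__(self, "volumes", volumes)
        object.__setattr__(self, "signal", signal)

    @property
    def step(self) -> float:
        """Grid spacing in mL."""
        return float(self.volumes[1] - self.volumes[0])

    @property
    def span(self) -> float:
        return float(self.volumes[-1] - self.volumes[0])

    def area(self, window: Optional[tuple[float, float]] = None) -> float:
        """Trapezoidal area (mV·mL), optionally restricted to a volume window."""
        if window is None:
            return float(np.trapezoid(self.signal, self.volumes))
        lo, hi = window
        mask = (self.volumes >= lo) & (self.volumes <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window {window} contains fewer than two grid points")
        return float(np.trapezoid(self.signal[mask], self.volumes[mask]))

    def with_signal(self, signal: np.ndarray) -> "DetectorTrace":
        return DetectorTrace(self.detector, self.volumes, signal)


@dataclass
class MultiDetectorRun:
    """Aligned detector traces for one injection.

    Parameters
    ----------
    traces
        Mapping detector name -> :class:`DetectorTrace`. All traces must share
        one volume grid.
    injection_volume
        Injected volume in µL.
    injected_mass
        Total injected protein mass in µg, if known. Required for estimating
        a sample dn/dc and for mass recovery.
    sample_id
        Free-text identifier carried through reports.
    """

    traces: dict[str, DetectorTrace]
    injection_volume: float
    injected_mass: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("a run needs at least one trace")
        if self.injection_volume <= 0:
            raise ValueError("injection_volume must be positive (µL)")
        if self.injected_mass is not None and self.injected_mass <= 0:
            raise ValueError("injected_mass must be positive (µg) when given")
        grids = [t.volumes for t in self.traces.values()]
        ref = grids[0]
        for t in self.traces.values():
            if t.volumes.size != ref.size or np.max(np.abs(t.volumes - ref)) > _GRID_TOL:
                raise ValueError("all traces in a run must share one volume grid")

    @property
    def volumes(self) -> np.ndarray:
        return next(iter(self.traces.values())).volumes

    @property
    def step(self) -> float:
        return next(iter(self.traces.values())).step

    def __contains__(self, detector: str) -> bool:
        return detector in self.traces

    def __getitem__(self, detector: str) -> DetectorTrace:
        return self.traces[detector]

    def replace_traces(self, traces: Mapping[str, DetectorTrace]) -> "MultiDetectorRun":
        return MultiDetectorRun(
            traces=dict(traces),
            injection_volume=self.injection_volume,
            injected_mass=self.injected_mass,
            sample_id=self.sample_id,
        )
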