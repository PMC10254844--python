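"""Raw-trace preparation: detector alignment, baseline correction, peak
boundaries, and the slice table handed to the quantitation stage.

Peaks are detected on the RI trace — the concentration detector — because
light scattering over-weights high-Mw aggregates. Boundaries between
adjacent peaks go to the deepest valley; when the signal between two peaks
drops below an edge floor (default 0.5% of the global maximum) each peak is
bounded at its own floor crossing, and the outer flanks end where the signal
falls below the same floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .traces import DetectorTrace, MultiDetectorRun

__all__ = [
    "PeakRegion",
    "SliceTable",
    "align_detectors",
    "correct_baseline",
    "default_blank_windows",
    "detect_peaks",
    "build_slice_table",
]


@dataclass(frozen=True)
class PeakRegion:
    """One integrated peak: [start, end] mL with the apex (V_R) inside."""

    start: float
    end: float
    apex: float

    def __post_init__(self) -> None:
        if not self.start < self.apex < self.end:
            raise ValueError(
                f"require start < apex < end, got ({self.start}, {self.apex}, {self.end})"
            )

    def contains(self, volumes: np.ndarray) -> np.ndarray:
        return (volumes >= self.start) & (volumes <= self.end)


@dataclass
class SliceTable:
    """Baseline-corrected signals on a common grid, ready for slicing.

    ``noise_sd`` holds the per-detector residual standard deviation measured
    in the blank windows after correction; the quantitation stage uses it to
    set signal floors.
    """

    volumes: np.ndarray
    signals: dict[str, np.ndarray]
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sig in self.signals.items():
            if np.asarray(sig).shape != self.volumes.shape:
                raise ValueError(f"signal {name!r} not on the common grid")

    @property
    def step(self) -> float:
        return float(self.volumes[1] - self.volumes[0])


def default_blank_windows(volumes: np.ndarray,
                          edge_frac: float = 0.07) -> list[tuple[float, float]]:
    """Blank windows covering the outer ``edge_frac`` of the grid on each side."""
    lo, hi = float(volumes[0]), float(volumes[-1])
    span = hi - lo
    return [(lo, lo + edge_frac * span), (hi - edge_frac * span, hi)]


def align_detectors(run: MultiDetectorRun,
                    offsets: Mapping[str, float]) -> MultiDetectorRun:
    """Shift each trace by its volume offset onto the common grid.

    An offset of -0.05 mL moves features recorded 0.05 mL late back into
    register. Shifted traces are linearly interpolated; only the grid region
    covered by every shifted trace is retained.
    """
    if not offsets or all(v == 0 for v in offsets.values()):
        return run
    grid = run.volumes
    span = float(grid[-1] - grid[0])
    for det, off in offsets.items():
        if abs(off) >= span:
            raise ValueError(
                f"offset {off} mL for {det} exceeds the grid span ({span} mL)"
            )
    # trace value at v after alignment is the recorded value at v - offset
    lo = grid[0] + max(0.0, max((-o for o in offsets.values()), default=0.0))
    hi = grid[-1] + min(0.0, min((-o for o in offsets.values()), default=0.0))
    keep = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
    if keep.sum() < 2:
        raise ValueError("offsets leave no common grid region")
    new_grid = grid[keep]
    traces = {}
    for det, trace in run.traces.items():
        off = offsets.get(det, 0.0)
        shifted = np.interp(new_grid - off, trace.volumes, trace.signal)
        traces[det] = DetectorTrace(det, new_grid, shifted)
    return run.replace_traces(traces)


def correct_baseline(trace: DetectorTrace,
                     blank_windows: Sequence[tuple[float, float]]) -> DetectorTrace:
    """Subtract the straight line fitted to the signal inside blank windows.

    Blank windows should bracket the elution region (at least one before and
    one after). A pronounced slope inside a single window — signal leaking
    into the blank — triggers a warning, not an error.
    """
    if len(blank_windows) < 2:
        raise ValueError("need at least two blank windows (before and after elution)")
    vols, sig = trace.volumes, trace.signal
    mask = np.zeros(vols.size, dtype=bool)
    for lo, hi in blank_windows:
        mask |= (vols >= lo) & (vols <= hi)
    if mask.sum() < 2:
        raise ValueError("blank windows contain fewer than two grid points")

    coeffs = np.polyfit(vols[mask], sig[mask], 1)
    baseline = np.polyval(coeffs, vols)

    # per-window slope check: a window sitting on a peak flank has a local
    # slope far beyond what the quietest window's residual noise supports
    stats = []
    for lo, hi in blank_windows:
        wmask = (vols >= lo) & (vols <= hi)
        if wmask.sum() < 3:
            continue
        wfit = np.polyfit(vols[wmask], sig[wmask], 1)
        wresid = float(np.std(sig[wmask] - np.polyval(wfit, vols[wmask])))
        stats.append(((lo, hi), float(wfit[0]), wresid))
    if stats:
        noise_sd = min(s[2] for s in stats)
        # floor relative to the trace amplitude: sub-1e-4 structure is
        # irrelevant to any downstream quantity
        floor = max(6 * noise_sd, 1e-4 * float(np.max(np.abs(sig))), 1e-9)
        for (lo, hi), wslope, _ in stats:
            excess = abs(wslope - coeffs[0]) * (hi - lo)
            if excess > floor:
                warnings.warn(
                    f"blank window ({lo}, {hi}) on {trace.detector} shows "
                    "structure (slope inconsistent with a flat baseline); "
                    "it may overlap a peak",
                    stacklevel=2,
                )
    return trace.with_signal(sig - baseline)


def _flank_crossing(signal: np.ndarray, apex_idx: int, floor: float,
                    direction: int, stop: int) -> int:
    """March from the apex until the signal drops below ``floor``; return the
    last index still at/above the floor (clipped at ``stop``)."""
    i = apex_idx
    while i != stop and signal[i + direction] >= floor:
        i += direction
    return i


def detect_peaks(
    ri_trace: DetectorTrace,
    min_height_frac: float = 0.02,
    min_separation: float = 0.3,
    edge_floor_frac: float = 0.005,
) -> list[PeakRegion]:
    """Locate peaks on a baseline-corrected RI trace.

    Apexes are local maxima above ``min_height_frac`` of the global maximum;
    apexes closer than ``min_separation`` mL keep only the taller. Returns
    regions sorted by apex; an all-noise trace yields an empty list.
    """
    vols, sig = ri_trace.volumes, ri_trace.signal
    global_max = float(np.max(sig)) if sig.size else 0.0
    if global_max <= 0:
        return []
    distance = max(1, int(round(min_separation / ri_trace.step)))
    apexes, _ = find_peaks(sig, height=min_height_frac * global_max,
                           distance=distance)
    if apexes.size == 0:
        return []
    floor = edge_floor_frac * global_max

    n = sig.size
    bounds: list[list[int]] = [[0, n - 1] for _ in apexes]
    # outer flanks
    bounds[0][0] = _flank_crossing(sig, int(apexes[0]), floor, -1, 0)
    bounds[-1][1] = _flank_crossing(sig, int(apexes[-1]), floor, +1, n - 1)
    # boundaries between adjacent apexes
    for k in range(len(apexes) - 1):
        a, b = int(apexes[k]), int(apexes[k + 1])
        inner = sig[a + 1:b]
        vmin_idx = a + 1 + int(np.argmin(inner))
        if sig[vmin_idx] >= floor:
            bounds[k][1] = vmin_idx
            bounds[k + 1][0] = vmin_idx
        else:  # sub-floor gap: bound each peak at its own floor crossing
            bounds[k][1] = _flank_crossing(sig, a, floor, +1, b)
            bounds[k + 1][0] = _flank_crossing(sig, b, floor, -1, a)

    regions = []
    for (lo, hi), apex in zip(bounds, apexes):
        lo = min(lo, apex - 1)
        hi = max(hi, apex + 1)
        lo = max(lo, 0)
        hi = min(hi, n - 1)
        regions.append(PeakRegion(start=float(vols[lo]), end=float(vols[hi]),
                                  apex=float(vols[apex])))
    return regions


def build_slice_table(
    run: MultiDetectorRun,
    blank_windows: Optional[Sequence[tuple[float, float]]] = None,
    detector_offsets: Optional[Mapping[str, float]] = None,
) -> SliceTable:
    """Align, baseline-correct and stack all traces of a run."""
    if detector_offsets:
        run = align_detectors(run, detector_offsets)
    vols = run.volumes
    if blank_windows is None:
        blank_windows = default_blank_windows(vols)
    signals: dict[str, np.ndarray] = {}
    noise: dict[str, float] = {}
    mask = np.zeros(vols.size, dtype=bool)
    for lo, hi in blank_windows:
        mask |= (vols >= lo) & (vols <= hi)
    for det, trace in run.traces.items():
        corrected = correct_baseline(trace, blank_windows)
        signals[det] = corrected.signal
        noise[det] = float(np.std(corrected.signal[mask]))
    return SliceTable(volumes=vols, signals=signals, noise_sd=noise)
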