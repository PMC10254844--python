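"""Synthetic multi-detector SEC chromatograms with known ground truth.

Each species elutes as a Gaussian in retention volume. For a species with
injected mass m (µg) the noiseless area (mV·mL) of its peak on each detector
follows the detector response model:

    RI    : K_RI   · (dn/dc) · m
    UV    : K_UV   · (dA/dc) · m
    RALS  : K_LS   · Mw · (dn/dc)² · m
    LALS  : K_LS   · Mw · (dn/dc)² · m
    VISC  : K_Visc · IV · m

RALS and LALS are generated with identical ideal responses: every analyte
here is far smaller than the laser wavelength (Rh ≤ 12.5 nm), so angular
dissymmetry is negligible. Additive Gaussian noise and a linear baseline
drift are applied after superposition of all species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .calibration import CalibrationConstants
from .traces import DETECTORS, DetectorTrace, MultiDetectorRun

__all__ = ["SpeciesSpec", "InstrumentModel", "simulate_run", "DEFAULT_CONSTANTS"]

#: Default detector constants used by the bundled instrument model
#: (arbitrary but fixed mV·mL scale factors).
DEFAULT_CONSTANTS = CalibrationConstants(k_ri=5.0, k_uv=3.0, k_ls=2.0, k_visc=4.0)


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth description of one eluting species.

    Units: mw kDa, dndc mL/g, dadc mL/(mg·cm), iv dL/g, vr and sigma mL.
    ``mass_fraction`` is this species' share of the total injected mass.
    """

    name: str
    mw: float
    dndc: float
    iv: float
    mass_fraction: float
    vr: float
    sigma: float
    dadc: float = 0.0

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.name}: mw must be positive")
        if self.dndc <= 0:
            raise ValueError(f"{self.name}: dndc must be positive")
        if self.dadc < 0:
            raise ValueError(f"{self.name}: dadc must be nonnegative")
        if self.iv <= 0:
            raise ValueError(f"{self.name}: iv must be positive")
        if not 0 <= self.mass_fraction <= 1:
            raise ValueError(f"{self.name}: mass_fraction must be in [0, 1]")
        if self.vr <= 0 or self.sigma <= 0:
            raise ValueError(f"{self.name}: vr and sigma must be positive")


NoiseLike = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class InstrumentModel:
    """Idealized tetra-detector platform: grid, constants, noise, drift.

    ``noise_sd`` and ``baseline_drift`` accept either a scalar applied to all
    detectors or a per-detector mapping. ``detector_offsets`` shifts each
    trace along the volume axis, emulating serial plumbing delay between
    detectors.
    """

    constants: CalibrationConstants = DEFAULT_CONSTANTS
    noise_sd: NoiseLike = 0.05  # mV
    baseline_drift: NoiseLike = 0.0  # mV/mL
    detector_offsets: Mapping[str, float] = field(default_factory=dict)
    grid_start: float = 5.0  # mL
    grid_end: float = 14.0  # mL
    grid_step: float = 0.01  # mL

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_end <= self.grid_start:
            raise ValueError("grid_end must exceed grid_start")

    def volume_grid(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def per_detector(self, value: NoiseLike, detector: str) -> float:
        if isinstance(value, Mapping):
            return float(value.get(detector, 0.0))
        return float(value)

    def noiseless(self) -> "InstrumentModel":
        return replace(self, noise_sd=0.0, baseline_drift=0.0)


def _check_species(species: Sequence[SpeciesSpec], instrument: InstrumentModel) -> None:
    if not species:
        raise ValueError("species list must be nonempty")
    total = sum(sp.mass_fraction for sp in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"species mass fractions must sum to 1 (got {total!r}); "
            "normalize the composition first"
        )
    for sp in species:
        lo, hi = sp.vr - 5 * sp.sigma, sp.vr + 5 * sp.sigma
        if lo < instrument.grid_start or hi > instrument.grid_end:
            raise ValueError(
                f"volume grid [{instrument.grid_start}, {instrument.grid_end}] mL "
                f"does not cover species {sp.name!r} (needs {lo:.2f}–{hi:.2f} mL)"
            )
    # SEC elutes large species first; a violation usually means a typo.
    ordered = sorted(species, key=lambda sp: sp.vr)
    mws = [sp.mw for sp in ordered]
    if any(b > a for a, b in zip(mws, mws[1:])):
        warnings.warn(
            "species with larger Mw assigned larger retention volume; "
            "SEC normally elutes large species first",
            stacklevel=3,
        )


def _species_area(sp: SpeciesSpec, detector: str, constants: CalibrationConstants,
                  mass: float) -> float:
    """Noiseless peak area (mV·mL) of one species on one detector."""
    if detector == "RI":
        return constants.k_ri * sp.dndc * mass
    if detector == "UV":
        return (constants.k_uv or 0.0) * sp.dadc * mass
    if detector in ("RALS", "LALS"):
        return constants.k_ls * sp.mw * sp.dndc**2 * mass
    if detector == "VISC":
        return (constants.k_visc or 0.0) * sp.iv * mass
    raise ValueError(f"unknown detector {detector!r}")


def simulate_run(
    species: Sequence[SpeciesSpec],
    instrument: InstrumentModel,
    injected_mass: float,
    injection_volume: float,
    seed: int,
    sample_id: str = "",
    detectors: Sequence[str] = DETECTORS,
) -> MultiDetectorRun:
    """Simulate one injection of a species mixture.

    Parameters
    ----------
    injected_mass
        Total protein mass loaded, µg; split over species by mass_fraction.
    injection_volume
        Injection volume, µL (metadata; the response model works in mass).
    seed
        Seeds a dedicated generator: identical seeds give bit-identical runs.
    """
    if injected_mass <= 0:
        raise ValueError("injected_mass must be positive (µg)")
    _check_species(species, instrument)

    volumes = instrument.volume_grid()
    rng = np.random.default_rng(seed)
    traces: dict[str, DetectorTrace] = {}
    for detector in detectors:  # fixed order keeps the RNG stream reproducible
        offset = instrument.per_detector(instrument.detector_offsets, detector) \
            if instrument.detector_offsets else 0.0
        signal = np.zeros_like(volumes)
        for sp in species:
            area = _species_area(sp, detector, instrument.constants,
                                 sp.mass_fraction * injected_mass)
            if area:
                signal += area * stats.norm.pdf(volumes, loc=sp.vr + offset,
                                                scale=sp.sigma)
        drift = instrument.per_detector(instrument.baseline_drift, detector)
        if drift:
            signal = signal + drift * (volumes - volumes[0])
        sd = instrument.per_detector(instrument.noise_sd, detector)
        if sd > 0:
            signal = signal + rng.normal(0.0, sd, size=volumes.size)
        traces[detector] = DetectorTrace(detector, volumes, signal)

    return MultiDetectorRun(
        traces=traces,
        injection_volume=injection_volume,
        injected_mass=injected_mass,
        sample_id=sample_id,
    )
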