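"""Detector calibration against a protein standard.

Multi-detection SEC needs no column calibration, but the four detector
responses must be put on a physical scale. Running a standard of known
concentration, Mw, dn/dc, dA/dc and intrinsic viscosity determines the
response constants:

    RI area    = K_RI   · (dn/dc) · m
    UV area    = K_UV   · (dA/dc) · m
    LS area    = K_LS   · Mw · (dn/dc)² · m
    Visc area  = K_Visc · IV · m

with m the injected mass (concentration × injection volume) and areas the
baseline-corrected detector peak areas in mV·mL. Units at this boundary:
mL/g for dn/dc, mL/(mg·cm) for dA/dc, kDa for Mw, dL/g for IV, µg for m.

Bovine serum albumin is the conventional standard; the default parameter set
(66.4 kDa, dn/dc 0.185 mL/g) uses literature values and is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .traces import LS_DETECTORS, MultiDetectorRun

__all__ = [
    "CalibrationConstants",
    "CalibrationStandard",
    "calibrate_from_standard",
    "estimate_dndc",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Detector response constants (mV·mL per unit physical product).

    ``k_uv`` and ``k_visc`` may be ``None`` when the corresponding detector
    was absent from the calibration run.
    """

    k_ri: float
    k_ls: float
    k_uv: Optional[float] = None
    k_visc: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("k_ri", "k_ls", "k_uv", "k_visc"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class CalibrationStandard:
    """Known properties of the calibration standard.

    ``monomer_window`` restricts integration to the monomer peak: real BSA
    preparations contain dimer, which would otherwise inflate K_LS (the LS
    response is Mw-weighted).
    """

    mw: float = 66.4  # kDa, BSA monomer
    dndc: float = 0.185  # mL/g
    dadc: float = 0.667  # mL/(mg·cm) at 280 nm
    iv: float = 0.041  # dL/g
    concentration: float = 2.0  # mg/mL as injected
    monomer_window: tuple[float, float] = (9.3, 10.9)  # mL

    def __post_init__(self) -> None:
        for name in ("mw", "dndc", "dadc", "iv", "concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"standard {name} must be positive")
        lo, hi = self.monomer_window
        if not lo < hi:
            raise ValueError("monomer_window start must precede end")


def _corrected_area(
    run: MultiDetectorRun,
    detector: str,
    window: tuple[float, float],
    blank_windows: Optional[Sequence[tuple[float, float]]],
) -> float:
    # Local import: processing imports nothing from here, but keeps module
    # load order flexible for the public API.
    from .processing import correct_baseline, default_blank_windows

    trace = run[detector]
    if blank_windows is None:
        blank_windows = default_blank_windows(trace.volumes)
    corrected = correct_baseline(trace, blank_windows)
    return corrected.area(window)


def calibrate_from_standard(
    run: MultiDetectorRun,
    standard: CalibrationStandard,
    blank_windows: Optional[Sequence[tuple[float, float]]] = None,
) -> CalibrationConstants:
    """Invert the detector response equations on a standard run.

    The injected mass is ``standard.concentration × run.injection_volume``
    (mg/mL × µL = µg). Areas are baseline-corrected trapezoidal integrals
    over the standard's monomer window. A missing UV or viscometer trace
    yields ``None`` for the corresponding constant; a missing RI or LS trace
    is an error because Mw determination is then impossible.

    If the standard is not fully monomeric, restricting to the monomer window
    scales every constant down by the in-window mass fraction. That common
    factor cancels in the K_RI/K_LS and K_RI/K_Visc ratios that set the Mw
    and IV scales, which is why a monomer window is preferred over
    integrating the dimer along with the monomer (the dimer's doubled mass
    would bias K_LS specifically). Only dn/dc estimation, which uses K_RI
    alone, benefits from a standard of accurately known total concentration.
    """
    if "RI" not in run:
        raise ValueError("calibration requires an RI trace")
    ls_present = [d for d in LS_DETECTORS if d in run]
    if not ls_present:
        raise ValueError("calibration requires at least one light-scattering trace")

    mass = standard.concentration * run.injection_volume  # µg
    if mass <= 0:
        raise ValueError("injected mass of the standard must be positive")

    window = standard.monomer_window
    lo, hi = window
    vols = run.volumes
    if lo < vols[0] or hi > vols[-1]:
        raise ValueError(
            f"monomer window {window} lies outside the run grid "
            f"({vols[0]:.2f}–{vols[-1]:.2f} mL)"
        )

    def area_of(detector: str) -> float:
        a = _corrected_area(run, detector, window, blank_windows)
        if a <= 0:
            raise ValueError(
                f"nonpositive corrected {detector} area over {window}; "
                "check the monomer window"
            )
        return a

    a_ri = area_of("RI")
    a_ls = float(np.mean([area_of(d) for d in ls_present]))

    k_ri = a_ri / (standard.dndc * mass)
    k_ls = a_ls / (standard.mw * standard.dndc**2 * mass)
    k_uv = area_of("UV") / (standard.dadc * mass) if "UV" in run else None
    k_visc = area_of("VISC") / (standard.iv * mass) if "VISC" in run else None
    return CalibrationConstants(k_ri=k_ri, k_ls=k_ls, k_uv=k_uv, k_visc=k_visc)


def estimate_dndc(
    run: MultiDetectorRun,
    constants: CalibrationConstants,
    blank_windows: Optional[Sequence[tuple[float, float]]] = None,
) -> float:
    """Whole-sample dn/dc (mL/g) from the total RI response and injected mass.

    Assumes full mass recovery on the column: the entire injected mass elutes
    within the acquisition window. This mirrors routine practice where sample
    concentrations are used to back-calculate dn/dc.
    """
    if run.injected_mass is None:
        raise ValueError(
            "run has no injected_mass; supply the sample dn/dc explicitly instead"
        )
    if "RI" not in run:
        raise ValueError("dn/dc estimation requires an RI trace")
    vols = run.volumes
    total = _corrected_area(run, "RI", (float(vols[0]), float(vols[-1])), blank_windows)
    if total <= 0:
        raise ValueError("nonpositive total RI area; cannot estimate dn/dc")
    return total / (constants.k_ri * run.injected_mass)
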