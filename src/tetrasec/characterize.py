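"""Slice-wise molecular characterization and per-peak summary quantities.

This is the heart of the package. With calibrated detector constants and the
sample dn/dc, each chromatogram slice yields:

    mass_i  = RI_i · Δv / (K_RI · dn/dc)                       [µg]
    Mw_i    = (LS_i / RI_i) · K_RI / (K_LS · dn/dc)            [kDa]
    IV_i    = (Visc_i / RI_i) · K_RI · dn/dc / K_Visc          [dL/g]

ratio algebra of the four detector response equations. LS_i is the mean of
the RALS and LALS channels by default (both record the same ideal response
for analytes far below the Zimm regime); either channel alone is selectable.
Because the Mw and IV estimates are signal ratios, they blow up on peak
flanks, so slices with RI below a signal floor are left undefined.

Per peak, the slice distribution is condensed into the standard molar-mass
moments

    Mn = Σc / Σ(c/M),  Mw = ΣcM / Σc,  Mz = ΣcM² / ΣcM,  Pd = Mw/Mn,

a concentration-weighted intrinsic viscosity, the RI-mass share, and the
hydrodynamic radius of the equivalent sphere consistent with (Mw, IV):

    Rh = (3 [η] M / (10 π N_A))^(1/3)

with [η] in cm³/g and M in g/mol (the Einstein viscosity relation solved
for the sphere radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationConstants
from .processing import PeakRegion, SliceTable

__all__ = [
    "SliceResult",
    "PeakResult",
    "slice_analysis",
    "peak_moments",
    "hydrodynamic_radius",
    "peak_shares",
    "estimate_composition",
    "mass_recovery",
    "characterize_peaks",
]

N_AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class SliceResult:
    """One chromatogram slice: mass, and Mw/IV where the signal supports them."""

    volume: float  # mL
    mass: float  # µg eluting in this slice
    conc: float  # mg/mL-equivalent (mass / injection volume)
    mw: float  # kDa; NaN below the signal floor
    iv: float  # dL/g; NaN below the floor or without a viscometer


@dataclass
class PeakResult:
    """Per-peak characterization mirroring a sample report table row."""

    region: PeakRegion
    mw: float  # kDa, weight-average
    mn: float  # kDa
    mz: float  # kDa
    pd: float  # Mw/Mn
    iv: Optional[float]  # dL/g, concentration-weighted; None without viscometry
    rh: Optional[float]  # nm; None when IV unavailable
    share: float  # % of RI mass over all integrated peaks
    mass: float  # µg
    mw_se: Optional[float] = None  # within-run slice-scatter SE, diagnostic only
    label: Optional[str] = None  # filled by the QC classifier

    @property
    def vr(self) -> float:
        """Retention volume at the peak apex (mL)."""
        return self.region.apex


def _ls_signal(slices: SliceTable, ls_mode: str) -> np.ndarray:
    present = [d for d in ("RALS", "LALS") if d in slices.signals]
    if ls_mode == "hybrid":
        if not present:
            raise ValueError("no light-scattering trace (RALS/LALS) in run")
        return np.mean([slices.signals[d] for d in present], axis=0)
    if ls_mode in ("rals", "lals"):
        det = ls_mode.upper()
        if det not in slices.signals:
            raise ValueError(f"ls_mode={ls_mode!r} but {det} trace is missing")
        return slices.signals[det]
    raise ValueError(f"ls_mode must be 'hybrid', 'rals' or 'lals', got {ls_mode!r}")


def slice_analysis(
    slices: SliceTable,
    constants: CalibrationConstants,
    dndc: float,
    injection_volume: float,
    ls_mode: str = "hybrid",
    floor_frac: float = 0.01,
    noise_floor_factor: float = 3.0,
) -> list[SliceResult]:
    """Per-slice concentration, Mw and IV from calibrated detector ratios.

    The signal floor is ``max(noise_floor_factor × blank noise, floor_frac ×
    RI maximum)``: slices with RI below it keep their mass but get NaN for
    the ratio quantities.
    """
    if dndc <= 0:
        raise ValueError("dndc must be positive")
    if "RI" not in slices.signals:
        raise ValueError("slice analysis requires an RI trace")
    ri = slices.signals["RI"]
    ls = _ls_signal(slices, ls_mode)
    dv = slices.step

    mass = ri * dv / (constants.k_ri * dndc)  # µg per slice
    conc = mass / injection_volume  # mg/mL-equivalent

    floor = max(noise_floor_factor * slices.noise_sd.get("RI", 0.0),
                floor_frac * float(np.max(ri)))
    defined = ri > floor

    with np.errstate(divide="ignore", invalid="ignore"):
        mw = np.where(defined, ls / ri, np.nan) * constants.k_ri / (constants.k_ls * dndc)
        if "VISC" in slices.signals and constants.k_visc is not None:
            visc = slices.signals["VISC"]
            iv = np.where(defined, visc / ri, np.nan) * constants.k_ri * dndc / constants.k_visc
        else:
            iv = np.full_like(ri, np.nan)

    return [
        SliceResult(volume=float(v), mass=float(m), conc=float(c),
                    mw=float(w), iv=float(x))
        for v, m, c, w, x in zip(slices.volumes, mass, conc, mw, iv)
    ]


def _region_arrays(slices: Sequence[SliceResult], region: Optional[PeakRegion]):
    vols = np.array([s.volume for s in slices])
    mass = np.array([s.mass for s in slices])
    mw = np.array([s.mw for s in slices])
    iv = np.array([s.iv for s in slices])
    if region is None:
        keep = np.ones(vols.size, dtype=bool)
    else:
        keep = (vols >= region.start) & (vols <= region.end)
    return vols[keep], mass[keep], mw[keep], iv[keep]


def peak_moments(slices: Sequence[SliceResult],
                 region: PeakRegion) -> tuple[float, float, float, float]:
    """(Mn, Mw, Mz, Pd) over the defined slices of one peak region."""
    _, mass, mw, _ = _region_arrays(slices, region)
    ok = np.isfinite(mw)
    mass, mw = mass[ok], mw[ok]
    if mass.size < 3:
        raise ValueError(
            f"region around {region.apex:.2f} mL has fewer than 3 defined slices"
        )
    if np.any(mw <= 0):
        raise ValueError(
            f"nonpositive slice Mw inside region around {region.apex:.2f} mL"
        )
    mn = mass.sum() / np.sum(mass / mw)
    mw_bar = np.sum(mass * mw) / mass.sum()
    mz = np.sum(mass * mw**2) / np.sum(mass * mw)
    return float(mn), float(mw_bar), float(mz), float(mw_bar / mn)


def hydrodynamic_radius(mw, iv):
    """Equivalent-sphere hydrodynamic radius (nm) from Mw (kDa) and IV (dL/g).

    Solves the Einstein viscosity relation for the radius of the sphere that
    a molecule of molar mass M and intrinsic viscosity [η] would occupy:
    Rh = (3·[η]·M / (10·π·N_A))^(1/3). Accepts scalars or arrays.
    """
    mw_arr = np.asarray(mw, dtype=float)
    iv_arr = np.asarray(iv, dtype=float)
    if np.any(mw_arr <= 0) or np.any(iv_arr <= 0):
        raise ValueError("mw and iv must be positive")
    m_g_mol = mw_arr * 1e3
    iv_cm3_g = iv_arr * 100.0  # dL/g -> cm³/g
    r_cm = (3.0 * iv_cm3_g * m_g_mol / (10.0 * math.pi * N_AVOGADRO)) ** (1.0 / 3.0)
    r_nm = r_cm * 1e7
    return float(r_nm) if np.isscalar(mw) and np.isscalar(iv) else r_nm


def peak_shares(slices: Sequence[SliceResult],
                regions: Sequence[PeakRegion]) -> list[float]:
    """Percent of integrated RI mass in each region (sums to 100)."""
    for r1, r2 in zip(regions, regions[1:]):
        if r2.start < r1.end - 1e-12:
            raise ValueError("regions must be non-overlapping and sorted")
    masses = [float(_region_arrays(slices, r)[1].sum()) for r in regions]
    total = sum(masses)
    if total <= 0:
        raise ValueError("zero total mass over the given regions")
    return [100.0 * m / total for m in masses]


def estimate_composition(apparent_dndc: float, comp_a_dndc: float,
                         comp_b_dndc: float) -> tuple[float, bool]:
    """Weight fraction of component A from a two-component dn/dc mixing rule.

    Solves ``apparent = w·a + (1−w)·b``. Returns ``(w, clamped)`` where
    ``clamped`` flags an apparent dn/dc outside the [a, b] range (w is then
    clipped to [0, 1]).
    """
    if comp_a_dndc == comp_b_dndc:
        raise ValueError("component dn/dc values are equal; composition is "
                         "unidentifiable")
    w = (apparent_dndc - comp_b_dndc) / (comp_a_dndc - comp_b_dndc)
    clamped = not 0.0 <= w <= 1.0
    return float(min(1.0, max(0.0, w))), clamped


def mass_recovery(
    slices: Sequence[SliceResult],
    regions: Optional[Sequence[PeakRegion]],
    injected_mass: Optional[float],
) -> Optional[float]:
    """Percent of the injected mass found in the chromatogram.

    ``regions=None`` integrates the full slice table (column recovery);
    passing regions restricts to those windows. Without a known injected
    mass the quantity is undefined and ``None`` is returned.
    """
    if injected_mass is None:
        return None
    if injected_mass <= 0:
        raise ValueError("injected_mass must be positive")
    if regions is None:
        eluted = float(np.sum([s.mass for s in slices]))
    else:
        eluted = float(sum(_region_arrays(slices, r)[1].sum() for r in regions))
    return 100.0 * eluted / injected_mass


def characterize_peaks(
    slices: Sequence[SliceResult],
    regions: Sequence[PeakRegion],
) -> list[PeakResult]:
    """Condense slice results into one :class:`PeakResult` per region."""
    if not regions:
        return []
    shares = peak_shares(slices, regions)
    peaks: list[PeakResult] = []
    for region, share in zip(regions, shares):
        mn, mw, mz, pd = peak_moments(slices, region)
        _, mass, mw_sl, iv_sl = _region_arrays(slices, region)
        ok = np.isfinite(mw_sl)
        w = mass[ok] / mass[ok].sum()
        mw_se = float(np.sqrt(np.sum(w * (mw_sl[ok] - mw) ** 2) / max(ok.sum() - 1, 1)))
        iv_ok = np.isfinite(iv_sl)
        if iv_ok.any():
            iv_bar = float(np.sum(mass[iv_ok] * iv_sl[iv_ok]) / mass[iv_ok].sum())
            rh = hydrodynamic_radius(mw, iv_bar) if iv_bar > 0 else None
        else:
            iv_bar, rh = None, None
        peaks.append(PeakResult(
            region=region, mw=mw, mn=mn, mz=mz, pd=pd, iv=iv_bar, rh=rh,
            share=share, mass=float(mass.sum()), mw_se=mw_se,
        ))
    return peaks
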