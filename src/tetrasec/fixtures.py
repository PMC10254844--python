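"""Registry of synthetic sample compositions used for testing and demos.

Each fixture emulates one of the characterized samples of the underlying
study system — a protein-A-purified IgG preparation, an HRP preparation, the
ultrafiltered IgG-HRP conjugation product, the pre/post-reduction
intermediates, three commercial IgG-HRP reagents, and a BSA calibration
standard. Species Mw, retention volume and mass shares follow the published
characterization of these samples; peak widths are plausibility choices (the
study reports none), and every species in a fixture shares one dn/dc because
the analysis path uses a single whole-sample dn/dc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .calibration import CalibrationStandard
from .simulate import InstrumentModel, SpeciesSpec, simulate_run
from .traces import MultiDetectorRun

__all__ = ["FIXTURES", "make_fixture", "fixture_meta", "simulate_fixture"]

_DNDC = 0.185  # mL/g, shared by all fixture species (see module docstring)


@dataclass(frozen=True)
class FixtureMeta:
    """Injection metadata and description for a registered fixture."""

    sample_id: str
    description: str
    concentration: float  # mg/mL
    injection_volume: float = 50.0  # µL
    monomer_window: Optional[tuple[float, float]] = None  # mL, standards only

    @property
    def injected_mass(self) -> float:
        """µg loaded on column (concentration × injection volume)."""
        return self.concentration * self.injection_volume


def _mix(rows: Sequence[tuple[str, float, float, float, float, float, float]]
         ) -> list[SpeciesSpec]:
    """Build SpeciesSpec list from (name, mw, iv, dadc, share, vr, sigma) rows,
    normalizing shares to sum exactly to one."""
    total = sum(r[4] for r in rows)
    return [
        SpeciesSpec(name=name, mw=mw, dndc=_DNDC, iv=iv, dadc=dadc,
                    mass_fraction=share / total, vr=vr, sigma=sigma)
        for name, mw, iv, dadc, share, vr, sigma in rows
    ]


# name -> (species rows, meta). The default InstrumentModel (5–14 mL grid at
# 0.01 mL, 0.05 mV noise) applies to every fixture.
_REGISTRY: dict[str, tuple[list[SpeciesSpec], FixtureMeta]] = {
    "igg_prep": (
        _mix([
            ("aggregate", 900.0, 0.075, 1.40, 6.0, 6.80, 0.12),
            ("dimer", 300.0, 0.055, 1.40, 2.0, 8.35, 0.13),
            ("IgG monomer", 152.5, 0.042, 1.40, 92.0, 9.30, 0.14),
        ]),
        FixtureMeta("igg_prep",
                    "protein-A-purified IgG: 92% monomer, 2% dimer, 6% aggregate",
                    concentration=1.5),
    ),
    "hrp_prep": (
        _mix([
            ("impurity", 75.0, 0.035, 0.70, 6.2, 10.20, 0.13),
            ("HRP monomer", 43.1, 0.032, 0.70, 93.8, 10.90, 0.13),
        ]),
        FixtureMeta("hrp_prep", "HRP preparation: ~94% monomer plus an impurity",
                    concentration=2.0),
    ),
    "igg_hrp_pre_reduction": (
        _mix([
            ("aggregate", 902.2, 0.075, 1.20, 52.76, 6.80, 0.22),
            ("IgG-HRP conjugate", 232.2, 0.047, 1.20, 39.59, 8.60, 0.18),
            ("unidentified", 71.8, 0.034, 0.80, 7.66, 10.90, 0.15),
        ]),
        FixtureMeta("igg_hrp_pre_reduction",
                    "conjugation mixture before borohydride reduction",
                    concentration=3.0),
    ),
    "igg_hrp_post_reduction": (
        _mix([
            ("aggregate", 983.1, 0.075, 1.20, 55.47, 6.80, 0.22),
            ("IgG-HRP conjugate", 246.4, 0.047, 1.20, 38.64, 8.60, 0.18),
            ("unidentified", 83.3, 0.034, 0.80, 5.90, 10.90, 0.15),
        ]),
        FixtureMeta("igg_hrp_post_reduction",
                    "conjugation mixture after borohydride reduction",
                    concentration=3.0),
    ),
    "uf_igg_hrp": (
        _mix([
            ("aggregate", 1273.4, 0.075, 1.20, 61.82, 6.80, 0.22),
            ("IgG-HRP conjugate", 234.9, 0.047, 1.20, 32.06, 8.60, 0.18),
            ("unidentified", 64.0, 0.033, 0.80, 6.12, 10.90, 0.15),
        ]),
        FixtureMeta("uf_igg_hrp",
                    "final ultrafiltered IgG-HRP product: aggregate-rich, "
                    "1:2 conjugate, small unidentified species",
                    concentration=3.0),
    ),
    "commercial_1": (
        _mix([
            ("aggregate", 965.0, 0.076, 1.30, 16.18, 7.10, 0.22),
            ("conjugate 1:4", 321.2, 0.059, 1.30, 5.20, 8.20, 0.10),
            ("conjugate 1:2", 225.2, 0.054, 1.30, 9.13, 8.70, 0.10),
            ("free IgG", 145.5, 0.046, 1.40, 61.94, 9.40, 0.13),
            ("unidentified", 68.5, 0.040, 0.80, 7.52, 10.80, 0.13),
        ]),
        FixtureMeta("commercial_1", "commercial rabbit anti-goat IgG-HRP",
                    concentration=1.0),
    ),
    "commercial_2": (
        _mix([
            ("aggregate", 1175.7, 0.080, 1.30, 21.27, 6.80, 0.22),
            ("conjugate 1:5", 371.4, 0.061, 1.30, 9.71, 8.00, 0.10),
            ("conjugate 1:2", 236.1, 0.053, 1.30, 8.99, 8.70, 0.10),
            ("free IgG", 156.6, 0.046, 1.40, 42.36, 9.40, 0.13),
            ("unidentified", 55.6, 0.034, 0.80, 17.67, 10.90, 0.13),
        ]),
        FixtureMeta("commercial_2", "commercial goat anti-rabbit IgG-HRP",
                    concentration=1.0),
    ),
    "commercial_3": (
        _mix([
            ("aggregate", 1754.5, 0.078, 1.30, 15.75, 6.70, 0.22),
            ("conjugate 1:5", 353.2, 0.064, 1.30, 8.58, 8.20, 0.10),
            ("conjugate 1:2", 223.7, 0.055, 1.30, 6.97, 8.70, 0.10),
            ("free IgG", 144.8, 0.046, 1.40, 56.16, 9.40, 0.13),
            ("unidentified", 62.7, 0.041, 0.80, 12.55, 10.80, 0.13),
        ]),
        FixtureMeta("commercial_3", "commercial rabbit anti-guinea-pig IgG-HRP",
                    concentration=1.0),
    ),
    "bsa_standard": (
        _mix([
            ("BSA monomer", 66.4, 0.041, 0.667, 100.0, 10.10, 0.14),
        ]),
        FixtureMeta("bsa_standard", "monomeric BSA calibration standard",
                    concentration=2.0, monomer_window=(9.3, 10.9)),
    ),
    "bsa_standard_dimer": (
        _mix([
            ("BSA dimer", 132.8, 0.045, 0.667, 10.0, 9.55, 0.13),
            ("BSA monomer", 66.4, 0.041, 0.667, 90.0, 10.10, 0.14),
        ]),
        FixtureMeta("bsa_standard_dimer",
                    "BSA standard with 10% dimer (window-sensitivity checks)",
                    concentration=2.0, monomer_window=(9.75, 10.9)),
    ),
}

FIXTURES: tuple[str, ...] = tuple(_REGISTRY)


def make_fixture(name: str) -> tuple[list[SpeciesSpec], InstrumentModel]:
    """Return the (species, instrument) parameter set for a registered fixture."""
    try:
        species, _ = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registered fixtures: {', '.join(FIXTURES)}"
        ) from None
    return list(species), InstrumentModel()


def fixture_meta(name: str) -> FixtureMeta:
    """Injection metadata (mass, volume, windows) for a registered fixture."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; registered fixtures: {', '.join(FIXTURES)}"
        )
    return _REGISTRY[name][1]


def fixture_standard(name: str = "bsa_standard") -> CalibrationStandard:
    """CalibrationStandard describing a BSA fixture's known properties."""
    species, meta = _REGISTRY[name]
    if meta.monomer_window is None:
        raise KeyError(f"fixture {name!r} is not a calibration standard")
    monomer = max(species, key=lambda sp: sp.mass_fraction)
    return CalibrationStandard(
        mw=monomer.mw, dndc=monomer.dndc, dadc=monomer.dadc, iv=monomer.iv,
        concentration=meta.concentration, monomer_window=meta.monomer_window,
    )


def simulate_fixture(
    name: str,
    seed: int,
    noiseless: bool = False,
    instrument: Optional[InstrumentModel] = None,
) -> MultiDetectorRun:
    """Simulate one run of a registered fixture."""
    species, default_instrument = make_fixture(name)
    meta = fixture_meta(name)
    inst = instrument if instrument is not None else default_instrument
    if noiseless:
        inst = inst.noiseless()
    return simulate_run(
        species, inst,
        injected_mass=meta.injected_mass,
        injection_volume=meta.injection_volume,
        seed=seed, sample_id=meta.sample_id,
    )
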