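"""The model/results pair tying the pipeline together.

:class:`MultiDetectionSEC` is built from a run plus calibration constants
(statsmodels-style); :meth:`~MultiDetectionSEC.fit` executes alignment,
baseline correction, peak detection, slice analysis and per-peak
characterization and returns a :class:`SECResults` carrying the estimates, a
``summary()`` table, and hooks for QC classification and plotting.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationConstants, estimate_dndc
from .characterize import (PeakResult, SliceResult, characterize_peaks,
                           mass_recovery, slice_analysis)
from .config import AnalysisConfig
from .processing import (PeakRegion, SliceTable, build_slice_table,
                         default_blank_windows, detect_peaks)
from .qc import ReferenceComponents, SampleReport, classify_peaks
from .traces import DetectorTrace, MultiDetectorRun

__all__ = ["MultiDetectionSEC", "SECResults"]

logger = logging.getLogger("tetrasec")


class MultiDetectionSEC:
    """Multi-detection SEC characterization model for one run.

    Parameters
    ----------
    run
        The chromatogram to characterize.
    constants
        Calibrated detector constants (see
        :func:`tetrasec.calibration.calibrate_from_standard`).
    config
        Analysis configuration; defaults are sensible for the bundled
        instrument model.

    Examples
    --------
    >>> from tetrasec import MultiDetectionSEC, fixtures, calibration
    >>> std = fixtures.simulate_fixture("bsa_standard", seed=0)
    >>> constants = calibration.calibrate_from_standard(
    ...     std, fixtures.fixture_standard())
    >>> run = fixtures.simulate_fixture("uf_igg_hrp", seed=1)
    >>> res = MultiDetectionSEC(run, constants).fit()
    >>> len(res.peaks)
    3
    """

    def __init__(
        self,
        run: MultiDetectorRun,
        constants: CalibrationConstants,
        config: Optional[AnalysisConfig] = None,
    ) -> None:
        self.run = run
        self.constants = constants
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, constants: CalibrationConstants,
                 config: Optional[AnalysisConfig] = None) -> "MultiDetectionSEC":
        """Build the model from a trace CSV file."""
        from .io import read_run

        return cls(read_run(path), constants, config)

    def fit(self) -> "SECResults":
        """Run the full characterization and return the results object."""
        cfg = self.config
        table = build_slice_table(
            self.run,
            blank_windows=cfg.blank_windows,
            detector_offsets=cfg.detector_offsets or None,
        )
        if cfg.dndc is not None:
            dndc = cfg.dndc
            dndc_source = "config"
        else:
            dndc = estimate_dndc(self.run, self.constants,
                                 blank_windows=cfg.blank_windows)
            dndc_source = "estimated from injected mass"
        logger.info("analysis %s: dn/dc=%.4f mL/g (%s), ls_mode=%s, "
                    "min_height_frac=%.3g, min_separation=%.3g mL",
                    self.run.sample_id or "<unnamed>", dndc, dndc_source,
                    cfg.ls_mode, cfg.min_height_frac, cfg.min_separation)

        ri_trace = DetectorTrace("RI", table.volumes, table.signals["RI"])
        regions = detect_peaks(ri_trace,
                               min_height_frac=cfg.min_height_frac,
                               min_separation=cfg.min_separation,
                               edge_floor_frac=cfg.edge_floor_frac)
        slices = slice_analysis(table, self.constants, dndc,
                                injection_volume=self.run.injection_volume,
                                ls_mode=cfg.ls_mode,
                                floor_frac=cfg.slice_floor_frac,
                                noise_floor_factor=cfg.noise_floor_factor)
        peaks = characterize_peaks(slices, regions)
        recovery = mass_recovery(slices, None, self.run.injected_mass)
        logger.info("analysis %s: %d peaks, recovery=%s",
                    self.run.sample_id or "<unnamed>", len(peaks),
                    f"{recovery:.1f}%" if recovery is not None else "n/a")
        return SECResults(model=self, slice_table=table, slices=slices,
                          regions=regions, peaks=peaks, dndc=dndc,
                          dndc_source=dndc_source, recovery=recovery)


class SECResults:
    """Fitted characterization of one run.

    Attributes
    ----------
    peaks : list of PeakResult
        Per-peak V_R, Mw, Mn, Mz, Pd, IV, Rh, share and mass.
    dndc : float
        The sample dn/dc used (mL/g) and its provenance in ``dndc_source``.
    recovery : float or None
        Percent of the injected mass found in the chromatogram.
    """

    def __init__(self, model: MultiDetectionSEC, slice_table: SliceTable,
                 slices: Sequence[SliceResult], regions: Sequence[PeakRegion],
                 peaks: Sequence[PeakResult], dndc: float, dndc_source: str,
                 recovery: Optional[float]) -> None:
        self.model = model
        self.slice_table = slice_table
        self.slices = list(slices)
        self.regions = list(regions)
        self.peaks = list(peaks)
        self.dndc = dndc
        self.dndc_source = dndc_source
        self.recovery = recovery

    @property
    def sample_id(self) -> str:
        return self.model.run.sample_id

    def to_frame(self) -> pd.DataFrame:
        """Per-peak results as a table mirroring a characterization report."""
        rows = []
        for p in self.peaks:
            rows.append({
                "V_R_mL": p.vr, "Mw_kDa": p.mw, "Mn_kDa": p.mn, "Mz_kDa": p.mz,
                "Pd": p.pd, "IV_dL_g": p.iv, "Rh_nm": p.rh,
                "share_pct": p.share, "mass_ug": p.mass, "label": p.label,
            })
        return pd.DataFrame(rows)

    def classify(self, refs: Optional[ReferenceComponents] = None) -> SampleReport:
        """Label peaks (aggregate / conjugate 1:n / free species) and total
        the shares per label."""
        cfg = self.model.config
        refs = refs or ReferenceComponents(
            antibody_mw=cfg.antibody_mw, enzyme_mw=cfg.enzyme_mw,
            tolerance_frac=cfg.tolerance_frac)
        return classify_peaks(self.peaks, refs,
                              aggregate_pd_threshold=cfg.aggregate_pd_threshold,
                              sample_id=self.sample_id, recovery=self.recovery)

    def summary(self) -> str:
        """Human-readable characterization summary."""
        lines = [
            "Multi-detection SEC characterization",
            "=" * 64,
            f"sample:     {self.sample_id or '<unnamed>'}",
            f"dn/dc:      {self.dndc:.4f} mL/g ({self.dndc_source})",
            f"recovery:   "
            + (f"{self.recovery:.1f} %" if self.recovery is not None else "n/a"),
            f"peaks:      {len(self.peaks)}",
            "-" * 64,
            f"{'V_R':>6} {'Mw':>8} {'Mw/Mn':>7} {'IV':>7} {'Rh':>6} {'share':>7}",
            f"{'(mL)':>6} {'(kDa)':>8} {'':>7} {'(dL/g)':>7} {'(nm)':>6} {'(%)':>7}",
            "-" * 64,
        ]
        for p in self.peaks:
            iv = f"{p.iv:.3f}" if p.iv is not None else "  --"
            rh = f"{p.rh:.2f}" if p.rh is not None else " --"
            lines.append(
                f"{p.vr:6.2f} {p.mw:8.1f} {p.pd:7.3f} {iv:>7} {rh:>6} "
                f"{p.share:7.2f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot(self, ax=None, detectors: Optional[Sequence[str]] = None):
        """Overlay the baseline-corrected traces with peak regions shaded.

        Requires matplotlib (the ``plot`` extra).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        detectors = detectors or list(self.slice_table.signals)
        for det in detectors:
            ax.plot(self.slice_table.volumes, self.slice_table.signals[det],
                    label=det, lw=1)
        for region in self.regions:
            ax.axvspan(region.start, region.end, alpha=0.08, color="grey")
            ax.axvline(region.apex, color="grey", lw=0.5, ls=":")
        ax.set_xlabel("retention volume (mL)")
        ax.set_ylabel("signal (mV)")
        ax.set_title(self.sample_id)
        ax.legend(frameon=False, fontsize=8)
        return ax
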