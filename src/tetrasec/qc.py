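"""Conjugation-process quality control on characterized peaks.

Turns per-peak absolute Mw, polydispersity and shares into the questions a
conjugation chemist actually asks: how many enzymes per antibody, how much
aggregate, is free antibody or free enzyme left, and what did each process
step change.

Stoichiometry follows from the Mw excess of a conjugate peak over the free
antibody in units of the enzyme mass: a ~235 kDa peak over a ~153 kDa IgG
with ~43 kDa HRP gives (235−153)/43 ≈ 1.9, i.e. an average 1:2 conjugate.
Aggregates are called by high polydispersity or by Mw beyond what chemistry
allows on a single antibody (the classical limit of five to six coupled
enzyme molecules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .characterize import PeakResult

__all__ = [
    "ReferenceComponents",
    "SampleReport",
    "ProcessComparison",
    "estimate_stoichiometry",
    "classify_peaks",
    "compare_process_steps",
]

#: Chemical limit on enzymes coupled per antibody, used in the aggregate call.
MAX_ENZYMES_PER_ANTIBODY = 6

#: Residual above which the stoichiometry is reported as "1:n or 1:n+1".
AMBIGUITY_RESIDUAL = 0.35


@dataclass(frozen=True)
class ReferenceComponents:
    """Free-component references for classification (kDa)."""

    antibody_mw: float = 152.5  # IgG monomer
    enzyme_mw: float = 43.1  # HRP monomer
    tolerance_frac: float = 0.10  # relative Mw matching tolerance

    def __post_init__(self) -> None:
        if self.antibody_mw <= 0 or self.enzyme_mw <= 0:
            raise ValueError("reference Mw values must be positive")
        if not 0 < self.tolerance_frac < 0.5:
            raise ValueError("tolerance_frac must lie in (0, 0.5)")


@dataclass
class SampleReport:
    """Labeled per-peak QC summary for one sample."""

    sample_id: str
    peaks: list[PeakResult]
    aggregate_share: float
    conjugate_share: float
    free_antibody_share: float
    free_enzyme_share: float
    unidentified_share: float
    recovery: Optional[float] = None
    conjugate_mw: Optional[float] = None  # share-weighted over conjugate peaks

    @property
    def label_shares(self) -> dict[str, float]:
        shares: dict[str, float] = {}
        for p in self.peaks:
            shares[p.label or "unidentified"] = shares.get(p.label or "unidentified",
                                                           0.0) + p.share
        return shares


@dataclass
class ProcessComparison:
    """Stage-to-stage share and conjugate-Mw deltas across process steps."""

    stages: list[SampleReport]
    share_deltas: list[dict[str, float]]  # one dict per consecutive pair
    conjugate_mw_deltas: list[Optional[float]]
    aggregate_alerts: list[tuple[int, float]]  # (transition index, delta)

    @property
    def n_transitions(self) -> int:
        return len(self.share_deltas)


def estimate_stoichiometry(conjugate_mw: float,
                           refs: ReferenceComponents) -> tuple[int, float]:
    """Average enzymes per antibody from a conjugate peak's Mw.

    Returns ``(n, residual_fraction)`` where ``n`` is the nearest nonnegative
    integer to ``(Mw − antibody)/enzyme`` and the residual is the distance to
    it. A residual above ~0.35 means the average sits between two integer
    stoichiometries and should be reported as a pair (1:n or 1:n+1).
    """
    floor = refs.antibody_mw * (1 - refs.tolerance_frac)
    if conjugate_mw < floor:
        raise ValueError(
            f"Mw {conjugate_mw:.1f} kDa is below the antibody reference "
            f"({refs.antibody_mw:.1f} kDa) beyond tolerance; not a conjugate"
        )
    raw = (conjugate_mw - refs.antibody_mw) / refs.enzyme_mw
    n = max(0, int(math.floor(raw + 0.5)))
    return n, abs(raw - n)


def _label_peak(peak: PeakResult, refs: ReferenceComponents,
                aggregate_pd_threshold: float) -> str:
    mw, tol = peak.mw, refs.tolerance_frac
    if abs(mw - refs.enzyme_mw) <= tol * refs.enzyme_mw:
        return "free enzyme"
    if abs(mw - refs.antibody_mw) <= tol * refs.antibody_mw:
        return "free antibody"
    if mw > refs.antibody_mw * (1 + tol):
        nakane_limit = refs.antibody_mw + MAX_ENZYMES_PER_ANTIBODY * refs.enzyme_mw
        if peak.pd >= aggregate_pd_threshold or mw > nakane_limit:
            return "aggregate"
        n, residual = estimate_stoichiometry(mw, refs)
        if n == 0:
            return "unidentified"
        if residual > AMBIGUITY_RESIDUAL:
            lo = int(math.floor((mw - refs.antibody_mw) / refs.enzyme_mw))
            return f"conjugate 1:{lo} or 1:{lo + 1}"
        return f"conjugate 1:{n}"
    return "unidentified"


def classify_peaks(
    peaks: Sequence[PeakResult],
    refs: Optional[ReferenceComponents] = None,
    aggregate_pd_threshold: float = 1.15,
    sample_id: str = "",
    recovery: Optional[float] = None,
) -> SampleReport:
    """Assign species labels to characterized peaks and total the shares.

    Every peak receives a label from {aggregate, conjugate 1:n, free
    antibody, free enzyme, unidentified}; labeled shares sum to the total
    share of the input peaks.
    """
    refs = refs or ReferenceComponents()
    totals = {"aggregate": 0.0, "conjugate": 0.0, "free antibody": 0.0,
              "free enzyme": 0.0, "unidentified": 0.0}
    conj_share = 0.0
    conj_mw_weighted = 0.0
    for peak in peaks:
        label = _label_peak(peak, refs, aggregate_pd_threshold)
        peak.label = label
        key = "conjugate" if label.startswith("conjugate") else label
        totals[key] += peak.share
        if key == "conjugate":
            conj_share += peak.share
            conj_mw_weighted += peak.share * peak.mw
    return SampleReport(
        sample_id=sample_id,
        peaks=list(peaks),
        aggregate_share=totals["aggregate"],
        conjugate_share=totals["conjugate"],
        free_antibody_share=totals["free antibody"],
        free_enzyme_share=totals["free enzyme"],
        unidentified_share=totals["unidentified"],
        recovery=recovery,
        conjugate_mw=(conj_mw_weighted / conj_share) if conj_share > 0 else None,
    )


def compare_process_steps(
    reports: Sequence[SampleReport],
    aggregate_alert_threshold: float = 5.0,
) -> ProcessComparison:
    """Deltas of every labeled share (and conjugate Mw) between stages.

    Labels missing from one stage enter the delta as zero share. An
    aggregate-share increase above ``aggregate_alert_threshold`` percentage
    points between consecutive stages raises an alert entry.
    """
    if len(reports) < 2:
        raise ValueError("need at least two stage reports to compare")
    share_deltas: list[dict[str, float]] = []
    mw_deltas: list[Optional[float]] = []
    alerts: list[tuple[int, float]] = []
    for i, (prev, curr) in enumerate(zip(reports, reports[1:])):
        a, b = prev.label_shares, curr.label_shares
        labels = sorted(set(a) | set(b))
        delta = {lab: b.get(lab, 0.0) - a.get(lab, 0.0) for lab in labels}
        share_deltas.append(delta)
        agg_delta = curr.aggregate_share - prev.aggregate_share
        if agg_delta > aggregate_alert_threshold:
            alerts.append((i, agg_delta))
        if prev.conjugate_mw is not None and curr.conjugate_mw is not None:
            mw_deltas.append(curr.conjugate_mw - prev.conjugate_mw)
        else:
            mw_deltas.append(None)
    return ProcessComparison(
        stages=list(reports),
        share_deltas=share_deltas,
        conjugate_mw_deltas=mw_deltas,
        aggregate_alerts=alerts,
    )
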