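"""File formats: the trace CSV dialect and YAML round-trips for constants,
standards and fixture parameters.

Trace CSV dialect
-----------------
Leading comment lines carry run metadata, then a header row and numeric data::

    # sample_id: uf_igg_hrp
    # injection_volume_uL: 50.0
    # injected_mass_ug: 150.0
    volume_mL,RI_mV,UV_mV,RALS_mV,LALS_mV,VISC_mV
    5.00,0.012,...,...

Missing detectors appear as empty columns. Values survive a write/read
round-trip to 1e-9.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationConstants, CalibrationStandard
from .traces import DETECTORS, DetectorTrace, MultiDetectorRun

__all__ = [
    "TraceFormatError",
    "read_run",
    "write_run",
    "save_constants",
    "load_constants",
    "load_standard",
    "save_standard",
]

_COLUMNS = ["volume_mL"] + [f"{d}_mV" for d in DETECTORS]


class TraceFormatError(ValueError):
    """Malformed trace file; carries the offending line number when known."""


def write_run(run: MultiDetectorRun, path: str | Path) -> None:
    """Write a run in the trace CSV dialect."""
    path = Path(path)
    lines = [f"# sample_id: {run.sample_id}",
             f"# injection_volume_uL: {run.injection_volume!r}"]
    if run.injected_mass is not None:
        lines.append(f"# injected_mass_ug: {run.injected_mass!r}")
    frame = pd.DataFrame({"volume_mL": run.volumes})
    for det in DETECTORS:
        col = f"{det}_mV"
        frame[col] = run.traces[det].signal if det in run else np.nan
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.15g", na_rep="")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_run(path: str | Path) -> MultiDetectorRun:
    """Read a run written by :func:`write_run` (lossless to 1e-9)."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = 0
    with path.open() as fh:
        raw = fh.readlines()
    for i, line in enumerate(raw):
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            header_line = i + 1
        else:
            break

    try:
        frame = pd.read_csv(_io.StringIO("".join(raw[header_line:])))
    except Exception as exc:  # noqa: BLE001 - rewrap with line context
        raise TraceFormatError(
            f"{path}: could not parse CSV body starting at line {header_line + 1}: {exc}"
        ) from exc

    if "volume_mL" not in frame.columns:
        raise TraceFormatError(
            f"{path}: missing required column 'volume_mL' "
            f"(header at line {header_line + 1})"
        )
    def numeric_column(col: str) -> np.ndarray:
        raw = frame[col]
        values = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        # entries that were present but failed to parse (empty cells are fine)
        present = raw.notna() & (raw.astype(str).str.strip() != "")
        bad = np.flatnonzero(np.isnan(values) & present.to_numpy())
        if bad.size:
            raise TraceFormatError(
                f"{path}: non-numeric {col} value at line "
                f"{header_line + 2 + int(bad[0])}"
            )
        return values

    volumes = numeric_column("volume_mL")
    if np.any(np.isnan(volumes)):
        k = int(np.flatnonzero(np.isnan(volumes))[0])
        raise TraceFormatError(
            f"{path}: missing volume at line {header_line + 2 + k}"
        )
    if np.any(np.diff(volumes) <= 0):
        k = int(np.flatnonzero(np.diff(volumes) <= 0)[0])
        raise TraceFormatError(
            f"{path}: volume not strictly increasing at line {header_line + 3 + k}"
        )

    traces: dict[str, DetectorTrace] = {}
    for det in DETECTORS:
        col = f"{det}_mV"
        if col not in frame.columns:
            continue
        signal = numeric_column(col)
        if np.all(np.isnan(signal)):
            continue  # empty column: detector absent
        if np.any(np.isnan(signal)):
            k = int(np.flatnonzero(np.isnan(signal))[0])
            raise TraceFormatError(
                f"{path}: missing {col} value at line {header_line + 2 + k}"
            )
        traces[det] = DetectorTrace(det, volumes, signal)
    if not traces:
        raise TraceFormatError(f"{path}: no detector columns present")

    injection_volume = float(meta.get("injection_volume_uL", "nan"))
    if not np.isfinite(injection_volume):
        raise TraceFormatError(f"{path}: missing '# injection_volume_uL:' metadata")
    injected_mass = meta.get("injected_mass_ug")
    return MultiDetectorRun(
        traces=traces,
        injection_volume=injection_volume,
        injected_mass=float(injected_mass) if injected_mass is not None else None,
        sample_id=meta.get("sample_id", ""),
    )


def save_constants(constants: CalibrationConstants, path: str | Path) -> None:
    data = {k: getattr(constants, k) for k in ("k_ri", "k_uv", "k_ls", "k_visc")}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_constants(path: str | Path) -> CalibrationConstants:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return CalibrationConstants(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid calibration constants file: {exc}") from exc


def save_standard(standard: CalibrationStandard, path: str | Path) -> None:
    data = {
        "mw": standard.mw, "dndc": standard.dndc, "dadc": standard.dadc,
        "iv": standard.iv, "concentration": standard.concentration,
        "monomer_window": list(standard.monomer_window),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_standard(path: str | Path) -> CalibrationStandard:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "monomer_window" in data:
        data["monomer_window"] = tuple(data["monomer_window"])
    try:
        return CalibrationStandard(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid standard file: {exc}") from exc
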