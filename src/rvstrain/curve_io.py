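"""Reading, writing and validation of strain curves and event annotations.

On-disk formats
---------------
Curve file
    CSV with header ``time_ms,strain_pct``: one row per acquired frame,
    time in milliseconds (absolute, from the start of the exported cine
    loop), longitudinal strain in percent (negative = shortening).
Events file
    JSON or YAML object with keys ``subject_id``, ``segment``,
    ``qrs_onset_ms``, ``pv_close_ms`` and optionally ``pv_open_ms`` and
    ``framerate_hz``.  The QRS onset is an annotation on the exported
    trace; it is *not* assumed to coincide with the first sample.
Manifest
    JSON array of ``{"curve": <path>, "events": <path>}`` pairs, paths
    relative to the manifest file.

All numbers use a decimal point and commas as field separators, so files
are locale-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CurveShapeError,
    EventOrderError,
    EventSpanError,
    MissingColumnError,
    MonotonicityError,
    NonNumericError,
)

SEGMENTS = ("basal", "mid", "apical")

CURVE_COLUMNS = ("time_ms", "strain_pct")


@dataclass
class StrainCurve:
    """One segment's longitudinal strain time series.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the curve belongs to.
    segment : str
        RV free-wall segment: ``basal``, ``mid`` or ``apical``.
    times : array-like of float
        Sample times in milliseconds, strictly increasing, length >= 3.
    strains : array-like of float
        Longitudinal strain in percent at each sample; negative values
        denote shortening.
    framerate_hz : float, optional
        Acquisition framerate, if known.
    """

    subject_id: str
    segment: str
    times: np.ndarray
    strains: np.ndarray
    framerate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        if self.segment not in SEGMENTS:
            raise CurveShapeError(
                f"segment must be one of {SEGMENTS}, got {self.segment!r}"
            )
        if self.times.ndim != 1 or self.strains.ndim != 1:
            raise CurveShapeError("times and strains must be 1-D")
        if len(self.times) != len(self.strains):
            raise CurveShapeError(
                f"times ({len(self.times)}) and strains ({len(self.strains)}) "
                "must have equal length"
            )
        if len(self.times) < 3:
            raise CurveShapeError("a strain curve needs at least 3 samples")
        if not np.all(np.isfinite(self.times)):
            raise NonNumericError("field 'time_ms' contains non-finite values")
        if not np.all(np.isfinite(self.strains)):
            raise NonNumericError("field 'strain_pct' contains non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise MonotonicityError(
                "field 'time_ms' must be strictly increasing"
            )
        if self.framerate_hz is not None and self.framerate_hz <= 0:
            raise CurveShapeError("framerate_hz must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CardiacEvents:
    """Cardiac-cycle event annotations anchoring the analysis windows.

    ``qrs_onset_ms`` marks electrical activation; ``pv_close_ms`` is
    pulmonary valve closure (end of systole) from RV outflow-tract
    Doppler; ``pv_open_ms`` (optional) is pulmonary valve opening.
    """

    qrs_onset_ms: float
    pv_close_ms: float
    pv_open_ms: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("qrs_onset_ms", "pv_close_ms"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise NonNumericError(f"field {name!r} must be a finite number")
        if self.qrs_onset_ms >= self.pv_close_ms:
            raise EventOrderError(
                "field 'qrs_onset_ms' must precede 'pv_close_ms' "
                f"({self.qrs_onset_ms} >= {self.pv_close_ms})"
            )
        if self.pv_open_ms is not None and self.pv_open_ms >= self.pv_close_ms:
            raise EventOrderError(
                "field 'pv_open_ms' must precede 'pv_close_ms' "
                f"({self.pv_open_ms} >= {self.pv_close_ms})"
            )


@dataclass
class CurveRecord:
    """A validated (curve, events) pair ready for analysis."""

    curve: StrainCurve
    events: CardiacEvents
    source_path: str = ""

    def __post_init__(self) -> None:
        t0, t1 = self.curve.times[0], self.curve.times[-1]
        for name in ("qrs_onset_ms", "pv_close_ms"):
            v = getattr(self.events, name)
            if not (t0 <= v <= t1):
                raise EventSpanError(
                    f"field {name!r} = {v} lies outside the curve span "
                    f"[{t0}, {t1}]"
                )


def _read_events_file(path: Path) -> dict:
    text = path.read_text()
    # YAML is a superset of JSON, so one loader handles both formats.
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NonNumericError(f"could not parse events file {path}: {exc}")
    if not isinstance(obj, dict):
        raise MissingColumnError(f"events file {path} must contain an object")
    return obj


def read_curve(path, events_path) -> CurveRecord:
    """Read a curve CSV and its event annotation into a :class:`CurveRecord`.

    Raises a distinct validation error for each failure mode: missing
    columns, non-numeric cells, non-monotone time, events outside the
    curve span.
    """
    path = Path(path)
    events_path = Path(events_path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CurveShapeError(f"could not read curve file {path}: {exc}")
    for col in CURVE_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(
                f"curve file {path} is missing column {col!r}"
            )
    for col in CURVE_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            bad = df[col][values.isna()].iloc[0]
            raise NonNumericError(
                f"column {col!r} in {path} contains non-numeric cell {bad!r}"
            )
        df[col] = values

    ev = _read_events_file(events_path)
    for key in ("qrs_onset_ms", "pv_close_ms"):
        if key not in ev:
            raise MissingColumnError(
                f"events file {events_path} is missing key {key!r}"
            )
    for key in ("qrs_onset_ms", "pv_close_ms", "pv_open_ms", "framerate_hz"):
        if key in ev and ev[key] is not None and not isinstance(ev[key], (int, float)):
            raise NonNumericError(
                f"key {key!r} in {events_path} is not numeric: {ev[key]!r}"
            )

    curve = StrainCurve(
        subject_id=str(ev.get("subject_id", path.stem)),
        segment=str(ev.get("segment", "basal")),
        times=df["time_ms"].to_numpy(),
        strains=df["strain_pct"].to_numpy(),
        framerate_hz=ev.get("framerate_hz"),
    )
    events = CardiacEvents(
        qrs_onset_ms=float(ev["qrs_onset_ms"]),
        pv_close_ms=float(ev["pv_close_ms"]),
        pv_open_ms=None if ev.get("pv_open_ms") is None else float(ev["pv_open_ms"]),
    )
    return CurveRecord(curve=curve, events=events, source_path=str(path))


def write_curve(record: CurveRecord, curve_path, events_path) -> None:
    """Write a record back to the curve-CSV + events-JSON pair of files."""
    curve_path = Path(curve_path)
    events_path = Path(events_path)
    df = pd.DataFrame(
        {"time_ms": record.curve.times, "strain_pct": record.curve.strains}
    )
    df.to_csv(curve_path, index=False, float_format="%.4f")
    ev = {
        "subject_id": record.curve.subject_id,
        "segment": record.curve.segment,
        "qrs_onset_ms": record.events.qrs_onset_ms,
        "pv_close_ms": record.events.pv_close_ms,
    }
    if record.events.pv_open_ms is not None:
        ev["pv_open_ms"] = record.events.pv_open_ms
    if record.curve.framerate_hz is not None:
        ev["framerate_hz"] = record.curve.framerate_hz
    events_path.write_text(json.dumps(ev, indent=1, sort_keys=True) + "\n")


METRICS_COLUMNS = (
    "subject_id",
    "segment",
    "onset_ms",
    "peak_strain_pct",
    "systolic_peak_strain_pct",
    "psi_pct",
    "points_onset",
    "points_psi",
    "points_sps",
    "points_total",
    "type",
)


def metrics_row(record: CurveRecord, metrics, result) -> dict:
    """Flatten one analyzed curve into a metrics-table row."""
    return {
        "subject_id": record.curve.subject_id,
        "segment": record.curve.segment,
        "onset_ms": round(metrics.onset_ms, 1),
        "peak_strain_pct": round(metrics.peak_strain_pct, 2),
        "systolic_peak_strain_pct": round(metrics.systolic_peak_strain_pct, 2),
        "psi_pct": round(metrics.psi_pct, 2),
        "points_onset": result.points_onset,
        "points_psi": result.points_psi,
        "points_sps": result.points_sps,
        "points_total": result.points_total,
        "type": result.pattern_type,
    }


def write_metrics(records: Sequence[tuple], path) -> None:
    """Write one row per analyzed curve to a CSV metrics table.

    ``records`` is a non-empty sequence of
    ``(CurveRecord, DeformationMetrics, ClassificationResult)`` triples.
    """
    if len(records) == 0:
        raise CurveShapeError("write_metrics requires at least one record")
    rows = [metrics_row(rec, m, c) for rec, m, c in records]
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[tuple[Path, Path]]:
    """Read a cohort manifest: JSON array of {curve, events} path pairs.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise MissingColumnError(f"could not read manifest {path}: {exc}")
    if not isinstance(entries, list):
        raise MissingColumnError(f"manifest {path} must be a JSON array")
    out = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict) or "curve" not in entry or "events" not in entry:
            raise MissingColumnError(
                f"manifest entry {i} must have 'curve' and 'events' keys"
            )
        base = path.parent
        out.append((base / entry["curve"], base / entry["events"]))
    return out
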