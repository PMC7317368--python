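"""Time re-referencing and uniform resampling of strain curves.

Every curve is restricted to the window from QRS onset to the last
recorded sample, shifted so that QRS onset is time zero, and linearly
interpolated onto a uniform 1000-sample grid.  A common dense grid makes
timing comparisons between curves (and between automatic and manual
annotations) independent of each recording's framerate.

Linear interpolation is used deliberately: it introduces no extrema that
are not already present in the sampled data, which matters because the
onset detector counts local maxima.  Strain values are kept exactly as
recorded — the curve is not re-zeroed at QRS onset — because the peak
comparison threshold and the −10% systolic cut-off are absolute strain
values on the curve as drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curve_io import CurveRecord
from .errors import CurveShapeError, EventOrderError

DEFAULT_N_SAMPLES = 1000


def frame_duration(framerate_hz: float) -> float:
    """Duration of one imaging frame in milliseconds (1000 / framerate).

    At the typical acquisition framerate of 75 Hz this is ~13.3 ms, the
    temporal resolution floor for any onset-timing comparison.
    """
    if framerate_hz <= 0:
        raise CurveShapeError("framerate_hz must be positive")
    return 1000.0 / framerate_hz


@dataclass
class PreparedCurve:
    """A strain curve on the uniform analysis grid.

    ``rel_times`` runs from 0 (QRS onset) to the end of the recording in
    equal steps; ``pv_close_rel_ms`` / ``pv_open_rel_ms`` are the valve
    events on the same clock.  ``native_frame_ms`` is the original
    inter-frame duration, kept so timing errors can be expressed in
    frames.
    """

    rel_times: np.ndarray
    strains: np.ndarray
    pv_close_rel_ms: float
    native_frame_ms: float
    pv_open_rel_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        if len(self.rel_times) != len(self.strains):
            raise CurveShapeError("rel_times and strains must have equal length")
        if self.rel_times[0] != 0.0:
            raise CurveShapeError("rel_times must start at 0 (QRS onset)")
        steps = np.diff(self.rel_times)
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            raise CurveShapeError("rel_times must be uniformly spaced")
        if not (0.0 < self.pv_close_rel_ms <= self.rel_times[-1]):
            raise EventOrderError(
                "pv_close_rel_ms must lie in (0, last rel_time]"
            )
        if self.native_frame_ms <= 0:
            raise CurveShapeError("native_frame_ms must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.rel_times)


def prepare(record: CurveRecord, n_samples: int = DEFAULT_N_SAMPLES) -> PreparedCurve:
    """Re-reference a record to QRS onset and resample to a uniform grid.

    Samples before QRS onset are discarded: the analysis windows (onset
    of shortening, systolic peak) are all defined from electrical
    activation forward.  The native frame duration is taken from the
    recorded framerate when available, otherwise as the median native
    inter-sample interval.
    """
    if n_samples < 2:
        raise CurveShapeError("n_samples must be at least 2")
    times = record.curve.times
    strains = record.curve.strains
    qrs = record.events.qrs_onset_ms
    if record.events.pv_close_ms <= qrs:
        raise EventOrderError("pv_close_ms must come after qrs_onset_ms")
    if int(np.sum(times >= qrs)) < 3:
        raise CurveShapeError(
            "need at least 3 native samples between QRS onset and curve end"
        )
    rel_end = times[-1] - qrs
    rel_times = np.linspace(0.0, rel_end, n_samples)
    resampled = np.interp(rel_times + qrs, times, strains)

    if record.curve.framerate_hz is not None:
        native_frame = frame_duration(record.curve.framerate_hz)
    else:
        native_frame = float(np.median(np.diff(times)))

    pv_open_rel = None
    if record.events.pv_open_ms is not None:
        pv_open_rel = record.events.pv_open_ms - qrs
    return PreparedCurve(
        rel_times=rel_times,
        strains=resampled,
        pv_close_rel_ms=record.events.pv_close_ms - qrs,
        pv_open_rel_ms=pv_open_rel,
        native_frame_ms=native_frame,
    )
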