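"""Detection of the onset of mechanical shortening.

The onset of shortening is the delay between electrical activation (QRS
onset) and the moment the segment starts to shorten on the strain curve.
Mechanical shortening always begins before pulmonary valve closure
(PVC), so only the part of the curve strictly before PVC is searched.

The procedure:

1. Find every local maximum of the strain signal before PVC.  A peak is
   a sample larger than both neighbours; a plateau of equal values
   higher than both flanks counts once, at its first sample.
2. If no peak exists, the onset is placed at QRS onset (time 0).
3. If one peak exists, its time is the onset.
4. With several peaks, walk through them in time order keeping a moving
   candidate: if the next peak lies more than 1.5% absolute strain below
   the current candidate, the candidate wins and the walk stops;
   otherwise the next peak becomes the candidate.  The threshold is an
   absolute strain offset, so the comparison is strict ("more than"):
   a drop of exactly 1.5% still moves the candidate forward.

The 1.5% rule skips small early oscillations (atrial contraction,
tracking wobble) that precede the true onset while refusing to move the
onset past a genuinely deep drop in strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .preprocess import PreparedCurve

DEFAULT_PEAK_OFFSET_PCT = 1.5


@dataclass
class PeakList:
    """Local strain maxima between QRS onset and pulmonary valve closure."""

    indices: np.ndarray   # sample indices into the prepared grid
    times: np.ndarray     # rel_times at those indices (ms)
    values: np.ndarray    # strain at those indices (%)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class OnsetResult:
    """Detected onset of shortening for one curve.

    ``onset_ms`` is 0 with ``selected_peak_index`` absent exactly when no
    peak was found before PVC (fallback: onset at QRS onset).
    """

    onset_ms: float
    selected_peak_index: Optional[int]
    n_peaks_considered: int


def find_peaks(curve: PreparedCurve) -> PeakList:
    """All strict interior local maxima with rel_time strictly before PVC.

    Plateaus (runs of equal values above both flanks) are reported once,
    at their first sample — relevant because dense interpolation of
    frame-limited data produces exact ties.
    """
    # plateau_size=(1, None) makes scipy report plateau edges; the left
    # edge is the first sample of the plateau.
    _, props = _scipy_find_peaks(curve.strains, plateau_size=(1, None))
    indices = props["left_edges"].astype(int)
    keep = curve.rel_times[indices] < curve.pv_close_rel_ms
    indices = indices[keep]
    return PeakList(
        indices=indices,
        times=curve.rel_times[indices],
        values=curve.strains[indices],
    )


def select_onset(
    peaks: PeakList, threshold: float = DEFAULT_PEAK_OFFSET_PCT
) -> Optional[int]:
    """Apply the iterative peak-offset rule; return the position of the
    selected peak within ``peaks`` (None when the list is empty).

    The candidate starts at the first peak; each later peak replaces it
    unless it lies more than ``threshold`` percent strain below the
    candidate, in which case the candidate is final.
    """
    n = len(peaks)
    if n == 0:
        return None
    candidate = 0
    for j in range(1, n):
        if peaks.values[candidate] - peaks.values[j] > threshold:
            break
        candidate = j
    return candidate


def onset_of_shortening(
    curve: PreparedCurve, threshold: float = DEFAULT_PEAK_OFFSET_PCT
) -> OnsetResult:
    """Detect the onset of shortening on a prepared curve."""
    peaks = find_peaks(curve)
    pos = select_onset(peaks, threshold=threshold)
    if pos is None:
        return OnsetResult(onset_ms=0.0, selected_peak_index=None,
                           n_peaks_considered=0)
    return OnsetResult(
        onset_ms=float(peaks.times[pos]),
        selected_peak_index=int(peaks.indices[pos]),
        n_peaks_considered=len(peaks),
    )
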