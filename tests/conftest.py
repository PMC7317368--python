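import numpy as np
import pytest

from rvstrain.preprocess import PreparedCurve


def make_prepared(strains, spacing_ms=25.0, pvc_rel_ms=None, frame_ms=None):
    """Build a PreparedCurve directly from a strain array on a uniform grid."""
    strains = np.asarray(strains, dtype=float)
    rel_times = np.arange(len(strains)) * spacing_ms
    if pvc_rel_ms is None:
        pvc_rel_ms = rel_times[-1]
    return PreparedCurve(
        rel_times=rel_times,
        strains=strains,
        pv_close_rel_ms=pvc_rel_ms,
        native_frame_ms=frame_ms if frame_ms is not None else spacing_ms,
    )


def two_peak_curve(first_peak=2.0, offset=0.63):
    """A curve with exactly two pre-PVC local maxima, the second lying
    `offset` percent strain below the first."""
    strains = [0.0, first_peak, 0.0, first_peak - offset,
               -2.0, -6.0, -12.0, -18.0, -20.0, -20.0, -15.0, -8.0, -2.0, 0.0]
    return make_prepared(strains, spacing_ms=25.0, pvc_rel_ms=250.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
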