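"""Deformation parameters and points-based pattern classification.

Four parameters summarize one RV strain curve:

* **onset of shortening** — delay from QRS onset to the start of
  mechanical shortening (see :mod:`rvstrain.onset_detect`);
* **peak strain (PS)** — the most negative strain over the whole
  analyzed window;
* **systolic peak strain (SPS)** — the most negative strain before or
  at pulmonary valve closure;
* **post-systolic index (PSI)** — ``100 * (PS - SPS) / PS``, the share
  of total shortening that happens after valve closure (0 when PS equals
  SPS).

Onset, PSI and SPS each earn points against a rubric of numeric bands;
the total maps to deformation-pattern type I (normal), II (delayed
onset, post-systolic shortening) or III (severely reduced systolic
function).  One shortcut precedes all scoring: a curve whose systolic
peak strain never drops below −10% scores 4 points outright and is
type III regardless of its onset and PSI, which are then not scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .curve_io import CurveRecord
from .errors import RubricError, UndefinedIndexError
from .onset_detect import DEFAULT_PEAK_OFFSET_PCT, onset_of_shortening
from .preprocess import PreparedCurve, prepare

PATTERN_TYPES = ("I", "II", "III")


@dataclass
class DeformationMetrics:
    """The four extracted parameters for one curve."""

    onset_ms: float
    peak_strain_pct: float
    systolic_peak_strain_pct: float
    psi_pct: float


@dataclass
class ClassificationResult:
    """Per-parameter points, their total, and the pattern type."""

    points_onset: int
    points_psi: int
    points_sps: int
    points_total: int
    pattern_type: str
    sps_shortcut: bool = False


def peak_strain(curve: PreparedCurve) -> float:
    """Peak strain: the most negative strain over the prepared window."""
    return float(np.min(curve.strains))


def systolic_peak_strain(curve: PreparedCurve) -> float:
    """Systolic peak strain: the most negative strain before or at PVC.

    The boundary is inclusive; if the uniform grid does not land exactly
    on the valve-closure time, the strain there is interpolated so the
    window truly ends at PVC.
    """
    mask = curve.rel_times <= curve.pv_close_rel_ms
    at_pvc = float(np.interp(curve.pv_close_rel_ms, curve.rel_times, curve.strains))
    return float(min(np.min(curve.strains[mask]), at_pvc))


def postsystolic_index(ps: float, sps: float) -> float:
    """Post-systolic index: ``100 * (ps - sps) / ps``; 0 when ps == sps."""
    if ps == sps:
        return 0.0
    if ps == 0.0:
        raise UndefinedIndexError(
            "post-systolic index undefined: peak strain is 0 but differs "
            "from systolic peak strain"
        )
    return 100.0 * (ps - sps) / ps


def _load_bands(raw, name) -> list[tuple[float, int]]:
    try:
        bands = [(float(b["upper"]), int(b["points"])) for b in raw]
    except (KeyError, TypeError, ValueError) as exc:
        raise RubricError(f"malformed band list {name!r}: {exc}")
    if not bands:
        raise RubricError(f"band list {name!r} is empty")
    uppers = [u for u, _ in bands]
    if sorted(uppers) != uppers or len(set(uppers)) != len(uppers):
        raise RubricError(f"band bounds in {name!r} must be strictly increasing")
    if not np.isinf(uppers[-1]):
        raise RubricError(f"band list {name!r} must end with an unbounded band")
    return bands


def _band_points(bands: Sequence[tuple[float, int]], value: float) -> int:
    for upper, points in bands:
        if value < upper:
            return points
    raise RubricError(f"no band covers value {value}")  # pragma: no cover


@dataclass
class ScoringRubric:
    """Numeric bands mapping (onset, PSI, SPS) to points and points to type.

    Bands are (upper bound, points) pairs, lower-inclusive and
    upper-exclusive, ending with an unbounded band, so every real value
    scores exactly once.  The package ships a default rubric file
    (``data/default_rubric.yaml``) holding the standard clinical
    cut-offs; alternative rubrics can be loaded from YAML or JSON.
    """

    onset_bands: list
    psi_bands: list
    sps_bands: list
    type_bands: list
    sps_shortcut_threshold_pct: float = -10.0

    def __post_init__(self) -> None:
        self.onset_bands = _load_bands(self.onset_bands, "onset_ms")
        self.psi_bands = _load_bands(self.psi_bands, "psi_pct")
        self.sps_bands = _load_bands(self.sps_bands, "sps_pct")
        tb = []
        try:
            for b in self.type_bands:
                tb.append((int(b[0]) if not isinstance(b, dict) else int(b["max_points"]),
                           str(b[1]) if not isinstance(b, dict) else str(b["type"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise RubricError(f"malformed type_bands: {exc}")
        if not tb or [m for m, _ in tb] != sorted({m for m, _ in tb}):
            raise RubricError("type_bands must have strictly increasing max_points")
        for _, t in tb:
            if t not in PATTERN_TYPES:
                raise RubricError(f"unknown pattern type {t!r}")
        self.type_bands = tb

    @classmethod
    def from_mapping(cls, raw: dict) -> "ScoringRubric":
        try:
            return cls(
                onset_bands=raw["onset_ms"],
                psi_bands=raw["psi_pct"],
                sps_bands=raw["sps_pct"],
                type_bands=raw["type_bands"],
                sps_shortcut_threshold_pct=float(
                    raw.get("sps_shortcut_threshold_pct", -10.0)
                ),
            )
        except KeyError as exc:
            raise RubricError(f"rubric is missing section {exc}")

    @classmethod
    def from_file(cls, path) -> "ScoringRubric":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise RubricError(f"rubric file {path} must contain a mapping")
        return cls.from_mapping(raw)

    @classmethod
    def default(cls) -> "ScoringRubric":
        ref = resources.files("rvstrain").joinpath("data/default_rubric.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text()))

    def points_for_onset(self, onset_ms: float) -> int:
        return _band_points(self.onset_bands, onset_ms)

    def points_for_psi(self, psi_pct: float) -> int:
        return _band_points(self.psi_bands, psi_pct)

    def points_for_sps(self, sps_pct: float) -> int:
        return _band_points(self.sps_bands, sps_pct)

    def type_for_points(self, total: int) -> str:
        for max_points, pattern in self.type_bands:
            if total <= max_points:
                return pattern
        raise RubricError(f"no type band covers total {total}")


def score_and_classify(
    metrics: DeformationMetrics, rubric: Optional[ScoringRubric] = None
) -> ClassificationResult:
    """Score one curve's parameters and map the total to a pattern type.

    The −10% shortcut is checked first: when the systolic peak strain is
    at or above the threshold the curve scores 4 points and is type III;
    onset and PSI contribute 0 and are flagged as not scored.
    """
    rubric = rubric or ScoringRubric.default()
    if metrics.systolic_peak_strain_pct >= rubric.sps_shortcut_threshold_pct:
        return ClassificationResult(
            points_onset=0,
            points_psi=0,
            points_sps=4,
            points_total=4,
            pattern_type=rubric.type_for_points(4),
            sps_shortcut=True,
        )
    p_onset = rubric.points_for_onset(metrics.onset_ms)
    p_psi = rubric.points_for_psi(metrics.psi_pct)
    p_sps = rubric.points_for_sps(metrics.systolic_peak_strain_pct)
    total = p_onset + p_psi + p_sps
    return ClassificationResult(
        points_onset=p_onset,
        points_psi=p_psi,
        points_sps=p_sps,
        points_total=total,
        pattern_type=rubric.type_for_points(total),
        sps_shortcut=False,
    )


def analyze_curve(
    record: CurveRecord,
    rubric: Optional[ScoringRubric] = None,
    n_samples: int = 1000,
    peak_offset_pct: float = DEFAULT_PEAK_OFFSET_PCT,
) -> Tuple[DeformationMetrics, ClassificationResult]:
    """Run the full pipeline on one record: prepare, extract, classify.

    Deterministic and non-interactive.  The onset is detected and
    reported for every curve; under the −10% shortcut it simply carries
    no points.
    """
    prepared = prepare(record, n_samples=n_samples)
    ps = peak_strain(prepared)
    sps = systolic_peak_strain(prepared)
    onset = onset_of_shortening(prepared, threshold=peak_offset_pct)
    if ps == sps or ps != 0.0:
        psi = postsystolic_index(ps, sps)
    else:  # pure-stretching curve; shortcut applies, index not scored
        psi = 0.0
    metrics = DeformationMetrics(
        onset_ms=onset.onset_ms,
        peak_strain_pct=ps,
        systolic_peak_strain_pct=sps,
        psi_pct=psi,
    )
    return metrics, score_and_classify(metrics, rubric)
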