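"""Synthetic RV strain curves with known ground truth.

Clinical strain recordings are rarely shareable, so every stage of the
pipeline is exercised against generated curves whose onset, systolic
peak strain (SPS), peak strain (PS) and post-systolic index (PSI) are
known exactly.

The continuous curve model is built from half-cosine ramps between
anchor points, which keeps the extrema count fully controlled (a sum of
Gaussians, by contrast, can create extra local maxima):

* baseline 0% before QRS onset;
* a pre-stretch bump rising from 0 to ``prestretch_amp_pct`` that peaks
  exactly at ``onset_true_ms`` — the local maximum the onset detector
  must find (type I curves get a small bump, diseased types a larger
  one, mimicking early passive stretch);
* a monotone systolic descent reaching ``sps_true_pct`` exactly at
  pulmonary valve closure;
* when PS lies below SPS, a post-systolic descent to ``ps_true_pct``
  (post-systolic shortening), then recovery to baseline by ``cycle_ms``.

Because every ramp has zero slope at its endpoints, frame-rate sampling
lands near the true extrema and the recovered parameters converge to
the specified values as the framerate grows.

The model is sampled at ``framerate_hz`` (default 75 Hz, a typical
value for RV-focused acquisitions), preceded by a short flat lead-in
before QRS onset so that time re-referencing is exercised.  Optional
noise is Gaussian, low-pass filtered with a moving-average window of at
least 3 samples before being added — raw white noise would litter the
curve with single-sample local maxima that frame-limited, tracker-
smoothed clinical curves do not show.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .curve_io import SEGMENTS, CardiacEvents, CurveRecord, StrainCurve, write_curve
from .errors import InfeasibleSpecError
from .metrics_classify import postsystolic_index

DEFAULT_FRAMERATE_HZ = 75.0
DEFAULT_PVC_MS = 350.0
DEFAULT_CYCLE_MS = 800.0
PSI_CONSISTENCY_TOL = 0.1
NOISE_SMOOTH_SAMPLES = 5
LEAD_IN_FRAMES = 3

#: Per-type sampling ranges for cohort generation.  Chosen to land well
#: inside the default rubric bands so that a correctly recovered
#: parameter cannot straddle a scoring boundary: type I curves score 0
#: points on every parameter, type II curves score 1+1+1, and type III
#: curves trigger the −10% systolic shortcut.
DEFAULT_PARAM_RANGES = {
    "I": {
        "onset_ms": (40.0, 90.0),
        "sps_pct": (-28.0, -22.0),
        "psi_pct": (0.0, 6.0),
        "prestretch_amp_pct": (0.5, 1.5),
    },
    "II": {
        "onset_ms": (122.0, 138.0),
        "sps_pct": (-18.5, -16.5),
        "psi_pct": (14.0, 21.0),
        "prestretch_amp_pct": (1.5, 3.5),
    },
    "III": {
        "onset_ms": (150.0, 240.0),
        "sps_pct": (-8.0, -4.0),
        "ps_pct": (-18.0, -12.0),
        "prestretch_amp_pct": (3.0, 6.0),
    },
}


@dataclass
class SyntheticSpec:
    """Ground-truth parameters from which one synthetic curve is built."""

    pattern_type: str
    onset_true_ms: float
    sps_true_pct: float
    ps_true_pct: float
    psi_true_pct: float
    prestretch_amp_pct: float = 1.0
    pvc_ms: float = DEFAULT_PVC_MS
    cycle_ms: float = DEFAULT_CYCLE_MS
    framerate_hz: float = DEFAULT_FRAMERATE_HZ
    noise_sd_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_type not in ("I", "II", "III"):
            raise InfeasibleSpecError(
                f"pattern_type must be I, II or III, got {self.pattern_type!r}"
            )
        if self.ps_true_pct > self.sps_true_pct:
            raise InfeasibleSpecError(
                "ps_true_pct must not exceed sps_true_pct "
                f"({self.ps_true_pct} > {self.sps_true_pct})"
            )
        if not (0.0 < self.onset_true_ms < self.pvc_ms < self.cycle_ms):
            raise InfeasibleSpecError(
                "need 0 < onset_true_ms < pvc_ms < cycle_ms"
            )
        if self.pattern_type == "III" and self.sps_true_pct < -10.0:
            raise InfeasibleSpecError(
                "type III requires sps_true_pct >= -10%"
            )
        if self.prestretch_amp_pct < 0:
            raise InfeasibleSpecError("prestretch_amp_pct must be >= 0")
        if self.noise_sd_pct < 0:
            raise InfeasibleSpecError("noise_sd_pct must be >= 0")
        if self.framerate_hz <= 0:
            raise InfeasibleSpecError("framerate_hz must be positive")
        expected_psi = (
            0.0 if self.ps_true_pct == self.sps_true_pct
            else postsystolic_index(self.ps_true_pct, self.sps_true_pct)
        )
        if abs(self.psi_true_pct - expected_psi) > PSI_CONSISTENCY_TOL:
            raise InfeasibleSpecError(
                f"psi_true_pct = {self.psi_true_pct} inconsistent with "
                f"ps/sps pair (implies {expected_psi:.3f})"
            )

    @classmethod
    def from_extrema(cls, pattern_type, onset_true_ms, sps_true_pct,
                     ps_true_pct, **kwargs) -> "SyntheticSpec":
        """Build a spec with the PSI derived from the PS/SPS pair."""
        psi = (0.0 if ps_true_pct == sps_true_pct
               else postsystolic_index(ps_true_pct, sps_true_pct))
        return cls(pattern_type=pattern_type, onset_true_ms=onset_true_ms,
                   sps_true_pct=sps_true_pct, ps_true_pct=ps_true_pct,
                   psi_true_pct=psi, **kwargs)


def _ramp(t: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Half-cosine ramp from (t0, v0) to (t1, v1); zero slope at both ends."""
    phase = (t - t0) / (t1 - t0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * phase))


def model_strain(spec: SyntheticSpec, rel_times: np.ndarray) -> np.ndarray:
    """Evaluate the continuous noise-free curve model.

    ``rel_times`` is time in ms relative to QRS onset; times outside
    [0, cycle_ms] return baseline 0.
    """
    t = np.asarray(rel_times, dtype=float)
    out = np.zeros_like(t)
    onset, pvc, cycle = spec.onset_true_ms, spec.pvc_ms, spec.cycle_ms
    has_pss = spec.sps_true_pct - spec.ps_true_pct > 1e-9
    # post-systolic trough placed a third of the way into diastole
    t_ps = pvc + 0.3 * (cycle - pvc)

    seg = (t > 0) & (t <= onset)
    out[seg] = _ramp(t[seg], 0.0, onset, 0.0, spec.prestretch_amp_pct)
    seg = (t > onset) & (t <= pvc)
    out[seg] = _ramp(t[seg], onset, pvc, spec.prestretch_amp_pct,
                     spec.sps_true_pct)
    if has_pss:
        seg = (t > pvc) & (t <= t_ps)
        out[seg] = _ramp(t[seg], pvc, t_ps, spec.sps_true_pct,
                         spec.ps_true_pct)
        seg = (t > t_ps) & (t < cycle)
        out[seg] = _ramp(t[seg], t_ps, cycle, spec.ps_true_pct, 0.0)
    else:
        seg = (t > pvc) & (t < cycle)
        out[seg] = _ramp(t[seg], pvc, cycle, spec.sps_true_pct, 0.0)
    return out


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    smooth = uniform_filter1d(white, size=NOISE_SMOOTH_SAMPLES, mode="reflect")
    scale = smooth.std()
    if scale > 0:
        smooth *= sd / scale
    return smooth


def generate_curve(
    spec: SyntheticSpec,
    subject_id: str = "synthetic",
    segment: str = "basal",
) -> CurveRecord:
    """Sample one synthetic curve record from a spec; deterministic in seed."""
    dt = 1000.0 / spec.framerate_hz
    lead_ms = LEAD_IN_FRAMES * dt
    times = np.arange(0.0, lead_ms + spec.cycle_ms + 0.5 * dt, dt)
    strains = model_strain(spec, times - lead_ms)
    if spec.noise_sd_pct > 0:
        rng = np.random.default_rng(spec.seed)
        strains = strains + _smoothed_noise(rng, len(times), spec.noise_sd_pct)
    pv_open = lead_ms + min(80.0, 0.5 * spec.pvc_ms)
    curve = StrainCurve(
        subject_id=subject_id,
        segment=segment,
        times=times,
        strains=strains,
        framerate_hz=spec.framerate_hz,
    )
    events = CardiacEvents(
        qrs_onset_ms=lead_ms,
        pv_close_ms=lead_ms + spec.pvc_ms,
        pv_open_ms=pv_open,
    )
    return CurveRecord(curve=curve, events=events,
                       source_path=f"synthetic://{subject_id}/{segment}")


@dataclass
class CohortEntry:
    """One generated curve together with its ground truth."""

    record: CurveRecord
    spec: SyntheticSpec


def _uniform(rng: np.random.Generator, lo_hi) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def random_spec(
    pattern_type: str,
    rng: np.random.Generator,
    param_ranges: Optional[dict] = None,
    framerate_hz: float = DEFAULT_FRAMERATE_HZ,
    noise_sd_pct: float = 0.0,
    pvc_ms: float = DEFAULT_PVC_MS,
    cycle_ms: float = DEFAULT_CYCLE_MS,
) -> SyntheticSpec:
    """Draw one ground-truth spec of the given type from parameter ranges."""
    ranges = (param_ranges or DEFAULT_PARAM_RANGES)[pattern_type]
    onset = _uniform(rng, ranges["onset_ms"])
    sps = _uniform(rng, ranges["sps_pct"])
    if "ps_pct" in ranges:
        ps = min(_uniform(rng, ranges["ps_pct"]), sps)
    else:
        # derive PS from the target PSI:  psi = 100*(ps - sps)/ps
        psi = _uniform(rng, ranges["psi_pct"])
        ps = sps / (1.0 - psi / 100.0)
    seed = int(rng.integers(0, 2**31 - 1))
    return SyntheticSpec.from_extrema(
        pattern_type=pattern_type,
        onset_true_ms=onset,
        sps_true_pct=sps,
        ps_true_pct=ps,
        prestretch_amp_pct=_uniform(rng, ranges["prestretch_amp_pct"]),
        pvc_ms=pvc_ms,
        cycle_ms=cycle_ms,
        framerate_hz=framerate_hz,
        noise_sd_pct=noise_sd_pct,
        seed=seed,
    )


def _type_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n subjects over the type mix."""
    mix = np.asarray(mix, dtype=float)
    if len(mix) != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise InfeasibleSpecError("type_mix must be 3 non-negative shares summing to 1")
    raw = n * mix
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_cohort(
    n_subjects: int,
    type_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    segment_count: int = 3,
    param_ranges: Optional[dict] = None,
    seed: int = 0,
    framerate_hz: float = DEFAULT_FRAMERATE_HZ,
    noise_sd_pct: float = 0.0,
    pvc_ms: float = DEFAULT_PVC_MS,
    cycle_ms: float = DEFAULT_CYCLE_MS,
) -> list[CohortEntry]:
    """Generate a reproducible cohort of ``n_subjects * segment_count`` curves.

    Each subject is assigned one deformation-pattern type (all of their
    segments share it, as in a real cohort) using largest-remainder
    apportionment of ``type_mix``, and each segment gets an independent
    draw of within-type parameters.
    """
    if n_subjects < 1:
        raise InfeasibleSpecError("n_subjects must be >= 1")
    if not (1 <= segment_count <= 3):
        raise InfeasibleSpecError("segment_count must be in 1..3")
    rng = np.random.default_rng(seed)
    counts = _type_counts(n_subjects, type_mix)
    types = [t for t, c in zip(("I", "II", "III"), counts) for _ in range(c)]
    rng.shuffle(types)
    entries = []
    for i, pattern_type in enumerate(types):
        subject_id = f"S{i + 1:03d}"
        for segment in SEGMENTS[:segment_count]:
            spec = random_spec(
                pattern_type, rng, param_ranges=param_ranges,
                framerate_hz=framerate_hz, noise_sd_pct=noise_sd_pct,
                pvc_ms=pvc_ms, cycle_ms=cycle_ms,
            )
            record = generate_curve(spec, subject_id=subject_id, segment=segment)
            entries.append(CohortEntry(record=record, spec=spec))
    return entries


def write_cohort(entries: Sequence[CohortEntry], out_dir) -> Path:
    """Write a cohort to disk: curve CSVs, event JSONs, a manifest and a
    ground-truth table.  Returns the manifest path."""
    if len(entries) == 0:
        raise InfeasibleSpecError("cohort is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    truth_rows = []
    for entry in entries:
        stem = f"{entry.record.curve.subject_id}_{entry.record.curve.segment}"
        curve_name, events_name = f"{stem}.csv", f"{stem}.events.json"
        write_curve(entry.record, out_dir / curve_name, out_dir / events_name)
        manifest.append({"curve": curve_name, "events": events_name})
        truth_rows.append(
            {"subject_id": entry.record.curve.subject_id,
             "segment": entry.record.curve.segment,
             **asdict(entry.spec)}
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest_path
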