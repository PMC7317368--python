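# Methods

## Signal model and assumptions

A strain curve is one cardiac cycle (or more) of regional longitudinal
strain ε(t) in percent, negative during shortening, sampled at the
acquisition framerate (typically 40–120 Hz for RV-focused views; the
package default is 75 Hz, giving 1000/75 ≈ 13.3 ms per frame). Three
manual annotations anchor the analysis: QRS onset, pulmonary valve
opening (optional) and pulmonary valve closure (PVC). The analysis
assumes mechanical shortening begins before PVC and that the curve
extends at least a few frames past QRS onset; it makes no assumption
about baseline drift or absolute timing of the exported cine loop.

## Preprocessing

Curves are cut to [QRS onset, last sample], shifted so QRS onset is
t = 0, and linearly interpolated to a uniform grid of 1000 samples.
Linear interpolation is deliberate: it creates no extrema that are not
already in the sampled data, and the onset detector counts extrema.
Samples before QRS onset are discarded because every extracted
parameter is defined from electrical activation forward. Strain values
are *not* re-zeroed at QRS onset: the 1.5% peak-offset rule and the
−10% systolic cut-off are absolute comparisons on the curve as drawn.
Peak detection runs on the interpolated grid, so all curves are treated
at the same (dense) resolution regardless of framerate.

The native frame duration is kept with each prepared curve — from the
recorded framerate when available, otherwise the median native
inter-sample interval — because one frame is the temporal resolution
floor for any timing statement.

## Onset of shortening

Local maxima are detected as samples strictly larger than both
neighbours (`scipy.signal.find_peaks`); a plateau of tied values above
both flanks counts once, at its first sample — the earliest defensible
onset, and a case that matters because dense interpolation of
frame-limited data produces exact ties. Maxima at or after PVC are
excluded ("before PVC" is read strictly).

Selection walks the peaks in time order with a moving candidate,
starting at the first peak: if the next peak lies **more than** 1.5%
absolute strain below the candidate (strict inequality; a drop of
exactly 1.5% does not stop the walk), the candidate is final; otherwise
the next peak becomes the candidate. The iteration is therefore a
pairwise chain — each comparison is between the surviving candidate and
the next peak, not between every peak and the first. With no peak the
onset falls back to 0 ms (QRS onset). The threshold is an absolute
strain offset, so rescaling a curve's amplitude can legitimately change
the selected peak; adding a constant cannot.

No prominence or width filter is applied beyond the 1.5% rule itself:
micro-maxima survive detection and are handled (or not) by the
selection walk. Consequently the detector is faithful on
tracker-smoothed clinical curves but will chase noise on signals with
high-frequency content; smooth the input first if that is the regime.

## Parameters and scoring

Peak strain PS is the minimum of the prepared curve; systolic peak
strain SPS is the minimum over t ≤ PVC, with the value at PVC obtained
by interpolation when the grid does not land on it (the boundary is
inclusive). The systolic window starts at QRS onset, not at pulmonary
valve opening; for curves whose pre-ejection strain dips lowest the two
conventions differ, and the QRS-anchored one is implemented. The
post-systolic index is PSI = 100·(PS − SPS)/PS, set to 0 when PS = SPS
and undefined (an error) only when PS = 0 while SPS differs — a case
the −10% shortcut removes before PSI is ever scored. PSI can exceed
100% only when the systolic "peak" is a stretch (SPS > 0).

Scoring uses ordered numeric bands (lower-inclusive, upper-exclusive,
last band unbounded) shipped as a reviewable YAML file rather than
hard-coded constants, since cut-offs of this kind are conventions that
centers may tune:

| points | onset (ms) | PSI (%) | SPS (%) |
|---|---|---|---|
| 0 | < 110 | < 10 | < −20 |
| 1 | 110–150 | 10–25 | −20 to −15 |
| 2 | ≥ 150 | ≥ 25 | −15 to −10 |
| 4 | — | — | ≥ −10 |

Totals map to types: 0–1 → I, 2–3 → II, 4–6 → III. A SPS at or above
−10% (inclusive at the boundary) takes the 4-point shortcut: total 4,
type III, onset and PSI recorded but carrying 0 points with a flag
noting they were not scored. One consequence, verified by the property
tests: the points total is monotone in each parameter except across the
shortcut transition, where a 5–6 point curve collapses to the fixed
4-point score — the *type* (III either way) is monotone everywhere.

## Synthetic curves

The generator exists to give every pipeline stage a ground truth. A
curve is assembled from half-cosine ramps between anchor points:
baseline 0% before QRS onset (a 3-frame lead-in exercises time
re-referencing), a pre-stretch rise peaking exactly at the true onset,
a monotone systolic descent reaching the true SPS exactly at PVC, an
optional post-systolic descent to the true PS bottoming a third of the
way into diastole, and recovery to baseline by end-cycle (default
cycle 800 ms, PVC 350 ms — physiologically plausible placeholders).
Piecewise cosines rather than Gaussian mixtures guarantee a known
extrema count, and their zero endpoint slopes mean frame-rate sampling
lands near the true extrema, so recovered parameters converge to the
specified ones.

Specs whose PSI disagrees with the PS/SPS pair by more than 0.1 are
rejected as infeasible. Noise, when requested, is Gaussian smoothed
with a 5-sample moving average before addition: raw white noise on a
dense grid would create single-sample maxima that frame-limited,
tracker-smoothed clinical curves do not exhibit. Default cohort ranges
place each type's parameters well inside one rubric band (type I scores
0+0+0, type II 1+1+1, type III takes the shortcut), so a correctly
recovered parameter cannot straddle a scoring boundary; all of a
subject's segments share one pattern type, as in real cohorts.

What the generator does **not** emulate: beat-to-beat variability,
baseline drift, tracking dropout, atrial-contraction notches, or any
estimate of real-world noise amplitude (no published statistics exist
for these curves). Passing tests therefore demonstrate algorithmic
correctness on well-posed curves, not clinical performance.

## Agreement statistics

`compare_onsets` treats the paired annotations symmetrically: signed
differences a − b feed the Bland–Altman mean and 1.96·SD limits (no
repeated-measures correction — one onset per curve); absolute
differences feed the median/IQR and the per-curve frame statistic
|a − b| / frame duration, with an option to use a single global frame
duration instead. ρ is Spearman's rank correlation (Pearson is reported
alongside). The ICC is the two-way random-effects, absolute-agreement,
single-measurement form (ICC(2,1), via `pingouin`), the standard choice
for two raters measuring the same quantity; exact agreement
short-circuits to ICC 1 since the F-based estimator degenerates at zero
error variance.

## Problem sizes and tolerances in the validation suite

The suite checks the onset detector against a literal brute-force
transcription of the peak rules on 1000 random noisy synthetic curves;
parameter recovery on 500 noise-free 75 Hz curves (onset within one
frame, PS/SPS within 0.5% strain, PSI within 1 point); and end-to-end
classification of a 62-subject × 3-segment (186-curve) noise-free
cohort, which must be deterministic under a fixed seed and match ground
truth exactly. These sizes keep the whole suite under ~10 s while
leaving the statistics well-powered.

## Limitations

- Classification uses a single curve; averaging parameters over all
  curves of a segment is out of scope.
- QRS onset and valve timings are inputs; the package does no ECG or
  Doppler processing.
- The default rubric is a convention, not a fitted model; studies using
  different cut-offs should supply their own rubric file.
- Reading vendor-proprietary exports (EchoPAC native files, DICOM) is
  out of scope; curves enter as delimited text.
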