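# Default points rubric for RV deformation-pattern classification.
#
# Each band list maps a parameter value to points.  A value falls in the
# first band whose `upper` bound it is strictly below (bounds are
# lower-inclusive, upper-exclusive); the final band is unbounded.
#
# A systolic peak strain at or above the shortcut threshold of -10%
# scores 4 points outright and forces a type III classification; onset
# and post-systolic index are then not scored (0 points).
#
# Totals map to the pattern type: 0-1 points type I (normal),
# 2-3 points type II, 4-6 points type III.
onset_ms:
  - {upper: 110, points: 0}
  - {upper: 150, points: 1}
  - {upper: .inf, points: 2}
psi_pct:
  - {upper: 10, points: 0}
  - {upper: 25, points: 1}
  - {upper: .inf, points: 2}
sps_pct:
  - {upper: -20, points: 0}
  - {upper: -15, points: 1}
  - {upper: -10, points: 2}
  - {upper: .inf, points: 4}
sps_shortcut_threshold_pct: -10.0
type_bands:
  - {max_points: 1, type: I}
  - {max_points: 3, type: II}
  - {max_points: 6, type: III}
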