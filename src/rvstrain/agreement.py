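"""Agreement statistics between two sets of onset annotations.

Given paired onset-of-shortening times from two raters (algorithm vs
operator, or operator vs operator), this module computes the standard
method-comparison battery:

* Bland–Altman: mean of the signed differences ``a - b``, their SD and
  the 1.96·SD limits of agreement;
* median and inter-quartile range of the absolute differences;
* Spearman rank correlation (with Pearson alongside);
* intraclass correlation coefficient, two-way random effects, absolute
  agreement, single measurement (ICC2), with its 95% CI — the standard
  form for two-rater absolute agreement;
* the share of curves whose absolute difference is within one imaging
  frame, using each curve's own frame duration by default (a global
  frame duration, e.g. the cohort mean, can be supplied instead).

Timing disagreements below one frame duration are below the temporal
resolution of the acquisition and cannot be meaningful.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CurveShapeError, MissingColumnError, NonNumericError

PATTERN_TYPES = ("I", "II", "III")


@dataclass
class PairedOnsets:
    """Paired onset annotations for a set of curves."""

    curve_ids: Sequence
    onsets_a: np.ndarray
    onsets_b: np.ndarray
    native_frame_ms: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_a = np.asarray(self.onsets_a, dtype=float)
        self.onsets_b = np.asarray(self.onsets_b, dtype=float)
        self.native_frame_ms = np.asarray(self.native_frame_ms, dtype=float)
        n = len(self.onsets_a)
        if not (len(self.curve_ids) == len(self.onsets_b)
                == len(self.native_frame_ms) == n):
            raise CurveShapeError("paired onset arrays must have equal length")
        if n < 2:
            raise CurveShapeError("need at least 2 paired onsets")
        if np.any(self.onsets_a < 0) or np.any(self.onsets_b < 0):
            raise NonNumericError("onsets must be >= 0 ms")
        if np.any(self.native_frame_ms <= 0):
            raise NonNumericError("native_frame_ms must be positive")

    @classmethod
    def from_csv(cls, path) -> "PairedOnsets":
        """Read pairs from a CSV with columns
        ``curve_id, onset_a_ms, onset_b_ms, frame_ms``."""
        df = pd.read_csv(path)
        for col in ("curve_id", "onset_a_ms", "onset_b_ms", "frame_ms"):
            if col not in df.columns:
                raise MissingColumnError(
                    f"pairs file {path} is missing column {col!r}"
                )
        return cls(
            curve_ids=df["curve_id"].tolist(),
            onsets_a=df["onset_a_ms"].to_numpy(),
            onsets_b=df["onset_b_ms"].to_numpy(),
            native_frame_ms=df["frame_ms"].to_numpy(),
        )


@dataclass
class AgreementReport:
    mean_diff_ms: float
    sd_diff_ms: float
    loa_low_ms: float
    loa_high_ms: float
    median_abs_diff_ms: float
    iqr_abs_diff_ms: Tuple[float, float]
    rho: float
    rho_p: float
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci: Tuple[float, float]
    frac_within_1_frame: float
    n: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _icc2(a: np.ndarray, b: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1) via pingouin; degenerate exact agreement short-circuits to 1."""
    if np.array_equal(a, b):
        return 1.0, (1.0, 1.0)
    import pingouin as pg

    n = len(a)
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "rating": np.concatenate([a, b]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # degenerate inputs (zero error variance) trip internal divides
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="rating"
        ).set_index("Type")
    # pingouin labels the two-way random, absolute-agreement, single-rater
    # form "ICC2" or "ICC(A,1)" depending on version
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(x) for x in row[ci_col])
    return float(row["ICC"]), (lo, hi)


def compare_onsets(
    pairs: PairedOnsets, global_frame_ms: Optional[float] = None
) -> AgreementReport:
    """Compute the full agreement report for paired onset annotations.

    Signed differences are ``a - b`` (Bland–Altman); absolute differences
    feed the median/IQR and frame statistics.  ``global_frame_ms``
    replaces the per-curve frame durations when given.
    """
    a, b = pairs.onsets_a, pairs.onsets_b
    diffs = a - b
    abs_diffs = np.abs(diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    q1, q3 = (float(q) for q in np.percentile(abs_diffs, [25, 75]))

    rho, rho_p = stats.spearmanr(a, b)
    r, r_p = stats.pearsonr(a, b) if len(a) > 2 else (np.nan, np.nan)
    icc, icc_ci = _icc2(a, b)

    frames = (np.full_like(abs_diffs, float(global_frame_ms))
              if global_frame_ms is not None else pairs.native_frame_ms)
    frame_diffs = abs_diffs / frames
    return AgreementReport(
        mean_diff_ms=mean,
        sd_diff_ms=sd,
        loa_low_ms=mean - 1.96 * sd,
        loa_high_ms=mean + 1.96 * sd,
        median_abs_diff_ms=float(np.median(abs_diffs)),
        iqr_abs_diff_ms=(q1, q3),
        rho=float(rho),
        rho_p=float(rho_p),
        pearson_r=float(r),
        pearson_p=float(r_p),
        icc=icc,
        icc_ci=icc_ci,
        frac_within_1_frame=float(np.mean(frame_diffs <= 1.0)),
        n=len(a),
    )


def compare_classifications(
    types_a: Sequence[str], types_b: Sequence[str]
) -> Tuple[float, pd.DataFrame]:
    """Exact-match agreement fraction and 3×3 confusion table (a in rows)."""
    if len(types_a) != len(types_b):
        raise CurveShapeError("classification sequences must have equal length")
    if len(types_a) == 0:
        raise CurveShapeError("classification sequences must be non-empty")
    sa = pd.Series(types_a, name="a")
    sb = pd.Series(types_b, name="b")
    agreement = float((sa.to_numpy() == sb.to_numpy()).mean())
    confusion = (
        pd.crosstab(sa, sb)
        .reindex(index=PATTERN_TYPES, columns=PATTERN_TYPES, fill_value=0)
    )
    return agreement, confusion


def bland_altman_plot(pairs: PairedOnsets, path,
                      report: Optional[AgreementReport] = None) -> None:
    """Save a Bland–Altman scatter of the paired onsets to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = report or compare_onsets(pairs)
    means = (pairs.onsets_a + pairs.onsets_b) / 2.0
    diffs = pairs.onsets_a - pairs.onsets_b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7)
    ax.axhline(report.mean_diff_ms, color="red",
               label=f"mean {report.mean_diff_ms:.1f} ms")
    for y in (report.loa_low_ms, report.loa_high_ms):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel("mean onset of both methods (ms)")
    ax.set_ylabel("difference a − b (ms)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
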