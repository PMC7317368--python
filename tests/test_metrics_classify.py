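import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_prepared
from rvstrain import errors
from rvstrain.metrics_classify import (
    DeformationMetrics,
    ScoringRubric,
    analyze_curve,
    peak_strain,
    postsystolic_index,
    score_and_classify,
    systolic_peak_strain,
)
from rvstrain.synth import SyntheticSpec, generate_curve, random_spec


@pytest.fixture(scope="module")
def rubric():
    return ScoringRubric.default()


# ---------------------------------------------------------------------------
# extrema
# ---------------------------------------------------------------------------


def test_peak_strain_is_global_minimum():
    prep = make_prepared([0.0, -5.0, -22.4, -18.0, -9.0])
    assert peak_strain(prep) == -22.4
    assert peak_strain(make_prepared([-5.0, -5.0, -5.0, -5.0])) == -5.0


def test_systolic_peak_strain_windows_at_pvc():
    # global minimum after PVC; pre-PVC minimum is -12
    strains = [0.0, -6.0, -12.0, -10.0, -20.0, -25.0, -15.0]
    prep = make_prepared(strains, pvc_rel_ms=75.0)
    assert systolic_peak_strain(prep) == -12.0
    assert peak_strain(prep) == -25.0


def test_systolic_peak_strain_inclusive_and_interpolated_at_pvc():
    # monotone decrease through PVC: SPS is the (interpolated) value at PVC
    strains = np.linspace(0.0, -24.0, 13)  # 25 ms spacing, -2 per step
    prep = make_prepared(strains, pvc_rel_ms=112.5)  # between two samples
    assert systolic_peak_strain(prep) == pytest.approx(-9.0)


def test_extrema_match_brute_force_and_ordering(rng):
    for _ in range(200):
        strains = rng.normal(-10, 6, 80)
        pvc = float(rng.uniform(100, 1900))
        prep = make_prepared(strains, spacing_ms=25.0, pvc_rel_ms=pvc)
        ps = peak_strain(prep)
        sps = systolic_peak_strain(prep)
        assert ps == np.min(strains)
        assert ps <= sps + 1e-12


# ---------------------------------------------------------------------------
# post-systolic index
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ps, sps, expected",
    [(-18.0, -18.0, 0.0), (-20.0, -15.0, 25.0), (-10.0, 0.0, 100.0)],
)
def test_postsystolic_index_arithmetic(ps, sps, expected):
    assert postsystolic_index(ps, sps) == pytest.approx(expected)


def test_postsystolic_index_undefined_for_zero_peak_strain():
    with pytest.raises(errors.UndefinedIndexError):
        postsystolic_index(0.0, 2.0)


def test_psi_exceeds_100_only_with_systolic_stretching():
    assert postsystolic_index(-10.0, 2.0) > 100.0
    assert postsystolic_index(-10.0, -0.5) < 100.0
    assert postsystolic_index(-10.0, 0.0) == 100.0


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------


def test_sps_shortcut_scores_4_points_type_III(rubric):
    m = DeformationMetrics(onset_ms=50.0, peak_strain_pct=-15.0,
                           systolic_peak_strain_pct=-8.0, psi_pct=46.7)
    res = score_and_classify(m, rubric)
    assert res.sps_shortcut
    assert res.points_sps == 4
    assert res.points_onset == res.points_psi == 0
    assert res.points_total == 4
    assert res.pattern_type == "III"


def test_sps_shortcut_boundary_is_inclusive_at_minus_10(rubric):
    m = DeformationMetrics(0.0, -20.0, -10.0, 50.0)
    assert score_and_classify(m, rubric).sps_shortcut
    m = DeformationMetrics(0.0, -20.0, -10.001, 49.995)
    assert not score_and_classify(m, rubric).sps_shortcut


def test_totals_4_to_6_map_to_type_III(rubric):
    # without the shortcut: late onset (2) + high PSI (2) + reduced SPS (1)
    m = DeformationMetrics(200.0, -30.0, -16.0, 46.7)
    res = score_and_classify(m, rubric)
    assert res.points_total >= 4
    assert res.pattern_type == "III"
    assert not res.sps_shortcut


def test_normal_curve_scores_type_I(rubric):
    m = DeformationMetrics(50.0, -28.0, -27.0, postsystolic_index(-28.0, -27.0))
    res = score_and_classify(m, rubric)
    assert res.points_total == 0
    assert res.pattern_type == "I"


@given(
    onset=st.floats(0.0, 400.0),
    sps=st.floats(-35.0, -10.5),
    psi=st.floats(0.0, 90.0),
    worsen=st.sampled_from(["onset", "psi", "sps"]),
    delta=st.floats(0.1, 60.0),
)
@settings(max_examples=200, deadline=None)
def test_scoring_is_monotone_in_each_parameter(onset, sps, psi, worsen, delta):
    """Worsening one parameter (later onset, higher PSI, higher SPS) never
    decreases the points total away from the shortcut transition, and never
    improves the pattern type anywhere (the fixed 4-point shortcut score can
    undercut a 5-6 point total, but both are type III)."""
    rubric = ScoringRubric.default()
    rank = {"I": 0, "II": 1, "III": 2}

    def classify(o, s, p):
        ps = min(s / (1.0 - min(p, 99.0) / 100.0), s)
        return score_and_classify(DeformationMetrics(o, ps, s, p), rubric)

    base = classify(onset, sps, psi)
    if worsen == "onset":
        worse = classify(onset + delta, sps, psi)
    elif worsen == "psi":
        worse = classify(onset, sps, psi + delta)
    else:
        worse = classify(onset, min(sps + delta, -0.1), psi)
    if not (base.sps_shortcut or worse.sps_shortcut):
        assert worse.points_total >= base.points_total
    assert rank[worse.pattern_type] >= rank[base.pattern_type]


def test_rubric_rejects_noncovering_bands():
    raw = {
        "onset_ms": [{"upper": 110, "points": 0}],  # not unbounded
        "psi_pct": [{"upper": ".inf", "points": 0}],
        "sps_pct": [{"upper": ".inf", "points": 0}],
        "type_bands": [{"max_points": 6, "type": "I"}],
    }
    with pytest.raises(errors.RubricError):
        ScoringRubric.from_mapping(raw)


def test_rubric_roundtrip_from_file(tmp_path, rubric):
    import yaml

    path = tmp_path / "rubric.yaml"
    raw = {
        "onset_ms": [{"upper": u, "points": p} for u, p in rubric.onset_bands],
        "psi_pct": [{"upper": u, "points": p} for u, p in rubric.psi_bands],
        "sps_pct": [{"upper": u, "points": p} for u, p in rubric.sps_bands],
        "sps_shortcut_threshold_pct": rubric.sps_shortcut_threshold_pct,
        "type_bands": [{"max_points": m, "type": t} for m, t in rubric.type_bands],
    }
    path.write_text(yaml.safe_dump(raw))
    loaded = ScoringRubric.from_file(path)
    assert loaded.onset_bands == rubric.onset_bands
    assert loaded.type_bands == rubric.type_bands


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_analyze_curve_type_I_synthetic():
    spec = SyntheticSpec.from_extrema("I", 60.0, -28.0, -28.5,
                                      prestretch_amp_pct=1.0)
    metrics, result = analyze_curve(generate_curve(spec))
    assert result.pattern_type == "I"
    assert metrics.peak_strain_pct == pytest.approx(-28.5, abs=0.5)


def test_analyze_curve_shortcut_overrides_other_parameters():
    # early onset and tiny PSI, but SPS = -9: still type III
    spec = SyntheticSpec.from_extrema("III", 40.0, -9.0, -9.2,
                                      prestretch_amp_pct=0.5)
    _, result = analyze_curve(generate_curve(spec))
    assert result.pattern_type == "III"
    assert result.sps_shortcut


def test_shortcut_consistency_on_random_curves(rng):
    """SPS >= -10% forces type III regardless of every other parameter."""
    for i in range(100):
        spec = random_spec(["I", "II", "III"][i % 3], rng,
                           noise_sd_pct=float(rng.uniform(0, 0.3)))
        metrics, result = analyze_curve(generate_curve(spec))
        assert metrics.peak_strain_pct <= metrics.systolic_peak_strain_pct
        if metrics.peak_strain_pct < 0:
            assert metrics.psi_pct >= 0.0
        if metrics.systolic_peak_strain_pct >= -10.0:
            assert result.pattern_type == "III"
            assert result.sps_shortcut
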