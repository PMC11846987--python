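"""Metric suite versus independent brute-force references and geometry laws."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from esokin import (
    DegenerateGeometryError,
    DegenerateInputError,
    PreprocessConfig,
    count_zero_crossings,
    cumulative_distance,
    fit_confidence_ellipse,
    genre_preset,
    global_magnitude,
    rms,
    segment_ratios,
    simulate_session,
    summarize_one,
    summarize_session,
)
from esokin.preprocess import preprocess_sensor

CHI2_2_95 = 5.991464547107979  # chi-square 0.95 quantile, 2 df


# ---------------------------------------------------------------- references
def brute_rms(x):
    total = 0.0
    for v in x:
        total += v * v
    return math.sqrt(total / len(x))


def brute_magnitude(x, y, z, euclidean=False):
    out = []
    for a, b, c in zip(x, y, z):
        if euclidean:
            out.append(math.sqrt(a * a + b * b + c * c))
        else:
            out.append(abs(a) + abs(b) + abs(c))
    return np.array(out)


def brute_zero_crossings(axes, deadband=0.0):
    total = 0
    for v in axes:
        prev = 0.0
        for s in v:
            s = 0.0 if abs(s) <= deadband else math.copysign(1.0, s)
            if s != 0.0:
                if prev != 0.0 and s != prev:
                    total += 1
                prev = s
    return total


def brute_cumulative_distance(d):
    total = 0.0
    for i in range(len(d) - 1):
        total += abs(d[i + 1] - d[i])
    return total


def brute_ellipse(points, coverage=0.95):
    """Covariance by explicit loops + closed-form 2x2 eigenvalues."""
    n = len(points)
    mx = sum(p[0] for p in points) / n
    my = sum(p[1] for p in points) / n
    sxx = sum((p[0] - mx) ** 2 for p in points) / (n - 1)
    syy = sum((p[1] - my) ** 2 for p in points) / (n - 1)
    sxy = sum((p[0] - mx) * (p[1] - my) for p in points) / (n - 1)
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    q = CHI2_2_95
    a, b = math.sqrt(q * lam1), math.sqrt(q * lam2)
    return a, b, math.pi * a * b, a / b


# ------------------------------------------------------------------ examples
def test_global_magnitude_examples():
    assert global_magnitude([3.0], [4.0], [0.0])[0] == 7.0
    assert global_magnitude([3.0], [4.0], [0.0], "euclidean")[0] == 5.0
    assert global_magnitude([0.0], [0.0], [0.0])[0] == 0.0
    assert global_magnitude([-1.0], [-1.0], [-1.0])[0] == 3.0


def test_rms_of_constant_and_sine():
    assert rms(np.full(100, -3.0)) == 3.0
    t = np.arange(5000) / 500.0
    assert rms(np.sin(2 * np.pi * 3.0 * t)) == pytest.approx(1 / np.sqrt(2),
                                                             abs=1e-3)


def test_segment_ratios_examples():
    assert segment_ratios(2, 1, 0.5) == (2, 2)
    assert segment_ratios(1, 1, 1) == (1, 1)
    assert segment_ratios(1, 2, 4) == (0.5, 0.5)
    with pytest.raises(DegenerateInputError):
        segment_ratios(1.0, 0.0, 1.0)


def test_zero_crossing_examples():
    ones = np.ones(4)
    assert count_zero_crossings([1, -1, 1, -1], ones, ones) == 3
    assert count_zero_crossings(ones, ones, ones) == 0
    # exact zeros carry the previous sign: touching zero is not a crossing
    assert count_zero_crossings([1, 0, 1], [1] * 3, [1] * 3) == 0
    assert count_zero_crossings([1, 0, -1], [1] * 3, [1] * 3) == 1


def test_zero_crossing_sine_matches_brute_force():
    t = np.arange(5000) / 500.0
    v = np.sin(2 * np.pi * 1.0 * t + 0.1)
    ones = np.ones_like(v)
    assert count_zero_crossings(v, ones, ones) == \
        brute_zero_crossings([v, ones, ones])


def test_cumulative_distance_examples():
    assert cumulative_distance([0, 0.1, 0.3, 0.2]) == pytest.approx(0.4)
    ramp = np.linspace(0, 2.5, 100)
    assert cumulative_distance(ramp) == pytest.approx(2.5)


def test_metrics_match_brute_force_on_random_traces(rng):
    x, y, z = rng.normal(size=(3, 100))
    np.testing.assert_allclose(global_magnitude(x, y, z),
                               brute_magnitude(x, y, z), rtol=1e-9)
    np.testing.assert_allclose(global_magnitude(x, y, z, "euclidean"),
                               brute_magnitude(x, y, z, True), rtol=1e-9)
    assert rms(x) == pytest.approx(brute_rms(x), rel=1e-9)
    assert count_zero_crossings(x, y, z) == brute_zero_crossings([x, y, z])
    mag = global_magnitude(x, y, z)
    assert cumulative_distance(mag) == pytest.approx(
        brute_cumulative_distance(mag), rel=1e-9)
    pts = rng.normal(size=(100, 2))
    fit = fit_confidence_ellipse(pts)
    a, b, area, ratio = brute_ellipse(pts.tolist())
    assert fit.a == pytest.approx(a, rel=1e-9)
    assert fit.b == pytest.approx(b, rel=1e-9)
    assert fit.area_cm2 == pytest.approx(area, rel=1e-9)
    assert fit.long_short_ratio == pytest.approx(ratio, rel=1e-9)


# ------------------------------------------------------------------- ellipse
def test_ellipse_isotropic_gaussian_area(rng):
    pts = rng.normal(0.0, 1.0, size=(100_000, 2))
    fit = fit_confidence_ellipse(pts)
    assert fit.area_cm2 == pytest.approx(np.pi * CHI2_2_95, rel=0.02)
    assert fit.long_short_ratio == pytest.approx(1.0, rel=0.02)
    assert fit.area_cm2 == pytest.approx(np.pi * fit.a * fit.b, rel=1e-9)


def test_ellipse_recovers_diagonal_covariance_ratio(rng):
    pts = rng.normal(0.0, [2.0, 1.0], size=(100_000, 2))
    fit = fit_confidence_ellipse(pts)
    assert fit.long_short_ratio == pytest.approx(2.0, rel=0.02)
    angle = abs(fit.orientation_rad) % np.pi  # long axis is the x axis
    assert min(angle, np.pi - angle) < 0.05


def test_ellipse_collinear_points_degenerate():
    pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    with pytest.raises(DegenerateGeometryError):
        fit_confidence_ellipse(pts)


def test_ellipse_coverage_is_respected(rng):
    # ~95% of Gaussian points fall inside the fitted 95% ellipse
    pts = rng.multivariate_normal([1.0, -2.0], [[3.0, 1.0], [1.0, 2.0]],
                                  size=50_000)
    fit = fit_confidence_ellipse(pts)
    c = np.cov(pts, rowvar=False)
    centered = pts - pts.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(c), centered)
    assert np.mean(d2 <= CHI2_2_95) == pytest.approx(0.95, abs=0.005)


# --------------------------------------------------------------- properties
finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@given(hnp.arrays(np.float64, (30, 2), elements=finite_floats),
       st.floats(0.1, 100.0))
def test_ellipse_scale_equivariance(pts, s):
    try:
        base = fit_confidence_ellipse(pts)
    except DegenerateGeometryError:
        return
    scaled = fit_confidence_ellipse(pts * s)
    assert scaled.a == pytest.approx(s * base.a, rel=1e-9)
    assert scaled.b == pytest.approx(s * base.b, rel=1e-9)
    assert scaled.area_cm2 == pytest.approx(s**2 * base.area_cm2, rel=1e-9)
    assert scaled.long_short_ratio == pytest.approx(base.long_short_ratio,
                                                    rel=1e-9)


@given(hnp.arrays(np.float64, (30, 2), elements=st.floats(-100, 100)),
       st.floats(0.0, 2 * np.pi))
def test_ellipse_rotation_invariance(pts, theta):
    try:
        base = fit_confidence_ellipse(pts)
    except DegenerateGeometryError:
        return
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    rotated = fit_confidence_ellipse(pts @ rot.T)
    assert rotated.area_cm2 == pytest.approx(base.area_cm2, rel=1e-9)
    assert rotated.long_short_ratio == pytest.approx(base.long_short_ratio,
                                                     rel=1e-9)


@given(hnp.arrays(np.float64, (3, 50), elements=finite_floats))
def test_l1_magnitude_dominates_l2(xyz):
    l1 = global_magnitude(*xyz)
    l2 = global_magnitude(*xyz, "euclidean")
    assert np.all(l1 >= l2 - 1e-12 * np.maximum(np.abs(l1), 1.0))


@given(hnp.arrays(np.float64, st.integers(2, 60), elements=finite_floats))
def test_cumulative_distance_reversal_and_concatenation(d):
    cd = cumulative_distance(d)
    assert cumulative_distance(d[::-1]) == pytest.approx(cd, rel=1e-12,
                                                         abs=1e-12)
    if len(d) >= 4:
        k = len(d) // 2
        left, right = d[: k + 1], d[k:]  # shared endpoint
        assert cumulative_distance(left) + cumulative_distance(right) == \
            pytest.approx(cd, rel=1e-12, abs=1e-12)


# ----------------------------------------------------------------- summary
def test_motionless_session_is_flagged_not_fatal():
    spec = genre_preset("FPS", seed=0, duration_s=30)
    spec.event_rate_hz = 0.0
    spec.noise_sd_mg = 0.0
    spec.outlier_rate = 0.0
    session, _ = simulate_session(spec)
    cfg = PreprocessConfig()
    processed = {r.placement: preprocess_sensor(r, cfg)
                 for r in session.recordings}
    summary = summarize_session(processed["hand"], processed["forearm"],
                                processed["arm"], cfg)
    assert summary.hand_rms < 0.01
    assert summary.cumulative_distance_m < 0.01
    assert summary.ellipse is None
    assert "degenerate-ellipse" in summary.flags


def test_isotropic_movement_gives_circular_footprint():
    # the fitted axis ratio is >= 1 by construction, with an upward
    # small-sample fluctuation of a few percent per session; pooling the
    # displacement clouds of several sessions isolates the generative shape
    clouds = []
    for seed in range(24):
        spec = genre_preset("MOBA", seed=seed, duration_s=300)
        spec.spatial_cov_cm2 = np.eye(2) * 4.0
        session, _ = simulate_session(spec)
        cfg = PreprocessConfig()
        hand = preprocess_sensor(session.hand, cfg)
        clouds.append(np.column_stack([hand.disp_x.samples,
                                       hand.disp_y.samples]) * 100.0)
    fit = fit_confidence_ellipse(np.vstack(clouds))
    assert fit.long_short_ratio == pytest.approx(1.0, rel=0.05)


def test_identical_sessions_identical_summaries():
    spec = genre_preset("FPS", seed=9, duration_s=30)
    s1, _ = simulate_session(spec)
    s2, _ = simulate_session(spec)
    r1 = summarize_one(s1)[0]
    r2 = summarize_one(s2)[0]
    assert r1.as_row() == r2.as_row()
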