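import numpy as np
import pytest

from mlcsens import (MLCGeometry, aperture_geometry, aperture_irregularity,
                     mu_per_gy, plan_irregularity)
from mlcsens.plans import ControlPoint

from _oracles import rasterize_aperture
from conftest import plan_from_apertures, uniform_aperture


def _cp(x1, x2, boundaries, jaw_x=(-200.0, 200.0), jaw_y=(-200.0, 200.0)):
    return ControlPoint(0, 0.0, 0.0, np.asarray(x1, float),
                        np.asarray(x2, float), jaw_x, jaw_y)


def _geometry(n_pairs, width=5.0, min_gap=0.5):
    return MLCGeometry.default(n_pairs, width, min_gap)


def test_mu_per_gy_definition():
    plan = plan_from_apertures([uniform_aperture(10, -5, 5)] * 2, n_pairs=10,
                               beam_mu=500.0, dose_per_fraction_gy=2.0)
    assert mu_per_gy(plan) == pytest.approx(250.0)
    hypo = plan_from_apertures([uniform_aperture(10, -5, 5)] * 2, n_pairs=10,
                               beam_mu=1450.0, dose_per_fraction_gy=7.25,
                               n_fractions=5)
    assert mu_per_gy(hypo) == pytest.approx(200.0)
    doubled = plan_from_apertures([uniform_aperture(10, -5, 5)] * 2, n_pairs=10,
                                  beam_mu=1000.0, dose_per_fraction_gy=2.0)
    assert mu_per_gy(doubled) == pytest.approx(2 * mu_per_gy(plan))


def test_square_and_rectangle_apertures():
    geom = _geometry(4)
    # two adjacent 5 mm strips open (-5, 5): a 10 x 10 square
    cp = _cp([0, -5, -5, 0], [0, 5, 5, 0], geom.leaf_boundaries_mm)
    ag = aperture_geometry(cp, geom)
    assert ag.area_mm2 == pytest.approx(100.0)
    assert ag.perimeter_mm == pytest.approx(40.0)
    assert ag.n_subapertures == 1
    assert aperture_irregularity(ag) == pytest.approx(4.0 / np.pi, rel=1e-12)

    # one strip open (-5, 5): 10 x 5 rectangle
    cp = _cp([0, -5, 0, 0], [0, 5, 0, 0], geom.leaf_boundaries_mm)
    ag = aperture_geometry(cp, geom)
    assert ag.area_mm2 == pytest.approx(50.0)
    assert ag.perimeter_mm == pytest.approx(30.0)

    # one strip open (-10, 10): 20 x 5 rectangle, AI = 2500/(400 pi)
    cp = _cp([0, -10, 0, 0], [0, 10, 0, 0], geom.leaf_boundaries_mm)
    ag = aperture_geometry(cp, geom)
    assert aperture_irregularity(ag) == pytest.approx(
        50.0 ** 2 / (4 * np.pi * 100.0), rel=1e-12)


def test_disconnected_subapertures_summed():
    geom = _geometry(5)
    x1 = [-5, 0, 0, 0, -5]
    x2 = [5, 0, 0, 0, 5]
    ag = aperture_geometry(_cp(x1, x2, geom.leaf_boundaries_mm), geom)
    assert ag.n_subapertures == 2
    assert ag.area_mm2 == pytest.approx(100.0)
    assert ag.perimeter_mm == pytest.approx(60.0)


def test_jaw_truncation_applies_before_geometry():
    geom = _geometry(2)  # strips [-5,0) and [0,5)
    cp = _cp([-10, -10], [10, 10], geom.leaf_boundaries_mm,
             jaw_x=(-5.0, 5.0), jaw_y=(-5.0, 2.5))
    ag = aperture_geometry(cp, geom)
    assert ag.area_mm2 == pytest.approx(10.0 * 7.5)
    assert ag.perimeter_mm == pytest.approx(2 * (10.0 + 7.5))


def test_ai_invariant_to_translation_and_scale():
    geom = _geometry(6)
    rng = np.random.default_rng(1)
    lo = np.sort(rng.uniform(-40, 0, 6))
    hi = lo + rng.uniform(5, 30, 6)
    base = aperture_geometry(_cp(lo, hi, geom.leaf_boundaries_mm), geom)
    shifted = aperture_geometry(_cp(lo + 17.0, hi + 17.0,
                                    geom.leaf_boundaries_mm), geom)
    assert aperture_irregularity(shifted) == \
        pytest.approx(aperture_irregularity(base), rel=1e-12)
    # uniform 2x scaling of the aperture (strip widths double too)
    big = MLCGeometry.default(6, 10.0)
    scaled = aperture_geometry(_cp(2 * lo, 2 * hi, big.leaf_boundaries_mm), big)
    assert aperture_irregularity(scaled) == \
        pytest.approx(aperture_irregularity(base), rel=1e-12)


def test_isoperimetric_lower_bound_random_apertures():
    geom = _geometry(20)
    rng = np.random.default_rng(8)
    for _ in range(50):
        lo = rng.uniform(-45, 30, 20)
        hi = lo + rng.uniform(1, 25, 20)
        closed = rng.random(20) < 0.3
        lo[closed] = hi[closed] = 0.0
        ag = aperture_geometry(_cp(lo, hi, geom.leaf_boundaries_mm), geom)
        if ag.area_mm2 > 0:
            assert aperture_irregularity(ag) >= 4.0 / np.pi - 1e-12


def test_area_perimeter_match_rasterization_oracle():
    """Random 20-strip apertures against a 0.1-mm pixel-count oracle."""
    geom = _geometry(20)
    rng = np.random.default_rng(17)
    for i in range(30):
        lo = np.round(rng.uniform(-45, 25, 20), 1)
        hi = np.round(lo + rng.uniform(2, 25, 20), 1)
        closed = rng.random(20) < 0.25
        lo[closed] = hi[closed] = 0.0
        jaw_x = (-60.0, 60.0)
        jaw_y = (-60.0, 60.0) if i % 2 else (-32.5, 37.5)
        cp = _cp(lo, hi, geom.leaf_boundaries_mm, jaw_x=jaw_x, jaw_y=jaw_y)
        ag = aperture_geometry(cp, geom)
        if ag.area_mm2 == 0:
            continue
        area_o, perim_o = rasterize_aperture(lo, hi, geom.leaf_boundaries_mm,
                                             jaw_x, jaw_y)
        assert ag.area_mm2 == pytest.approx(area_o, rel=0.01)
        assert ag.perimeter_mm == pytest.approx(perim_o, rel=0.01)


def test_plan_irregularity_is_mu_weighted_mean():
    geom_rows = 4
    square = uniform_aperture(geom_rows, -5.0, 5.0, open_rows=[1, 2])
    rect = uniform_aperture(geom_rows, -10.0, 10.0, open_rows=[1])
    ai_square = 4.0 / np.pi
    ai_rect = 50.0 ** 2 / (4 * np.pi * 100.0)

    # constant aperture: PI equals its AI for any meterset pattern
    plan = plan_from_apertures([square] * 4, n_pairs=geom_rows,
                               weights=[0.0, 0.7, 0.9, 1.0])
    assert plan_irregularity(plan).pi == pytest.approx(ai_square, rel=1e-12)

    # two equal-MU segments -> arithmetic mean of the two AIs
    plan = plan_from_apertures([square, rect, rect], n_pairs=geom_rows,
                               weights=[0.0, 0.5, 1.0])
    assert plan_irregularity(plan).pi == \
        pytest.approx(0.5 * (ai_square + ai_rect), rel=1e-12)

    # shifting MU toward the irregular segment raises PI
    skewed = plan_from_apertures([square, rect, rect], n_pairs=geom_rows,
                                 weights=[0.0, 0.2, 1.0])
    assert plan_irregularity(skewed).pi > plan_irregularity(plan).pi

    # PI invariant under uniform MU rescaling
    rescaled = plan_from_apertures([square, rect, rect], n_pairs=geom_rows,
                                   beam_mu=731.0, weights=[0.0, 0.5, 1.0])
    assert plan_irregularity(rescaled).pi == \
        pytest.approx(plan_irregularity(plan).pi, rel=1e-12)


def test_closed_plan_rejected():
    n = 4
    closed = uniform_aperture(n, 0.0, 0.0, open_rows=[])
    plan = plan_from_apertures([closed] * 2, n_pairs=n)
    with pytest.raises(ValueError, match="open"):
        plan_irregularity(plan)
    ag = aperture_geometry(plan.beams[0].control_points[0],
                           plan.beams[0].geometry)
    assert ag.area_mm2 == 0 and ag.perimeter_mm == 0
    with pytest.raises(ValueError):
        aperture_irregularity(ag)
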