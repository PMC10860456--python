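import numpy as np
import pytest
from hypothesis import given, strategies as st

from mlcsens import ErrorSpec, apply_random, apply_systematic, build_error_set
from mlcsens.errors import STUDY_MAGNITUDES_MM

from conftest import plan_from_apertures, uniform_aperture


def _wide_plan(n_pairs=10, x1=-20.0, x2=20.0, min_gap=0.5, n_cp=3):
    ap = [uniform_aperture(n_pairs, x1, x2) for _ in range(n_cp)]
    return plan_from_apertures(ap, n_pairs=n_pairs, min_gap_mm=min_gap)


@pytest.mark.parametrize("mode,sign", [("systematic_close", -1),
                                       ("systematic_open", +1)])
@pytest.mark.parametrize("delta", STUDY_MAGNITUDES_MM)
def test_systematic_gap_change_is_twice_delta(mode, sign, delta):
    plan = _wide_plan()
    res = apply_systematic(plan, ErrorSpec(mode, delta))
    assert not res.clamps
    for cp_ref, cp_err in zip(plan.beams[0].control_points,
                              res.plan.beams[0].control_points):
        gap_ref = cp_ref.x2_mm - cp_ref.x1_mm
        gap_err = cp_err.x2_mm - cp_err.x1_mm
        np.testing.assert_allclose(gap_err - gap_ref, sign * 2 * delta)
        # jaws untouched
        assert cp_err.jaw_x_mm == cp_ref.jaw_x_mm


def test_close_example_and_clamp_rule():
    """Pair (-10, 10) closed by 2 mm becomes (-8, 8); pair (-1, 1) closed by
    2 mm with min_gap 0 collapses to (0, 0) and is logged."""
    plan = _wide_plan(n_pairs=4, x1=-10, x2=10, min_gap=0.0, n_cp=2)
    plan.beams[0].control_points[0].x1_mm[1] = -1.0
    plan.beams[0].control_points[0].x2_mm[1] = 1.0
    res = apply_systematic(plan, ErrorSpec("systematic_close", 2.0))
    cp = res.plan.beams[0].control_points[0]
    assert cp.x1_mm[0] == pytest.approx(-8.0)
    assert cp.x2_mm[0] == pytest.approx(8.0)
    assert cp.x1_mm[1] == pytest.approx(0.0)
    assert cp.x2_mm[1] == pytest.approx(0.0)
    assert (0, 0, 1) == (res.clamps[0].beam_index, res.clamps[0].cp_index,
                         res.clamps[0].leaf_index)


def test_open_then_close_recovers_plan():
    plan = _wide_plan()
    opened = apply_systematic(plan, ErrorSpec("systematic_open", 1.5)).plan
    back = apply_systematic(opened, ErrorSpec("systematic_close", 1.5))
    assert not back.clamps
    for cp_ref, cp_err in zip(plan.beams[0].control_points,
                              back.plan.beams[0].control_points):
        np.testing.assert_allclose(cp_err.x1_mm, cp_ref.x1_mm, atol=1e-12)
        np.testing.assert_allclose(cp_err.x2_mm, cp_ref.x2_mm, atol=1e-12)


def test_close_composition_adds_deltas():
    plan = _wide_plan()
    two_step = apply_systematic(
        apply_systematic(plan, ErrorSpec("systematic_close", 0.75)).plan,
        ErrorSpec("systematic_close", 0.5)).plan
    one_step = apply_systematic(plan, ErrorSpec("systematic_close", 1.25)).plan
    for a, b in zip(two_step.beams[0].control_points,
                    one_step.beams[0].control_points):
        np.testing.assert_allclose(a.x1_mm, b.x1_mm, atol=1e-12)
        np.testing.assert_allclose(a.x2_mm, b.x2_mm, atol=1e-12)


def test_input_plan_not_mutated():
    plan = _wide_plan()
    before = [cp.x1_mm.copy() for cp in plan.beams[0].control_points]
    apply_systematic(plan, ErrorSpec("systematic_close", 2.0))
    apply_random(plan, ErrorSpec("random", 1.0, seed=1))
    for cp, x1 in zip(plan.beams[0].control_points, before):
        np.testing.assert_array_equal(cp.x1_mm, x1)


def test_random_displacement_sample_sd():
    """Pooled displacement SD within 5% of sigma at n = 10^4, mean near 0."""
    sigma = 1.0
    n_pairs, n_cp = 50, 100  # 2 banks x 50 x 100 = 10^4 displacements
    plan = _wide_plan(n_pairs=n_pairs, n_cp=n_cp)
    res = apply_random(plan, ErrorSpec("random", sigma, seed=11))
    assert not res.clamps
    disp = []
    for cp_ref, cp_err in zip(plan.beams[0].control_points,
                              res.plan.beams[0].control_points):
        disp.append(cp_err.x1_mm - cp_ref.x1_mm)
        disp.append(cp_err.x2_mm - cp_ref.x2_mm)
    disp = np.concatenate(disp)
    assert disp.size == 10_000
    assert np.std(disp) == pytest.approx(sigma, rel=0.05)
    assert abs(disp.mean()) < 3 * sigma / np.sqrt(disp.size)


def test_random_mode_deterministic_and_needs_seed():
    plan = _wide_plan()
    a = apply_random(plan, ErrorSpec("random", 0.5, seed=3)).plan
    b = apply_random(plan, ErrorSpec("random", 0.5, seed=3)).plan
    for cp_a, cp_b in zip(a.beams[0].control_points, b.beams[0].control_points):
        np.testing.assert_array_equal(cp_a.x1_mm, cp_b.x1_mm)
    with pytest.raises(ValueError, match="seed"):
        apply_random(plan, ErrorSpec("random", 0.5))


def test_small_random_error_never_clamps_wide_gaps():
    """sigma = 0.25 mm on gaps >= 10 mm: no clamp at the fixed test seed."""
    plan = _wide_plan(n_pairs=40, x1=-5.0, x2=5.0, n_cp=20)
    res = apply_random(plan, ErrorSpec("random", 0.25, seed=99))
    assert res.clamps == []


@given(mag=st.floats(0.1, 5.0), seed=st.integers(0, 2**16),
       mode=st.sampled_from(["systematic_close", "systematic_open", "random"]))
def test_no_operation_emits_crossed_leaves(mag, seed, mode):
    plan = _wide_plan(n_pairs=6, x1=-3.0, x2=3.0)
    spec = ErrorSpec(mode, mag, seed=seed if mode == "random" else None)
    res = apply_random(plan, spec) if mode == "random" \
        else apply_systematic(plan, spec)
    for cp in res.plan.beams[0].control_points:
        assert np.all(cp.x1_mm <= cp.x2_mm + 1e-12)


def test_error_set_cross_product_counts():
    plans = list(range(640))  # the builder only pairs, it never applies
    sys_set = build_error_set(plans, STUDY_MAGNITUDES_MM,
                              ["systematic_close", "systematic_open"])
    assert len(sys_set) == 5120
    assert len(build_error_set(plans[:1], [1.0], ["systematic_close"])) == 1
    rand = build_error_set(list(range(160)), STUDY_MAGNITUDES_MM, ["random"],
                           n_replicates=2, base_seed=1)
    assert len(rand) == 1280
    seeds = [spec.seed for _, spec in rand]
    assert len(set(seeds)) == len(seeds)  # distinct reproducible seeds
    with pytest.raises(ValueError, match="grid"):
        build_error_set(plans[:1], [], ["random"])


def test_error_spec_validation():
    with pytest.raises(ValueError):
        ErrorSpec("sideways", 1.0)
    with pytest.raises(ValueError):
        ErrorSpec("random", 0.0)
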