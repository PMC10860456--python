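import numpy as np
import pytest
from scipy.stats import spearmanr

from mlcsens import (CohortDesign, default_templates, enumerate_cohort,
                     make_phantom, make_plan, mu_per_gy, plan_irregularity)
from mlcsens.cohort import sweep_cohort
from mlcsens.dose import bev_coords


def test_phantom_is_deterministic(templates):
    a = make_phantom(templates["prostate"], 7)
    b = make_phantom(templates["prostate"], 7)
    for name in a.masks:
        np.testing.assert_array_equal(a.masks[name], b.masks[name])
    c = make_phantom(templates["prostate"], 8)
    assert any(not np.array_equal(a.masks[n], c.masks[n]) for n in a.masks)


def test_sphere_target_volume_matches_analytic(templates):
    """Voxelized 30 mm sphere at 2 mm spacing within 10% of (4/3) pi 15^3."""
    from dataclasses import replace
    tpl = replace(templates["brain_met"], target_size_mm=(30.0, 30.0))
    vol_analytic = 4.0 / 3.0 * np.pi * 15.0 ** 3
    for seed in range(5):
        ph = make_phantom(tpl, seed)
        vol_vox = ph.masks["target"].sum() * ph.spacing_mm ** 3
        assert vol_vox == pytest.approx(vol_analytic, rel=0.10)


def test_prostate_template_layout(templates):
    """Rectum posterior of the target, bladder anterior-superior."""
    ph = make_phantom(templates["prostate"], 1)
    _, ty, tz = ph.structure_coords("target")
    _, ry, _ = ph.structure_coords("rectum")
    _, by, bz = ph.structure_coords("bladder")
    assert ry.mean() > ty.mean() + 10
    assert by.mean() < ty.mean() - 10
    assert bz.mean() > tz.mean() + 5


def test_spine_target_wraps_cord(templates):
    """Concave spinal target: disjoint from the cord and surrounding it."""
    ph = make_phantom(templates["spine_met"], 2)
    target, cord = ph.masks["target"], ph.masks["spinal_cord"]
    assert not (target & cord).any()
    tx, ty, _ = ph.structure_coords("target")
    # target voxels on at least 3 of the 4 sides of the cord axis
    sides = [(tx > 8).any(), (tx < -8).any(), (ty > 8).any(), (ty < -8).any()]
    assert sum(sides) >= 3


def test_plan_generation_deterministic(templates):
    tpl = templates["lung"]
    ph = make_phantom(tpl, 3)
    p1 = make_plan(tpl, ph, 0.6, case_seed=3, n_control_points=24)
    p2 = make_plan(tpl, ph, 0.6, case_seed=3, n_control_points=24)
    for a, b in zip(p1.beams[0].control_points, p2.beams[0].control_points):
        np.testing.assert_array_equal(a.x1_mm, b.x1_mm)
        np.testing.assert_array_equal(a.x2_mm, b.x2_mm)
        assert a.cum_weight == b.cum_weight
    assert p1.total_mu() == p2.total_mu()


def test_zero_modulation_apertures_conform_to_target(templates):
    """At modulation 0 the aperture is the target outline plus margin: every
    target voxel projects inside every control point's opening, and raising
    modulation only narrows the gaps."""
    tpl = templates["prostate"]
    ph = make_phantom(tpl, 4)
    plan0 = make_plan(tpl, ph, 0.0, case_seed=4, n_control_points=16)
    plan9 = make_plan(tpl, ph, 0.9, case_seed=4, n_control_points=16)
    tX, tY, tZ = ph.structure_coords("target")
    geom = plan0.beams[0].geometry
    b = geom.leaf_boundaries_mm
    for cp0, cp9 in zip(plan0.beams[0].control_points,
                        plan9.beams[0].control_points):
        u = bev_coords(tX, tY, cp0.gantry_deg)
        for k in range(geom.n_pairs):
            sel = (tZ >= b[k]) & (tZ < b[k + 1])
            if not sel.any():
                continue
            assert cp0.x1_mm[k] <= u[sel].min()
            assert cp0.x2_mm[k] >= u[sel].max()
            # narrower at high modulation (on average this strip is open)
            assert cp9.x2_mm[k] - cp9.x1_mm[k] <= cp0.x2_mm[k] - cp0.x1_mm[k] + 1e-9
    assert mu_per_gy(plan0) < mu_per_gy(plan9)


def test_modulation_raises_complexity(templates):
    """PI and MU/Gy both increase from modulation 0.1 to 0.9 at fixed seed."""
    for site in ("prostate", "lung", "brain_met", "spine_met"):
        tpl = templates[site]
        ph = make_phantom(tpl, 11)
        lo = make_plan(tpl, ph, 0.1, case_seed=11)
        hi = make_plan(tpl, ph, 0.9, case_seed=11)
        assert plan_irregularity(hi).pi > plan_irregularity(lo).pi
        assert mu_per_gy(hi) > 3.0 * mu_per_gy(lo) * 0.9  # ~>= 3x span


def test_modulation_complexity_spearman_within_site(templates):
    """Within a site, modulation rank-orders both MU/Gy and PI (> 0.8)."""
    for site in ("lung", "spine_met"):
        specs = sweep_cohort((site,), np.linspace(0.1, 0.9, 9), base_seed=31)
        mods, mus, pis = [], [], []
        for s in specs:
            tpl = default_templates()[s.site]
            ph = make_phantom(tpl, s.case_seed)
            plan = make_plan(tpl, ph, s.modulation, case_seed=s.case_seed,
                             n_control_points=45)
            mods.append(s.modulation)
            mus.append(mu_per_gy(plan))
            pis.append(plan_irregularity(plan).pi)
        assert spearmanr(mods, mus).statistic > 0.8
        assert spearmanr(mods, pis).statistic > 0.8


def test_site_ordering_of_plan_irregularity(templates):
    """At matched modulation the spinal template is the most irregular and
    the brain-metastasis template the least."""
    means = {}
    for site in ("spine_met", "lung", "prostate", "brain_met"):
        tpl = templates[site]
        vals = [plan_irregularity(
            make_plan(tpl, make_phantom(tpl, seed), 0.5, case_seed=seed,
                      n_control_points=45)).pi for seed in range(3)]
        means[site] = np.mean(vals)
    assert means["spine_met"] > means["lung"] > means["prostate"] > means["brain_met"]


def test_cohort_enumeration_counts():
    paper_shaped = CohortDesign(n_cases=20, base_seed=0)
    specs = enumerate_cohort(paper_shaped)
    assert len(specs) == 640
    assert paper_shaped.n_plans == 640
    single = CohortDesign(sites=("lung",), tps_profiles=("jaw_tracking",),
                          fractionations=("standard",), beam_types=("FF",),
                          n_cases=1)
    assert len(enumerate_cohort(single)) == 1
    empty = CohortDesign(n_cases=0)
    assert enumerate_cohort(empty) == []


def test_cohort_enumeration_is_pure():
    d = CohortDesign(n_cases=2, base_seed=99)
    a, b = enumerate_cohort(d), enumerate_cohort(d)
    assert a == b
    c = enumerate_cohort(CohortDesign(n_cases=2, base_seed=100))
    assert [s.case_seed for s in a] != [s.case_seed for s in c]


def test_modulation_knob_validated(templates):
    tpl = templates["lung"]
    ph = make_phantom(tpl, 0)
    with pytest.raises(ValueError, match="modulation"):
        make_plan(tpl, ph, 1.5, case_seed=0)
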