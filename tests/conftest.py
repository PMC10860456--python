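import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from mlcsens import (CohortDesign, EngineConfig, MLCGeometry, Plan,  # noqa: E402
                     Prescription, StudyConfig, default_templates, run_study,
                     sweep_cohort)
from mlcsens.plans import Beam, ControlPoint  # noqa: E402


@pytest.fixture(scope="session")
def templates():
    return default_templates()


def plan_from_apertures(apertures, beam_mu=100.0, dose_per_fraction_gy=2.0,
                        n_fractions=1, n_pairs=20, leaf_width_mm=5.0,
                        min_gap_mm=0.5, jaws=None, gantries=None, weights=None,
                        site="prostate"):
    """Hand-built single-beam plan from explicit (x1, x2) bank arrays per CP."""
    geom = MLCGeometry.default(n_pairs, leaf_width_mm, min_gap_mm)
    n_cp = len(apertures)
    if gantries is None:
        gantries = np.linspace(0.0, 359.0, n_cp)
    if weights is None:
        weights = np.linspace(0.0, 1.0, n_cp)
    half = n_pairs * leaf_width_mm / 2.0
    if jaws is None:
        jaws = [((-200.0, 200.0), (-half, half))] * n_cp
    cps = []
    for i, ((x1, x2), g, w, (jx, jy)) in enumerate(
            zip(apertures, gantries, weights, jaws)):
        cps.append(ControlPoint(index=i, gantry_deg=float(g), cum_weight=float(w),
                                x1_mm=np.asarray(x1, float),
                                x2_mm=np.asarray(x2, float),
                                jaw_x_mm=jx, jaw_y_mm=jy))
    plan = Plan(plan_id="manual", site=site, tps_profile="jaw_tracking",
                fractionation=Prescription(dose_per_fraction_gy, n_fractions),
                beam_type="FF", beams=[Beam("b1", beam_mu, cps, geom)])
    plan.validate()
    return plan


def uniform_aperture(n_pairs, x1, x2, open_rows=None):
    """Bank arrays with the given interval on ``open_rows`` (default: all)."""
    a = np.zeros(n_pairs)
    b = np.zeros(n_pairs)
    rows = range(n_pairs) if open_rows is None else open_rows
    for k in rows:
        a[k], b[k] = x1, x2
    return a, b


@pytest.fixture(scope="session")
def spine_study():
    """Reduced single-site cohort: 4 spinal cases, full error grid, systematic
    close/open plus random mode — the linearity and random-vs-systematic
    testbed."""
    design = CohortDesign(sites=("spine_met",), tps_profiles=("jaw_tracking",),
                          fractionations=("standard",), beam_types=("FF",),
                          n_cases=4, base_seed=5)
    config = StudyConfig(random_sites=("spine_met",), random_replicates=1)
    return run_study(design, config)


@pytest.fixture(scope="session")
def sweep_study():
    """20-case cohort (4 sites x modulation grid 0.1..0.9): the
    complexity-correlation testbed."""
    specs = sweep_cohort(("prostate", "lung", "brain_met", "spine_met"),
                         (0.1, 0.3, 0.5, 0.7, 0.9), base_seed=23)
    config = StudyConfig(error_grid=(0.5, 2.0), random_sites=(),
                         include_oars=False)
    return run_study(specs=specs, config=config)


def mean_abs_target_slope(result):
    sens = result.sensitivities
    sel = sens[(sens["structure"] == "target")
               & sens["direction"].isin(["close", "open"])]
    return sel.groupby("case_id")["slope"].apply(lambda s: s.abs().mean())
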