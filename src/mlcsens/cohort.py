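"""Synthetic VMAT cohort generator: phantoms, plans and study designs.

The generator stands in for clinically optimized plans.  It emulates four
treatment-site templates (prostate, lung, brain metastasis, spinal
metastasis), each with a voxel phantom carrying a target and its
organs-at-risk, and builds single-arc VMAT plans whose apertures conform to
the target's beam's-eye-view outline.  An explicit ``modulation`` knob in
[0, 1] narrows leaf gaps, roughens per-leaf positions and meterset weights,
and scales total MU, so that MU/Gy and plan irregularity span a wide range
across a cohort — the engineered structure the downstream sensitivity and
correlation analyses rely on.

Site templates differ in target size, aperture margin and modulation
response: the spinal template wraps a concave target around the cord and
blocks the cord per control point, producing the most complex sequences;
the brain-metastasis template (small spherical target, generous margin,
weak modulation response) produces the simplest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import bev_coords
from .plans import (Beam, ControlPoint, MLCGeometry, Plan, PlanValidationError,
                    Prescription)

__all__ = [
    "OARSpec", "DoseConstraint", "SiteTemplate", "Phantom",
    "CohortDesign", "CaseSpec", "default_templates",
    "make_phantom", "make_plan", "enumerate_cohort", "realize_case",
    "sweep_cohort",
]


@dataclass(frozen=True)
class OARSpec:
    name: str
    shape: str                      # sphere | cylinder | ellipsoid | shell
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, ...]      # shape-specific: radius / (radius, length) / semi-axes


@dataclass(frozen=True)
class DoseConstraint:
    """DVH reporting target (used for reporting, not optimization)."""

    structure: str
    kind: str          # D_percent | V_gy | D_cc | D_max
    arg: float
    limit: float
    units: str         # "%" or "Gy" or "cc"
    fractionation: str = "any"   # standard | hypo | any


@dataclass(frozen=True)
class SiteTemplate:
    site: str
    target_shape: str                       # sphere | annular_wrap
    target_size_mm: tuple[float, float]     # diameter (or outer radius) jitter range
    target_center_mm: tuple[float, float, float]
    oar_specs: tuple[OARSpec, ...]
    prescriptions: dict                     # label -> Prescription
    a_value_target: float
    a_values_oar: dict
    dose_constraints: tuple[DoseConstraint, ...]
    aperture_margin_mm: float
    shrink_gain: float      # fraction of aperture width removed at modulation 1
    jitter_gain_mm: float   # per-leaf positional roughness at modulation 1
    base_mu_per_gy: float

    def __post_init__(self):
        if self.a_value_target >= 0:
            raise ValueError("target a-value must be negative")
        names = {o.name for o in self.oar_specs} | {"target"}
        for c in self.dose_constraints:
            if c.structure not in names:
                raise ValueError(f"constraint references unknown structure {c.structure!r}")


@dataclass
class Phantom:
    """Isotropic voxel grid with boolean structure masks (isocenter at 0 mm)."""

    spacing_mm: float
    shape: tuple[int, int, int]
    masks: dict[str, np.ndarray]
    origin_mm: np.ndarray

    def __post_init__(self):
        if "target" not in self.masks or not self.masks["target"].any():
            raise ValueError("phantom must contain a non-empty 'target' mask")
        for name, m in self.masks.items():
            if m.shape != tuple(self.shape):
                raise ValueError(f"mask {name!r} shape mismatch")

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flat arrays of voxel-center coordinates (mm)."""
        axes = [self.origin_mm[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing_mm
                for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return X.ravel(), Y.ravel(), Z.ravel()

    def structure_coords(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X, Y, Z = self.voxel_coords()
        sel = self.masks[name].ravel()
        return X[sel], Y[sel], Z[sel]


@dataclass(frozen=True)
class CohortDesign:
    sites: tuple[str, ...] = ("prostate", "lung", "brain_met", "spine_met")
    tps_profiles: tuple[str, ...] = ("jaw_tracking", "static_jaw")
    fractionations: tuple[str, ...] = ("standard", "hypo")
    beam_types: tuple[str, ...] = ("FF", "FFF")
    n_cases: int = 20
    base_seed: int = 0

    @property
    def n_plans(self) -> int:
        return (len(self.sites) * len(self.tps_profiles) * len(self.fractionations)
                * len(self.beam_types) * self.n_cases)


@dataclass(frozen=True)
class CaseSpec:
    case_id: str
    site: str
    tps_profile: str
    fractionation: str
    beam_type: str
    case_index: int
    case_seed: int
    modulation: float


# ---------------------------------------------------------------------------
# Site templates
# ---------------------------------------------------------------------------

def default_templates() -> dict[str, SiteTemplate]:
    """The four site templates with their standard/hypofractionated prescriptions."""
    prostate = SiteTemplate(
        site="prostate",
        target_shape="sphere",
        target_size_mm=(45.0, 55.0),
        target_center_mm=(0.0, 0.0, 0.0),
        oar_specs=(
            OARSpec("rectum", "cylinder", (0.0, 30.0, 0.0), (12.0, 70.0)),
            OARSpec("bladder", "sphere", (0.0, -30.0, 12.0), (20.0,)),
        ),
        prescriptions={"standard": Prescription(2.0, 39), "hypo": Prescription(7.25, 5)},
        a_value_target=-25.0,
        a_values_oar={"rectum": 8.33, "bladder": 2.0},
        dose_constraints=(
            DoseConstraint("target", "D_percent", 95, 90, "%"),
            DoseConstraint("target", "D_percent", 98, 90, "%"),
            DoseConstraint("target", "D_percent", 2, 110, "%"),
            DoseConstraint("rectum", "V_gy", 63, 17, "%", "standard"),
            DoseConstraint("rectum", "V_gy", 21, 60, "%", "standard"),
            DoseConstraint("rectum", "V_gy", 36.25, 4.6, "%", "hypo"),
            DoseConstraint("rectum", "V_gy", 18.13, 50, "%", "hypo"),
            DoseConstraint("bladder", "V_gy", 63, 25, "%", "standard"),
            DoseConstraint("bladder", "V_gy", 21, 50, "%", "standard"),
            DoseConstraint("bladder", "V_gy", 36.25, 7.8, "%", "hypo"),
            DoseConstraint("bladder", "V_gy", 18.13, 49, "%", "hypo"),
        ),
        aperture_margin_mm=6.0,
        shrink_gain=0.35,
        jitter_gain_mm=4.0,
        base_mu_per_gy=110.0,
    )
    lung = SiteTemplate(
        site="lung",
        target_shape="sphere",
        target_size_mm=(30.0, 40.0),
        target_center_mm=(26.0, 0.0, 0.0),
        oar_specs=(
            OARSpec("normal_lung", "ellipsoid", (20.0, 0.0, 0.0), (34.0, 40.0, 40.0)),
        ),
        prescriptions={"standard": Prescription(2.0, 30), "hypo": Prescription(13.0, 4)},
        a_value_target=-20.0,
        a_values_oar={"normal_lung": 1.15},
        dose_constraints=(
            DoseConstraint("target", "D_percent", 95, 90, "%"),
            DoseConstraint("target", "D_percent", 98, 90, "%"),
            DoseConstraint("target", "D_percent", 2, 110, "%"),
            DoseConstraint("normal_lung", "V_gy", 20, 35, "%"),
            DoseConstraint("normal_lung", "V_gy", 5, 60, "%"),
        ),
        aperture_margin_mm=6.0,
        shrink_gain=0.50,
        jitter_gain_mm=6.0,
        base_mu_per_gy=125.0,
    )
    brain = SiteTemplate(
        site="brain_met",
        target_shape="sphere",
        target_size_mm=(20.0, 28.0),
        target_center_mm=(0.0, 0.0, 0.0),
        oar_specs=(
            OARSpec("normal_brain", "sphere", (0.0, 0.0, 0.0), (45.0,)),
        ),
        prescriptions={"standard": Prescription(4.2, 10), "hypo": Prescription(10.0, 3)},
        a_value_target=-10.0,
        a_values_oar={"normal_brain": 4.0},
        dose_constraints=(
            DoseConstraint("target", "D_percent", 95, 90, "%"),
            DoseConstraint("target", "D_percent", 98, 90, "%"),
            DoseConstraint("target", "D_percent", 2, 110, "%"),
            DoseConstraint("normal_brain", "V_gy", 38.37, 7, "cc", "standard"),
            DoseConstraint("normal_brain", "V_gy", 23.1, 7, "cc", "hypo"),
        ),
        aperture_margin_mm=9.0,
        shrink_gain=0.22,
        jitter_gain_mm=2.5,
        base_mu_per_gy=90.0,
    )
    spine = SiteTemplate(
        site="spine_met",
        target_shape="annular_wrap",
        target_size_mm=(16.0, 19.0),     # outer radius range; cord sits inside
        target_center_mm=(0.0, 0.0, 0.0),
        oar_specs=(
            OARSpec("spinal_cord", "cylinder", (0.0, 0.0, 0.0), (5.0, 100.0)),
        ),
        prescriptions={"standard": Prescription(3.0, 10), "hypo": Prescription(16.0, 1)},
        a_value_target=-20.0,
        a_values_oar={"spinal_cord": 20.0},
        dose_constraints=(
            DoseConstraint("target", "D_percent", 90, 80, "%"),
            DoseConstraint("target", "D_percent", 98, 80, "%"),
            DoseConstraint("target", "D_percent", 2, 110, "%"),
            DoseConstraint("spinal_cord", "D_max", 0, 25, "Gy", "standard"),
            DoseConstraint("spinal_cord", "D_cc", 0.35, 10, "Gy", "hypo"),
        ),
        aperture_margin_mm=4.0,
        shrink_gain=0.60,
        jitter_gain_mm=7.0,
        base_mu_per_gy=140.0,
    )
    return {t.site: t for t in (prostate, lung, brain, spine)}


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

_PHANTOM_SHAPE = (56, 56, 44)
_PHANTOM_SPACING = 2.0


def _grid(shape, spacing):
    origin = -np.asarray(shape) * spacing / 2.0
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return origin, X, Y, Z


def _sphere(X, Y, Z, center, r):
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r ** 2


def _cylinder(X, Y, Z, center, r, length):
    radial = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= r ** 2
    return radial & (np.abs(Z - center[2]) <= length / 2.0)


def _ellipsoid(X, Y, Z, center, semi):
    return ((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2 + \
           ((Z - center[2]) / semi[2]) ** 2 <= 1.0


def make_phantom(template: SiteTemplate, case_seed: int,
                 spacing_mm: float = _PHANTOM_SPACING,
                 shape: tuple[int, int, int] = _PHANTOM_SHAPE) -> Phantom:
    """Deterministic voxel phantom for one case.

    Target size is jittered within the template range and OAR positions by a
    few millimetres, so cases within a site differ while keeping the
    template's topology (the spinal target always wraps the cord).
    """
    rng = np.random.default_rng([int(case_seed), 0xC0])
    origin, X, Y, Z = _grid(shape, spacing_mm)
    masks: dict[str, np.ndarray] = {}

    lo, hi = template.target_size_mm
    size = rng.uniform(lo, hi)
    tc = np.asarray(template.target_center_mm, dtype=float)

    if template.target_shape == "sphere":
        masks["target"] = _sphere(X, Y, Z, tc, size / 2.0)
    elif template.target_shape == "annular_wrap":
        # concave target: annulus around the cord, wrapped ~300 degrees
        r_out = size
        r_in = 8.0
        half_len = rng.uniform(20.0, 28.0)
        rad2 = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2
        ann = (rad2 >= r_in ** 2) & (rad2 <= r_out ** 2) & (np.abs(Z - tc[2]) <= half_len)
        phi = np.arctan2(Y - tc[1], X - tc[0])
        gap_center = rng.uniform(-np.pi, np.pi)
        dphi = np.abs((phi - gap_center + np.pi) % (2 * np.pi) - np.pi)
        masks["target"] = ann & (dphi > np.deg2rad(30.0))
    else:
        raise ValueError(f"unknown target shape {template.target_shape!r}")

    for oar in template.oar_specs:
        jitter = rng.uniform(-3.0, 3.0, size=3)
        center = np.asarray(oar.center_mm) + jitter
        if oar.shape == "sphere":
            m = _sphere(X, Y, Z, center, oar.size_mm[0])
        elif oar.shape == "cylinder":
            # cord position is structural for the spinal wrap; do not jitter it
            if template.target_shape == "annular_wrap":
                center = np.asarray(oar.center_mm, dtype=float)
            m = _cylinder(X, Y, Z, center, oar.size_mm[0], oar.size_mm[1])
        elif oar.shape == "ellipsoid":
            m = _ellipsoid(X, Y, Z, center, oar.size_mm)
        else:
            raise ValueError(f"unknown OAR shape {oar.shape!r}")
        if not m.any():
            raise ValueError(f"OAR {oar.name!r} fell outside the phantom grid")
        masks[oar.name] = m

    return Phantom(spacing_mm, tuple(shape), masks, origin)


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------

_MIN_OPEN_MM = 6.0      # smallest deliberately open gap the generator emits
_MU_GAIN = 2.5          # MU/Gy multiplier slope vs modulation


def make_plan(template: SiteTemplate, phantom: Phantom, modulation: float,
              tps_profile: str = "jaw_tracking", beam_type: str = "FF",
              case_seed: int = 0, fractionation: str = "standard",
              n_control_points: int = 90) -> Plan:
    """Single 360-degree arc conforming to the target's BEV outline.

    ``modulation`` in [0, 1] scales gap narrowing, per-leaf jitter, meterset
    roughness and total MU.  At 0 every aperture equals the target outline
    plus the template margin.  The ``static_jaw`` profile fixes the jaws to
    the whole-arc envelope and roughens leaf positions more (emulating a
    sequencer without jaw tracking); ``jaw_tracking`` fits the jaws to the
    open leaves at every control point.
    """
    if not 0.0 <= modulation <= 1.0:
        raise ValueError("modulation must lie in [0, 1]")
    if fractionation not in template.prescriptions:
        raise ValueError(f"unknown fractionation {fractionation!r}")

    rng = np.random.default_rng([int(case_seed), 0xA1])
    geom = MLCGeometry.default()
    bounds = geom.leaf_boundaries_mm
    margin = template.aperture_margin_mm
    jitter_sd = template.jitter_gain_mm * modulation
    if tps_profile == "static_jaw":
        jitter_sd *= 1.4

    tX, tY, tZ = phantom.structure_coords("target")
    block = None
    if template.target_shape == "annular_wrap" and "spinal_cord" in phantom.masks:
        block = phantom.structure_coords("spinal_cord")

    angles = np.linspace(0.0, 360.0, n_control_points)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)

    # the conformal margin applies in the leaf-width direction too: strips
    # within `margin` of the target's z-extent open to the outline of the
    # nearest target slice, so the superior/inferior target edges are not
    # penumbra-limited in v
    v_lo_t, v_hi_t = tZ.min() - margin, tZ.max() + margin
    k_lo = int(np.searchsorted(bounds, v_lo_t, side="right") - 1)
    k_hi = int(np.searchsorted(bounds, v_hi_t, side="left"))
    k_lo = max(k_lo, 0)
    k_hi = min(k_hi, geom.n_pairs)

    cps: list[ControlPoint] = []
    open_any = False
    outline_area = 0.0   # conformal-outline aperture area summed over the arc
    open_area = 0.0      # delivered (narrowed, blocked) aperture area
    for i, theta in enumerate(angles):
        u = bev_coords(tX, tY, theta)
        x1 = np.zeros(geom.n_pairs)
        x2 = np.zeros(geom.n_pairs)
        if block is not None:
            ub = bev_coords(block[0], block[1], theta)
        for k in range(k_lo, k_hi):
            sel = (tZ >= bounds[k] - margin) & (tZ < bounds[k + 1] + margin)
            if not sel.any():
                continue
            lo = u[sel].min() - margin
            hi = u[sel].max() + margin
            s = 0.5 + 0.5 * np.sin(2 * np.pi * (0.13 * k + 0.047 * i) + phase1)
            shrink = template.shrink_gain * modulation * (0.3 + 0.7 * s)
            center = 0.5 * (lo + hi) + rng.normal(0.0, jitter_sd) if jitter_sd > 0 \
                else 0.5 * (lo + hi)
            gap = max(_MIN_OPEN_MM, (hi - lo) * (1.0 - shrink))
            a, b = center - gap / 2.0, center + gap / 2.0
            if block is not None:
                selb = (block[2] >= bounds[k]) & (block[2] < bounds[k + 1])
                if selb.any():
                    c_lo, c_hi = ub[selb].min() - 1.0, ub[selb].max() + 1.0
                    if a < c_hi and b > c_lo:
                        # keep one side of the cord, alternating per control
                        # point so the aperture sweeps both sides over the
                        # arc; a blocked segment never closes entirely — the
                        # sequencer keeps a minimum segment width abutting
                        # the blocked region
                        if i % 2 == 0:
                            b = min(b, c_lo)
                            if b - a < _MIN_OPEN_MM:
                                a = b - _MIN_OPEN_MM
                        else:
                            a = max(a, c_hi)
                            if b - a < _MIN_OPEN_MM:
                                b = a + _MIN_OPEN_MM
            x1[k], x2[k] = a, b
            h = bounds[k + 1] - bounds[k]
            outline_area += (hi - lo) * h
            open_area += max(b - a, 0.0) * h
        if np.any(x2 > x1):
            open_any = True
        cps.append(ControlPoint(index=i, gantry_deg=float(min(theta, 360.0 - 1e-6)),
                                cum_weight=0.0, x1_mm=x1, x2_mm=x2,
                                jaw_x_mm=(0.0, 0.0), jaw_y_mm=(0.0, 0.0)))
    if not open_any:
        raise ValueError("target projects to an empty aperture at every angle")

    # jaws: per-control-point fit, or whole-arc envelope for static_jaw
    env_x = [np.inf, -np.inf]
    env_y = [np.inf, -np.inf]
    per_cp_jaws = []
    for cp in cps:
        opened = np.nonzero(cp.x2_mm > cp.x1_mm)[0]
        if opened.size:
            jx = (float(cp.x1_mm[opened].min() - 2.0), float(cp.x2_mm[opened].max() + 2.0))
            jy = (float(bounds[opened.min()] - 1.0), float(bounds[opened.max() + 1] + 1.0))
        else:
            jx, jy = (-2.0, 2.0), (-2.0, 2.0)
        per_cp_jaws.append((jx, jy))
        env_x = [min(env_x[0], jx[0]), max(env_x[1], jx[1])]
        env_y = [min(env_y[0], jy[0]), max(env_y[1], jy[1])]
    for cp, (jx, jy) in zip(cps, per_cp_jaws):
        if tps_profile == "static_jaw":
            cp.jaw_x_mm = (env_x[0], env_x[1])
            cp.jaw_y_mm = (env_y[0], env_y[1])
        else:
            cp.jaw_x_mm = jx
            cp.jaw_y_mm = jy

    # meterset weights: roughened by modulation
    w = 1.0 + 2.0 * modulation * np.abs(rng.standard_normal(n_control_points - 1))
    cum = np.concatenate([[0.0], np.cumsum(w) / w.sum()])
    cum[-1] = 1.0
    for cp, cw in zip(cps, cum):
        cp.cum_weight = float(cw)

    presc = template.prescriptions[fractionation]
    # narrower apertures deliver less fluence per MU, so the meterset needed
    # for the same prescription grows with the mean closedness of the
    # delivered apertures relative to the conformal outline (this also
    # captures the cord-blocking of the spinal template), on top of an
    # explicit modulation term
    openness = open_area / outline_area if outline_area > 0 else 1.0
    beam_mu = template.base_mu_per_gy / max(openness, 0.2) \
        * (1.0 + _MU_GAIN * modulation) * presc.dose_per_fraction_gy
    beam = Beam("arc1", float(beam_mu), cps, geom)
    plan = Plan(
        plan_id=f"{template.site}-{tps_profile}-{fractionation}-{beam_type}-s{case_seed}",
        site=template.site,
        tps_profile=tps_profile,
        fractionation=presc,
        beam_type=beam_type,
        beams=[beam],
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Cohort enumeration
# ---------------------------------------------------------------------------

def _case_seed(base_seed: int, idx: int) -> int:
    return int((base_seed * 1_000_003 + idx * 7_919 + 12_345) % (2 ** 31))


def enumerate_cohort(design: CohortDesign) -> list[CaseSpec]:
    """Full factorial enumeration of a cohort design.

    Case seeds and per-case modulation are derived deterministically from
    ``design.base_seed``; the paper-shaped design (4 sites x 2 profiles x
    2 fractionations x 2 beam types x 20 cases) enumerates 640 plans.
    """
    specs: list[CaseSpec] = []
    idx = 0
    for site in design.sites:
        for profile in design.tps_profiles:
            for fx in design.fractionations:
                for bt in design.beam_types:
                    for c in range(design.n_cases):
                        seed = _case_seed(design.base_seed, idx)
                        mod = float(np.random.default_rng([seed, 0x5EED])
                                    .uniform(0.1, 0.9))
                        specs.append(CaseSpec(
                            case_id=f"{site}-{profile}-{fx}-{bt}-{c:03d}",
                            site=site, tps_profile=profile, fractionation=fx,
                            beam_type=bt, case_index=c, case_seed=seed,
                            modulation=mod))
                        idx += 1
    return specs


def sweep_cohort(sites, modulations, tps_profile: str = "jaw_tracking",
                 fractionation: str = "standard", beam_type: str = "FF",
                 base_seed: int = 0) -> list[CaseSpec]:
    """Cohort with explicitly chosen modulation values per site.

    Unlike :func:`enumerate_cohort`, which draws modulation per case, this
    places cases on a fixed modulation grid — the layout used to probe how
    complexity metrics track dose-error sensitivity across a wide
    modulation range.
    """
    specs = []
    idx = 0
    for site in sites:
        for mod in modulations:
            seed = _case_seed(base_seed, idx)
            specs.append(CaseSpec(
                case_id=f"{site}-{tps_profile}-{fractionation}-{beam_type}-m{mod:.2f}",
                site=site, tps_profile=tps_profile, fractionation=fractionation,
                beam_type=beam_type, case_index=idx, case_seed=seed,
                modulation=float(mod)))
            idx += 1
    return specs


def realize_case(spec: CaseSpec, templates: dict[str, SiteTemplate] | None = None,
                 n_control_points: int = 90) -> tuple[Phantom, Plan]:
    """Materialize phantom and plan for one enumerated case."""
    templates = templates or default_templates()
    template = templates[spec.site]
    phantom = make_phantom(template, spec.case_seed)
    plan = make_plan(template, phantom, spec.modulation, spec.tps_profile,
                     spec.beam_type, spec.case_seed, spec.fractionation,
                     n_control_points=n_control_points)
    return phantom, plan
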