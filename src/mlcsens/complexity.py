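"""Plan complexity metrics: MU/Gy and plan irregularity.

MU/Gy is the ratio of total plan MU to the fraction dose — the simplest
modulation surrogate.  Plan irregularity (PI) follows Du et al.'s
noncircularity construction: per control point the aperture irregularity
AI = perimeter^2 / (4 pi area) of the rectilinear MLC-and-jaw opening,
per beam the segment-MU-weighted mean AI (beam irregularity, BI), and per
plan the beam-MU-weighted mean BI.  A circle would give 1; any rectilinear
aperture is bounded below by 4/pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plans import ControlPoint, MLCGeometry, Plan

__all__ = ["ApertureGeometry", "ComplexityResult", "mu_per_gy",
           "aperture_geometry", "aperture_irregularity", "plan_irregularity"]


@dataclass(frozen=True)
class ApertureGeometry:
    area_mm2: float
    perimeter_mm: float
    n_subapertures: int


@dataclass(frozen=True)
class ComplexityResult:
    mu_per_gy: float
    pi: float
    per_beam_bi: tuple[float, ...]
    per_cp_ai: tuple[tuple[float, ...], ...]   # one tuple per beam; nan where closed


def mu_per_gy(plan: Plan) -> float:
    """Total plan MU divided by the fraction dose."""
    d = plan.fractionation.dose_per_fraction_gy
    if d <= 0:
        raise ValueError("dose per fraction must be > 0")
    return plan.total_mu() / d


def _open_strips(cp: ControlPoint, geom: MLCGeometry):
    """Per leaf strip: jaw-clipped (x0, x1, height) with empty strips as None."""
    b = geom.leaf_boundaries_mm
    jy0, jy1 = cp.jaw_y_mm
    jx0, jx1 = cp.jaw_x_mm
    strips: list[tuple[float, float, float] | None] = []
    for k in range(geom.n_pairs):
        y0, y1 = max(b[k], jy0), min(b[k + 1], jy1)
        if y1 <= y0:
            strips.append(None)
            continue
        x0, x1 = max(float(cp.x1_mm[k]), jx0), min(float(cp.x2_mm[k]), jx1)
        if x1 <= x0:
            strips.append(None)
            continue
        strips.append((x0, x1, y1 - y0))
    return strips


def aperture_geometry(cp: ControlPoint, geom: MLCGeometry) -> ApertureGeometry:
    """Area and rectilinear boundary length of the open MLC-and-jaw region.

    The open region is a union of axis-aligned strips, one interval per leaf
    pair.  The perimeter sums each strip's two leaf-end verticals plus the
    horizontal boundary between vertically adjacent strips, which is the
    symmetric-difference length of their intervals (caps at the top and
    bottom fall out of the same rule against an empty neighbour).
    """
    strips = _open_strips(cp, geom)
    area = 0.0
    perim = 0.0
    n_sub = 0
    prev: tuple[float, float, float] | None = None
    for s in strips + [None]:
        if s is not None:
            x0, x1, h = s
            area += (x1 - x0) * h
            perim += 2.0 * h
        # horizontal boundary between previous strip and this one
        a = prev
        if a is None and s is None:
            prev = s
            continue
        len_a = (a[1] - a[0]) if a else 0.0
        len_b = (s[1] - s[0]) if s else 0.0
        overlap = 0.0
        if a and s:
            overlap = max(0.0, min(a[1], s[1]) - max(a[0], s[0]))
        perim += len_a + len_b - 2.0 * overlap
        if s is not None and (a is None or overlap <= 0.0):
            n_sub += 1
        prev = s
    return ApertureGeometry(area, perim, n_sub)


def aperture_irregularity(ag: ApertureGeometry) -> float:
    """AI = perimeter^2 / (4 pi area); undefined for a closed aperture."""
    if ag.area_mm2 <= 0:
        raise ValueError("aperture irregularity undefined for zero area")
    return ag.perimeter_mm ** 2 / (4.0 * np.pi * ag.area_mm2)


def plan_irregularity(plan: Plan, include_closed_mu: bool = False) -> ComplexityResult:
    """MU-weighted aperture irregularity of a plan.

    Segment MU of interval j (cumulative-weight difference times beam MU) is
    attributed to the interval's starting control point.  Control points with
    a closed aperture contribute no AI; by default their MU is also excluded
    from the beam's denominator (``include_closed_mu`` keeps it).
    """
    per_beam_bi = []
    per_cp_ai = []
    beam_mus = []
    for beam in plan.beams:
        seg = beam.segment_mu()
        ai = np.full(seg.size, np.nan)
        for j in range(seg.size):
            ag = aperture_geometry(beam.control_points[j], beam.geometry)
            if ag.area_mm2 > 0:
                ai[j] = aperture_irregularity(ag)
        open_seg = ~np.isnan(ai)
        denom = seg.sum() if include_closed_mu else seg[open_seg].sum()
        if not open_seg.any() or denom <= 0:
            raise ValueError(f"beam {beam.beam_id}: no open, weighted control points")
        per_beam_bi.append(float(np.nansum(ai * seg) / denom))
        per_cp_ai.append(tuple(ai))
        beam_mus.append(beam.beam_mu)
    beam_mus = np.asarray(beam_mus)
    pi = float(np.dot(per_beam_bi, beam_mus) / beam_mus.sum())
    return ComplexityResult(mu_per_gy(plan), pi, tuple(per_beam_bi), tuple(per_cp_ai))
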