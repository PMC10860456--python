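"""MLC positional-error injection.

Systematic errors displace both banks at every control point: in the
*closing* direction each bank moves toward its opponent by the error
magnitude (the gap shrinks by twice the magnitude), in the *opening*
direction away from it.  Random errors draw an independent zero-mean
Gaussian displacement with standard deviation equal to the magnitude for
every leaf of every bank at every control point.

Pairs that would cross after displacement are clamped symmetrically about
their midpoint to the geometry's minimum gap, and each clamp is logged so
analyses can quantify how often the mechanical floor was hit.  Parked pairs
(gap at or below the minimum and fully outside the jaw-defined field in Y)
are skipped by default — displacing them is physically meaningless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .plans import Plan

__all__ = ["ErrorSpec", "ErrorResult", "ClampEvent",
           "apply_systematic", "apply_random", "build_error_set",
           "STUDY_MAGNITUDES_MM"]

STUDY_MAGNITUDES_MM = (0.25, 0.5, 1.0, 2.0)

_SYSTEMATIC_MODES = ("systematic_close", "systematic_open")


@dataclass(frozen=True)
class ErrorSpec:
    mode: str                    # systematic_close | systematic_open | random
    magnitude_mm: float
    seed: int | None = None      # random mode only
    perturb_parked: bool = False

    def __post_init__(self):
        if self.mode not in _SYSTEMATIC_MODES + ("random",):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.magnitude_mm <= 0:
            raise ValueError("magnitude_mm must be > 0")


@dataclass(frozen=True)
class ClampEvent:
    beam_index: int
    cp_index: int
    leaf_index: int


@dataclass
class ErrorResult:
    plan: Plan
    clamps: list[ClampEvent] = field(default_factory=list)


def _parked_mask(cp, geometry) -> np.ndarray:
    """Pairs closed to the mechanical floor and fully outside the Y jaws."""
    gap = cp.x2_mm - cp.x1_mm
    b = geometry.leaf_boundaries_mm
    outside_y = (b[1:] <= cp.jaw_y_mm[0]) | (b[:-1] >= cp.jaw_y_mm[1])
    return (gap <= geometry.min_gap_mm + 1e-9) & outside_y


def _clamp_crossed(x1, x2, gap_before, min_gap, active) -> np.ndarray:
    """Clamp pairs displaced below the mechanical floor, symmetrically about
    their midpoint.  The clamped gap is ``min_gap``, except that a pair that
    already sat at or below the floor before displacement keeps its original
    gap — displacement must never open a closed pair."""
    floor = np.minimum(min_gap, np.maximum(gap_before, 0.0))
    bad = active & (x2 - x1 < floor - 1e-12)
    if bad.any():
        mid = 0.5 * (x1[bad] + x2[bad])
        x1[bad] = mid - floor[bad] / 2.0
        x2[bad] = mid + floor[bad] / 2.0
    return bad


def apply_systematic(plan: Plan, spec: ErrorSpec) -> ErrorResult:
    """Displace every non-parked pair by the spec's magnitude at every control point."""
    if spec.mode not in _SYSTEMATIC_MODES:
        raise ValueError(f"apply_systematic requires a systematic mode, got {spec.mode!r}")
    delta = spec.magnitude_mm if spec.mode == "systematic_close" else -spec.magnitude_mm
    out = plan.copy()
    out.plan_id = f"{plan.plan_id}+{spec.mode}{spec.magnitude_mm:g}mm"
    clamps: list[ClampEvent] = []
    for bi, beam in enumerate(out.beams):
        for ci, cp in enumerate(beam.control_points):
            active = ~_parked_mask(cp, beam.geometry) if not spec.perturb_parked \
                else np.ones(beam.geometry.n_pairs, dtype=bool)
            gap_before = cp.x2_mm - cp.x1_mm
            cp.x1_mm[active] += delta
            cp.x2_mm[active] -= delta
            bad = _clamp_crossed(cp.x1_mm, cp.x2_mm, gap_before,
                                 beam.geometry.min_gap_mm, active)
            clamps.extend(ClampEvent(bi, ci, int(k)) for k in np.nonzero(bad)[0])
    out.validate()
    return ErrorResult(out, clamps)


def apply_random(plan: Plan, spec: ErrorSpec) -> ErrorResult:
    """Independent Gaussian displacement (SD = magnitude) per leaf, bank and control point."""
    if spec.mode != "random":
        raise ValueError(f"apply_random requires mode 'random', got {spec.mode!r}")
    if spec.seed is None:
        raise ValueError("random mode requires a seed")
    rng = np.random.default_rng([int(spec.seed), 0xE7])
    out = plan.copy()
    out.plan_id = f"{plan.plan_id}+random{spec.magnitude_mm:g}mm-s{spec.seed}"
    clamps: list[ClampEvent] = []
    for bi, beam in enumerate(out.beams):
        for ci, cp in enumerate(beam.control_points):
            active = ~_parked_mask(cp, beam.geometry) if not spec.perturb_parked \
                else np.ones(beam.geometry.n_pairs, dtype=bool)
            gap_before = cp.x2_mm - cp.x1_mm
            d1 = rng.normal(0.0, spec.magnitude_mm, size=beam.geometry.n_pairs)
            d2 = rng.normal(0.0, spec.magnitude_mm, size=beam.geometry.n_pairs)
            cp.x1_mm[active] += d1[active]
            cp.x2_mm[active] += d2[active]
            bad = _clamp_crossed(cp.x1_mm, cp.x2_mm, gap_before,
                                 beam.geometry.min_gap_mm, active)
            clamps.extend(ClampEvent(bi, ci, int(k)) for k in np.nonzero(bad)[0])
    out.validate()
    return ErrorResult(out, clamps)


def apply_error(plan: Plan, spec: ErrorSpec) -> ErrorResult:
    if spec.mode == "random":
        return apply_random(plan, spec)
    return apply_systematic(plan, spec)


def build_error_set(plans, grid, modes, n_replicates: int = 1,
                    base_seed: int = 0) -> list[tuple]:
    """Cross product of plans x modes x magnitudes (x replicates for random mode).

    Returns ``(plan, ErrorSpec)`` pairs without applying the errors; the
    paper-shaped systematic set (640 plans x {close, open} x 4 magnitudes)
    enumerates 5120 entries.  Random-mode entries carry derived seeds so the
    set is reproducible from ``base_seed``.
    """
    grid = list(grid)
    modes = list(modes)
    if not grid:
        raise ValueError("magnitude grid must not be empty")
    if not modes:
        raise ValueError("mode list must not be empty")
    entries = []
    counter = itertools.count()
    for plan in plans:
        for mode in modes:
            for mag in grid:
                if mode == "random":
                    for _ in range(n_replicates):
                        seed = int((base_seed * 69_069 + next(counter) * 40_503 + 7)
                                   % (2 ** 31))
                        entries.append((plan, ErrorSpec(mode, mag, seed=seed)))
                else:
                    entries.append((plan, ErrorSpec(mode, mag)))
    return entries
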