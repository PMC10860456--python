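"""Surrogate forward dose engine and DVH computation.

The engine turns a plan plus a voxel phantom into a per-fraction dose grid.
It is deliberately simple — per control-point interval it builds the 2-D
aperture fluence at the isocenter plane (fractional pixel coverage of the
MLC-and-jaw opening), blurs it with a Gaussian penumbra, weights it by the
interval's meterset, and back-projects it through the phantom along the
interval's mean gantry direction with parallel rays.  The sum over intervals
is scaled once so that the reference plan's target mean dose equals the
prescribed dose per fraction; that calibration factor is frozen and reused
for the plan's error variants so that aperture-driven dose errors survive.

No scatter, heterogeneity, beam divergence or spectral modelling: the
quantity of interest is the *change* of dose with MLC aperture changes, and
the engine is linear in fluence, which is all the downstream sensitivity
analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["EngineConfig", "DoseGrid", "DVHCurve", "bev_coords",
           "compute_dose", "compute_dvh", "dvh_query"]


@dataclass(frozen=True)
class EngineConfig:
    penumbra_sigma_mm: float = 3.0
    fluence_spacing_mm: float = 1.0
    fluence_half_extent_mm: float = 110.0
    target_structure: str = "target"


@dataclass
class DoseGrid:
    """Per-fraction dose on the phantom's voxel grid (Gy)."""

    values_gy: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    calibration: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.values_gy)) or np.any(self.values_gy < 0):
            raise ValueError("dose values must be finite and non-negative")


@dataclass
class DVHCurve:
    """Differential dose-volume histogram for one structure."""

    structure: str
    bin_edges_gy: np.ndarray
    diff_volume: np.ndarray
    total_volume_cc: float

    def __post_init__(self):
        self.bin_edges_gy = np.asarray(self.bin_edges_gy, dtype=np.float64)
        self.diff_volume = np.asarray(self.diff_volume, dtype=np.float64)
        if self.diff_volume.size != self.bin_edges_gy.size - 1:
            raise ValueError("diff_volume must have one entry per bin")
        if np.any(self.diff_volume < -1e-12):
            raise ValueError("differential volumes must be >= 0")
        if abs(self.diff_volume.sum() - 1.0) > 1e-9:
            raise ValueError("differential volumes must sum to 1")

    @property
    def bin_centers_gy(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_gy[:-1] + self.bin_edges_gy[1:])

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative DVH on bin lower edges: fraction of volume with dose >= edge."""
        cum = 1.0 - np.concatenate([[0.0], np.cumsum(self.diff_volume)[:-1]])
        return self.bin_edges_gy[:-1], cum


def bev_coords(x_mm: np.ndarray, y_mm: np.ndarray, gantry_deg: float) -> np.ndarray:
    """Lateral beam's-eye-view coordinate of points for a given gantry angle.

    Parallel-ray projection: the longitudinal BEV coordinate equals the
    patient z-coordinate; the lateral one rotates with the gantry in the
    axial plane.
    """
    th = np.deg2rad(gantry_deg)
    return x_mm * np.cos(th) + y_mm * np.sin(th)


def _aperture_fluence(cp, geometry, u_centers: np.ndarray, v_centers: np.ndarray,
                      spacing: float) -> np.ndarray:
    """Fractional-coverage fluence map (v rows, u columns) of the open aperture."""
    F = np.zeros((v_centers.size, u_centers.size))
    jx0, jx1 = cp.jaw_x_mm
    jy0, jy1 = cp.jaw_y_mm
    bounds = geometry.leaf_boundaries_mm
    u_lo, u_hi = u_centers - spacing / 2, u_centers + spacing / 2
    v_lo, v_hi = v_centers - spacing / 2, v_centers + spacing / 2
    for k in range(geometry.n_pairs):
        y0, y1 = max(bounds[k], jy0), min(bounds[k + 1], jy1)
        if y1 <= y0:
            continue
        x0, x1 = max(cp.x1_mm[k], jx0), min(cp.x2_mm[k], jx1)
        if x1 <= x0:
            continue
        cov_u = np.clip((np.minimum(u_hi, x1) - np.maximum(u_lo, x0)) / spacing, 0.0, 1.0)
        cov_v = np.clip((np.minimum(v_hi, y1) - np.maximum(v_lo, y0)) / spacing, 0.0, 1.0)
        F += np.outer(cov_v, cov_u)
    return np.clip(F, 0.0, 1.0)


def _mean_gantry(a: float, b: float) -> float:
    """Mean of two gantry angles along the shorter arc."""
    d = (b - a + 180.0) % 360.0 - 180.0
    return (a + d / 2.0) % 360.0


def compute_dose(plan, phantom, config: EngineConfig | None = None,
                 calibration: float | None = None) -> DoseGrid:
    """Forward-project a plan through a phantom.

    When ``calibration`` is None the grid is scaled so the mean dose in the
    phantom's target structure equals the plan's dose per fraction and the
    factor is stored on the returned grid; pass a reference plan's stored
    factor to evaluate its error variants on the same absolute scale.
    """
    config = config or EngineConfig()
    if config.target_structure not in phantom.masks:
        raise ValueError(f"phantom has no structure {config.target_structure!r}")

    sp = config.fluence_spacing_mm
    half = config.fluence_half_extent_mm
    n = int(round(2 * half / sp)) + 1
    u_centers = np.linspace(-half, half, n)
    v_centers = u_centers

    X, Y, Z = phantom.voxel_coords()
    v_idx = (Z - v_centers[0]) / sp  # constant over gantry angles
    sigma_px = config.penumbra_sigma_mm / sp

    accum = np.zeros(X.size)
    for beam in plan.beams:
        seg_mu = beam.segment_mu()
        for j, mu in enumerate(seg_mu):
            if mu <= 0:
                continue
            cp = beam.control_points[j]
            theta = _mean_gantry(cp.gantry_deg, beam.control_points[j + 1].gantry_deg)
            F = _aperture_fluence(cp, beam.geometry, u_centers, v_centers, sp)
            if F.max() <= 0:
                continue
            F = ndimage.gaussian_filter(F, sigma_px, mode="constant")
            u = bev_coords(X, Y, theta)
            u_idx = (u - u_centers[0]) / sp
            accum += mu * ndimage.map_coordinates(F, [v_idx, u_idx], order=1,
                                                  mode="constant", cval=0.0)

    if calibration is None:
        tmask = phantom.masks[config.target_structure].ravel()
        mean_target = accum[tmask].mean()
        if mean_target <= 0:
            raise ValueError("target receives no dose; cannot calibrate")
        calibration = plan.fractionation.dose_per_fraction_gy / mean_target
    values = (accum * calibration).reshape(phantom.shape)
    return DoseGrid(values, phantom.spacing_mm, np.asarray(phantom.origin_mm),
                    float(calibration))


def compute_dvh(dose: DoseGrid, phantom, structure: str,
                bin_width_gy: float = 0.05, dose_scale: float = 1.0) -> DVHCurve:
    """Differential DVH of ``structure`` from a dose grid.

    ``dose_scale`` converts the per-fraction grid to the reporting scale
    (e.g. the number of fractions for total-dose DVHs).
    """
    if structure not in phantom.masks:
        raise ValueError(f"unknown structure {structure!r}")
    mask = phantom.masks[structure]
    if not mask.any():
        raise ValueError(f"structure {structure!r} has an empty mask")
    doses = dose.values_gy[mask] * dose_scale
    n_bins = max(1, int(np.ceil((doses.max() + 1e-12) / bin_width_gy)))
    edges = np.arange(n_bins + 1) * bin_width_gy
    hist, _ = np.histogram(doses, bins=edges)
    diff = hist / doses.size
    total_cc = mask.sum() * (phantom.spacing_mm / 10.0) ** 3
    return DVHCurve(structure, edges, diff, float(total_cc))


def dvh_query(dvh: DVHCurve, kind: str, arg: float = 0.0) -> float:
    """DVH point queries.

    ``D_percent``: minimum dose received by the hottest ``arg`` % of volume.
    ``V_gy``: fractional volume receiving at least ``arg`` Gy.
    ``D_cc``: minimum dose received by the hottest ``arg`` cm^3.
    ``D_max``: highest occupied dose bin.
    """
    centers = dvh.bin_centers_gy
    v = dvh.diff_volume
    occupied = v > 0
    if kind == "D_max":
        return float(centers[occupied][-1])
    if kind == "D_percent":
        if not 0 < arg <= 100:
            raise ValueError("D_percent argument must be in (0, 100]")
        frac = arg / 100.0
    elif kind == "D_cc":
        if not 0 < arg <= dvh.total_volume_cc:
            raise ValueError("D_cc argument must be in (0, total volume]")
        frac = arg / dvh.total_volume_cc
    elif kind == "V_gy":
        if arg < 0:
            raise ValueError("V_gy argument must be >= 0")
        return float(v[centers >= arg].sum())
    else:
        raise ValueError(f"unknown query kind {kind!r}")
    # hottest-fraction queries: accumulate volume from the hot end down
    cum_from_top = np.cumsum(v[::-1])[::-1]
    idx = np.nonzero(cum_from_top >= frac - 1e-12)[0]
    return float(centers[idx[-1]])
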