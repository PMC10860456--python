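"""Domain model for VMAT treatment plans.

A plan is a set of arc beams; each beam is an ordered list of control points
carrying the machine state (gantry angle, MLC bank positions, jaw positions,
cumulative meterset weight).  Leaf and jaw positions follow the IEC 61217
convention, projected to the isocenter plane and expressed in millimetres:
bank 1 is the negative-X bank, bank 2 the positive-X bank, so a physically
valid pair always satisfies ``x1 <= x2``.

Two serializations are supported: a JSON dialect (the native fixture format,
units mm / MU / Gy) and DICOM-RT Plan via :mod:`pydicom`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "PlanValidationError",
    "MLCGeometry",
    "ControlPoint",
    "Beam",
    "Prescription",
    "Plan",
    "read_plan",
    "write_plan",
]

SITES = ("prostate", "lung", "brain_met", "spine_met")
BEAM_TYPES = ("FF", "FFF")


class PlanValidationError(ValueError):
    """A plan, beam or control point violates a structural invariant."""


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass(frozen=True)
class MLCGeometry:
    """Static geometry of one MLC bank pair set.

    ``leaf_boundaries_mm`` holds the ``n_pairs + 1`` strictly ascending
    Y-coordinates of the leaf-strip boundaries at isocenter; leaf widths are
    the successive differences.  ``min_gap_mm`` is the smallest mechanically
    allowed gap between opposing leaves (a dynamic-leaf-gap floor).
    """

    leaf_boundaries_mm: np.ndarray
    min_gap_mm: float = 0.5

    def __post_init__(self):
        b = _as_f64(self.leaf_boundaries_mm)
        object.__setattr__(self, "leaf_boundaries_mm", b)
        if b.ndim != 1 or b.size < 2:
            raise PlanValidationError("leaf_boundaries_mm must hold >= 2 values")
        if not np.all(np.diff(b) > 0):
            raise PlanValidationError("leaf boundaries must be strictly ascending")
        if self.min_gap_mm < 0:
            raise PlanValidationError("min_gap_mm must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.leaf_boundaries_mm.size - 1

    @property
    def leaf_width_mm(self) -> np.ndarray:
        return np.diff(self.leaf_boundaries_mm)

    @classmethod
    def default(cls, n_pairs: int = 80, leaf_width_mm: float = 5.0,
                min_gap_mm: float = 0.5) -> "MLCGeometry":
        """Uniform-width MLC centred on the beam axis (default 80 x 5 mm)."""
        half = n_pairs * leaf_width_mm / 2.0
        return cls(np.linspace(-half, half, n_pairs + 1), min_gap_mm)


@dataclass
class ControlPoint:
    """Machine state snapshot at one point along an arc."""

    index: int
    gantry_deg: float
    cum_weight: float
    x1_mm: np.ndarray
    x2_mm: np.ndarray
    jaw_x_mm: tuple[float, float]
    jaw_y_mm: tuple[float, float]

    def __post_init__(self):
        self.x1_mm = _as_f64(self.x1_mm)
        self.x2_mm = _as_f64(self.x2_mm)
        self.jaw_x_mm = (float(self.jaw_x_mm[0]), float(self.jaw_x_mm[1]))
        self.jaw_y_mm = (float(self.jaw_y_mm[0]), float(self.jaw_y_mm[1]))

    def validate(self, geometry: MLCGeometry, where: str = "") -> None:
        if self.x1_mm.shape != self.x2_mm.shape or self.x1_mm.ndim != 1:
            raise PlanValidationError(f"{where}: bank arrays must be 1-D and equal length")
        if self.x1_mm.size != geometry.n_pairs:
            raise PlanValidationError(
                f"{where}: {self.x1_mm.size} leaf pairs, geometry has {geometry.n_pairs}")
        crossed = np.nonzero(self.x1_mm > self.x2_mm + 1e-9)[0]
        if crossed.size:
            raise PlanValidationError(
                f"{where}: bank-1 leaf beyond bank-2 at leaf indices {crossed.tolist()}")
        if self.jaw_x_mm[0] > self.jaw_x_mm[1] or self.jaw_y_mm[0] > self.jaw_y_mm[1]:
            raise PlanValidationError(f"{where}: jaw positions out of order")
        if not 0.0 <= self.gantry_deg < 360.0 + 1e-9:
            raise PlanValidationError(f"{where}: gantry angle {self.gantry_deg} outside [0, 360)")

    def copy(self) -> "ControlPoint":
        return ControlPoint(self.index, self.gantry_deg, self.cum_weight,
                            self.x1_mm.copy(), self.x2_mm.copy(),
                            self.jaw_x_mm, self.jaw_y_mm)


@dataclass
class Beam:
    beam_id: str
    beam_mu: float
    control_points: list[ControlPoint]
    geometry: MLCGeometry

    def validate(self, where: str = "") -> None:
        if self.beam_mu <= 0:
            raise PlanValidationError(f"{where}: beam_mu must be > 0")
        if len(self.control_points) < 2:
            raise PlanValidationError(f"{where}: a beam needs >= 2 control points")
        cw = np.array([cp.cum_weight for cp in self.control_points])
        if abs(cw[0]) > 1e-9 or abs(cw[-1] - 1.0) > 1e-9:
            raise PlanValidationError(f"{where}: cumulative weight must run from 0 to 1")
        if np.any(np.diff(cw) < -1e-12):
            raise PlanValidationError(f"{where}: cumulative weight must be non-decreasing")
        for i, cp in enumerate(self.control_points):
            cp.validate(self.geometry, where=f"{where} cp[{i}]")

    def segment_mu(self) -> np.ndarray:
        """MU delivered in each control-point interval (length n_cp - 1)."""
        cw = np.array([cp.cum_weight for cp in self.control_points])
        return self.beam_mu * np.diff(cw)

    def copy(self) -> "Beam":
        return Beam(self.beam_id, self.beam_mu,
                    [cp.copy() for cp in self.control_points], self.geometry)


@dataclass(frozen=True)
class Prescription:
    dose_per_fraction_gy: float
    n_fractions: int

    def __post_init__(self):
        if self.dose_per_fraction_gy <= 0:
            raise PlanValidationError("dose_per_fraction_gy must be > 0")
        if self.n_fractions < 1:
            raise PlanValidationError("n_fractions must be >= 1")

    @property
    def total_dose_gy(self) -> float:
        return self.dose_per_fraction_gy * self.n_fractions


@dataclass
class Plan:
    plan_id: str
    site: str
    tps_profile: str
    fractionation: Prescription
    beam_type: str
    beams: list[Beam]

    def validate(self) -> None:
        if not self.beams:
            raise PlanValidationError(f"plan {self.plan_id}: no beams")
        for b in self.beams:
            b.validate(where=f"plan {self.plan_id} beam {b.beam_id}")
        if self.total_mu() <= 0:
            raise PlanValidationError(f"plan {self.plan_id}: total MU must be > 0")

    def total_mu(self) -> float:
        return float(sum(b.beam_mu for b in self.beams))

    def copy(self) -> "Plan":
        return replace(self, beams=[b.copy() for b in self.beams])

    def iter_control_points(self) -> Iterator[tuple[int, int, ControlPoint]]:
        for bi, beam in enumerate(self.beams):
            for ci, cp in enumerate(beam.control_points):
                yield bi, ci, cp


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def plan_to_dict(plan: Plan) -> dict:
    return {
        "plan_id": plan.plan_id,
        "site": plan.site,
        "tps_profile": plan.tps_profile,
        "fractionation": {
            "dose_per_fraction_gy": plan.fractionation.dose_per_fraction_gy,
            "n_fractions": plan.fractionation.n_fractions,
        },
        "beam_type": plan.beam_type,
        "beams": [
            {
                "beam_id": b.beam_id,
                "beam_mu": b.beam_mu,
                "geometry": {
                    "leaf_boundaries_mm": b.geometry.leaf_boundaries_mm.tolist(),
                    "min_gap_mm": b.geometry.min_gap_mm,
                },
                "control_points": [
                    {
                        "index": cp.index,
                        "gantry_deg": cp.gantry_deg,
                        "cum_weight": cp.cum_weight,
                        "x1_mm": cp.x1_mm.tolist(),
                        "x2_mm": cp.x2_mm.tolist(),
                        "jaw_x_mm": list(cp.jaw_x_mm),
                        "jaw_y_mm": list(cp.jaw_y_mm),
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }


def plan_from_dict(d: dict) -> Plan:
    try:
        beams = []
        for bd in d["beams"]:
            geom = MLCGeometry(np.asarray(bd["geometry"]["leaf_boundaries_mm"]),
                               float(bd["geometry"]["min_gap_mm"]))
            cps = [
                ControlPoint(
                    index=int(cd["index"]),
                    gantry_deg=float(cd["gantry_deg"]),
                    cum_weight=float(cd["cum_weight"]),
                    x1_mm=cd["x1_mm"],
                    x2_mm=cd["x2_mm"],
                    jaw_x_mm=tuple(cd["jaw_x_mm"]),
                    jaw_y_mm=tuple(cd["jaw_y_mm"]),
                )
                for cd in bd["control_points"]
            ]
            beams.append(Beam(str(bd["beam_id"]), float(bd["beam_mu"]), cps, geom))
        plan = Plan(
            plan_id=str(d["plan_id"]),
            site=str(d["site"]),
            tps_profile=str(d["tps_profile"]),
            fractionation=Prescription(float(d["fractionation"]["dose_per_fraction_gy"]),
                                       int(d["fractionation"]["n_fractions"])),
            beam_type=str(d["beam_type"]),
            beams=beams,
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise PlanValidationError(f"missing element in plan JSON: {exc}") from exc
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# DICOM-RT Plan mapping
# ---------------------------------------------------------------------------

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


def _plan_to_dataset(plan: Plan):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id[:16]      # SH VR is capped at 16 chars
    ds.RTPlanDescription = (
        f"plan_id={plan.plan_id};"
        f"site={plan.site};tps_profile={plan.tps_profile};beam_type={plan.beam_type};"
        f"dose_per_fraction_gy={plan.fractionation.dose_per_fraction_gy!r};"
        f"n_fractions={plan.fractionation.n_fractions}"
    )

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan.fractionation.n_fractions
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for bi, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = round(beam.beam_mu, 5)
        fg.ReferencedBeamSequence.append(rb)

        bd = Dataset()
        bd.BeamNumber = bi
        bd.BeamName = beam.beam_id
        bd.BeamType = "DYNAMIC"
        bd.RadiationType = "PHOTON"
        bd.NumberOfControlPoints = len(beam.control_points)

        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = "MLCX"
        mlc.NumberOfLeafJawPairs = beam.geometry.n_pairs
        mlc.LeafPositionBoundaries = [round(v, 5) for v in beam.geometry.leaf_boundaries_mm]
        bd.BeamLimitingDeviceSequence = [mlc]

        bd.ControlPointSequence = []
        for cp in beam.control_points:
            cd = Dataset()
            cd.ControlPointIndex = cp.index
            cd.GantryAngle = round(cp.gantry_deg, 5)
            cd.CumulativeMetersetWeight = round(cp.cum_weight, 8)
            jx = Dataset()
            jx.RTBeamLimitingDeviceType = "ASYMX"
            jx.LeafJawPositions = [round(v, 5) for v in cp.jaw_x_mm]
            jy = Dataset()
            jy.RTBeamLimitingDeviceType = "ASYMY"
            jy.LeafJawPositions = [round(v, 5) for v in cp.jaw_y_mm]
            ml = Dataset()
            ml.RTBeamLimitingDeviceType = "MLCX"
            ml.LeafJawPositions = [round(v, 5) for v in cp.x1_mm] + \
                                  [round(v, 5) for v in cp.x2_mm]
            cd.BeamLimitingDevicePositionSequence = [jx, jy, ml]
            bd.ControlPointSequence.append(cd)
        ds.BeamSequence.append(bd)
    return ds


def _parse_description(desc: str) -> dict:
    out = {}
    for item in desc.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _plan_from_dataset(ds) -> Plan:
    meta = _parse_description(str(getattr(ds, "RTPlanDescription", "")))
    mu_by_number = {}
    for fg in ds.FractionGroupSequence:
        for rb in fg.ReferencedBeamSequence:
            mu_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    n_fractions = int(ds.FractionGroupSequence[0].NumberOfFractionsPlanned)

    beams = []
    for bd in ds.BeamSequence:
        boundaries = None
        for dev in getattr(bd, "BeamLimitingDeviceSequence", []):
            if dev.RTBeamLimitingDeviceType == "MLCX":
                boundaries = np.asarray([float(v) for v in dev.LeafPositionBoundaries])
        if boundaries is None:
            raise PlanValidationError(
                f"beam {bd.BeamNumber}: no MLCX entry in BeamLimitingDeviceSequence")
        geom = MLCGeometry(boundaries)
        cps = []
        jaw_x, jaw_y = (-200.0, 200.0), (-200.0, 200.0)
        for cd in bd.ControlPointSequence:
            x1 = x2 = None
            for pos in getattr(cd, "BeamLimitingDevicePositionSequence", []):
                vals = [float(v) for v in pos.LeafJawPositions]
                if pos.RTBeamLimitingDeviceType == "ASYMX":
                    jaw_x = (vals[0], vals[1])
                elif pos.RTBeamLimitingDeviceType == "ASYMY":
                    jaw_y = (vals[0], vals[1])
                elif pos.RTBeamLimitingDeviceType == "MLCX":
                    n = len(vals) // 2
                    x1, x2 = np.asarray(vals[:n]), np.asarray(vals[n:])
            if x1 is None:
                raise PlanValidationError(
                    f"beam {bd.BeamNumber} cp {cd.ControlPointIndex}: no MLCX positions")
            cps.append(ControlPoint(int(cd.ControlPointIndex), float(cd.GantryAngle),
                                    float(cd.CumulativeMetersetWeight), x1, x2,
                                    jaw_x, jaw_y))
        beams.append(Beam(str(getattr(bd, "BeamName", bd.BeamNumber)),
                          mu_by_number[int(bd.BeamNumber)], cps, geom))

    plan = Plan(
        plan_id=meta.get("plan_id", str(getattr(ds, "RTPlanLabel", "plan"))),
        site=meta.get("site", "prostate"),
        tps_profile=meta.get("tps_profile", "jaw_tracking"),
        fractionation=Prescription(float(meta.get("dose_per_fraction_gy", 2.0)),
                                   n_fractions),
        beam_type=meta.get("beam_type", "FF"),
        beams=beams,
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def read_plan(path: str | Path, dialect: str = "json") -> Plan:
    """Read a plan from ``path`` in the given dialect (``json`` or ``dicom_rtplan``)."""
    path = Path(path)
    if dialect == "json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PlanValidationError(f"{path}: malformed JSON at line {exc.lineno}") from exc
        return plan_from_dict(d)
    if dialect == "dicom_rtplan":
        import pydicom
        ds = pydicom.dcmread(path)
        return _plan_from_dataset(ds)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plan(plan: Plan, path: str | Path, dialect: str = "json") -> None:
    plan.validate()
    path = Path(path)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(plan_to_dict(plan), fh, indent=1)
        return
    if dialect == "dicom_rtplan":
        ds = _plan_to_dataset(plan)
        ds.save_as(path, enforce_file_format=True)
        return
    raise ValueError(f"unknown dialect {dialect!r}")
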