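"""Generalized equivalent uniform dose (gEUD).

gEUD = (sum_i v_i D_i^a)^(1/a) over differential DVH bins, with bin-center
doses D_i and fractional volumes v_i.  The exponent ``a`` encodes the
volume effect: large negative values make cold spots dominate (targets),
large positive values make hot spots dominate (serial organs), a = 1 is the
mean dose.  Evaluation goes through log-sum-exp so strongly negative or
positive exponents stay finite in double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import logsumexp

from .dose import DVHCurve

__all__ = ["GEUDParams", "AValueRegistry", "GEUDChange", "geud", "geud_change"]


@dataclass(frozen=True)
class GEUDParams:
    """Exponent and numerical floor for one structure's gEUD."""

    a: float
    dose_floor_gy: float = 0.01

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("a = 0 (geometric-mean limit) is not supported")
        if self.dose_floor_gy <= 0:
            raise ValueError("dose_floor_gy must be > 0")


# Target exponents follow the published site-specific choices; OAR exponents
# default to a = 1/n with the Burman-Emami volume-effect parameter n.
_DEFAULT_A = {
    "targets": {"prostate": -25.0, "lung": -20.0, "brain_met": -10.0,
                "spine_met": -20.0},
    "oars": {"rectum": 8.33, "bladder": 2.0, "normal_lung": 1.15,
             "spinal_cord": 20.0, "normal_brain": 4.0},
}


@dataclass
class AValueRegistry:
    """Site -> target exponent and structure -> OAR exponent lookup."""

    target_a: dict = field(default_factory=lambda: dict(_DEFAULT_A["targets"]))
    oar_a: dict = field(default_factory=lambda: dict(_DEFAULT_A["oars"]))

    def __post_init__(self):
        for site, a in self.target_a.items():
            if a >= 0:
                raise ValueError(f"target a-value for {site!r} must be negative")

    def for_structure(self, site: str, structure: str) -> GEUDParams:
        if structure == "target":
            return GEUDParams(self.target_a[site])
        return GEUDParams(self.oar_a[structure])

    @classmethod
    def from_file(cls, path) -> "AValueRegistry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(target_a=d["targets"], oar_a=d["oars"])

    @classmethod
    def default(cls) -> "AValueRegistry":
        with resources.files("mlcsens").joinpath("data/a_values.json").open() as fh:
            d = json.load(fh)
        return cls(target_a=d["targets"], oar_a=d["oars"])


@dataclass(frozen=True)
class GEUDChange:
    """gEUD of a reference/error DVH pair and its change."""

    ref_geud_gy: float
    err_geud_gy: float

    @property
    def delta_percent(self) -> float:
        return 100.0 * (self.err_geud_gy - self.ref_geud_gy) / self.ref_geud_gy

    @property
    def delta_gy(self) -> float:
        return self.err_geud_gy - self.ref_geud_gy


def geud(dvh: DVHCurve, params: GEUDParams) -> float:
    """Evaluate gEUD on a differential DVH.

    Bin-center doses are floored at ``params.dose_floor_gy`` so negative
    exponents remain finite when a structure contains (near-)zero-dose
    voxels; a floored gEUD then correctly reports a cold-spot-dominated
    low value.
    """
    v = dvh.diff_volume
    occ = v > 0
    d = np.maximum(dvh.bin_centers_gy[occ], params.dose_floor_gy)
    w = v[occ]
    log_sum = logsumexp(params.a * np.log(d), b=w)
    return float(np.exp(log_sum / params.a))


def geud_change(ref: DVHCurve, err: DVHCurve, params: GEUDParams) -> GEUDChange:
    """gEUD change of an error-plan DVH relative to its reference DVH."""
    if ref.structure != err.structure:
        raise ValueError("reference and error DVHs must describe the same structure")
    g_ref = geud(ref, params)
    g_err = geud(err, params)
    if g_ref <= 0:
        raise ValueError("reference gEUD is zero; percent change undefined")
    return GEUDChange(g_ref, g_err)
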