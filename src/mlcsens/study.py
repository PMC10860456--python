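"""End-to-end study orchestration.

``run_study`` executes the full pipeline over an enumerated cohort:
generate phantom and plan, inject systematic (and, for configured sites,
random) MLC positional errors, recompute dose with the frozen reference
calibration, build DVHs, evaluate gEUD changes, fit per-case sensitivity
slopes, compute complexity metrics, and derive per-scenario tolerances and
complexity-sensitivity correlations.  All randomness flows from the design's
base seed through named substreams, so a rerun with the same design
reproduces every table bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CaseSpec, CohortDesign, default_templates, realize_case
from .complexity import plan_irregularity
from .dose import EngineConfig, compute_dose, compute_dvh, dvh_query
from .errors import STUDY_MAGNITUDES_MM, ErrorSpec, apply_random, apply_systematic
from .geud import AValueRegistry, geud, geud_change
from .stats import (SensitivityResult, compare_groups, correlate,
                    derive_tolerance, fit_sensitivity)

__all__ = ["StudyConfig", "StudyResult", "run_study", "evaluate_constraints"]


@dataclass(frozen=True)
class StudyConfig:
    error_grid: tuple[float, ...] = STUDY_MAGNITUDES_MM
    systematic_modes: tuple[str, ...] = ("systematic_close", "systematic_open")
    random_sites: tuple[str, ...] = ("spine_met",)
    random_replicates: int = 1
    threshold_pct: float = 2.0
    aggregation: str = "mean"
    n_control_points: int = 90
    engine: EngineConfig = field(default_factory=EngineConfig)
    bin_width_gy: float = 0.05
    dose_scale: str = "total"          # "total" or "per_fraction"
    include_oars: bool = True


@dataclass
class StudyResult:
    cases: pd.DataFrame
    geud_changes: pd.DataFrame
    sensitivities: pd.DataFrame
    tolerances: pd.DataFrame
    correlations: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict

    def save(self, outdir) -> None:
        import json
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("cases", "geud_changes", "sensitivities", "tolerances",
                     "correlations", "comparisons"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


_DIRECTION = {"systematic_close": "close", "systematic_open": "open"}


def _dvhs(dose, phantom, structures, scale, bin_width):
    return {s: compute_dvh(dose, phantom, s, bin_width_gy=bin_width, dose_scale=scale)
            for s in structures}


def run_study(design: CohortDesign | None = None,
              config: StudyConfig | None = None, templates=None,
              registry: AValueRegistry | None = None,
              specs=None) -> StudyResult:
    """Run the full error-sensitivity study over a cohort.

    The cohort is either enumerated from ``design`` or passed directly as a
    list of case specs (e.g. from :func:`mlcsens.cohort.sweep_cohort`).
    """
    from .cohort import enumerate_cohort

    config = config or StudyConfig()
    templates = templates or default_templates()
    registry = registry or AValueRegistry()
    if specs is None:
        if design is None:
            raise ValueError("need a design or explicit case specs")
        specs = enumerate_cohort(design)

    case_rows, change_rows, sens_rows = [], [], []
    for spec in specs:
        template = templates[spec.site]
        phantom, plan = realize_case(spec, templates,
                                     n_control_points=config.n_control_points)
        cx = plan_irregularity(plan)
        scale = plan.fractionation.n_fractions if config.dose_scale == "total" else 1.0
        structures = ["target"]
        if config.include_oars:
            structures += [o.name for o in template.oar_specs]

        ref_dose = compute_dose(plan, phantom, config.engine)
        ref_dvh = _dvhs(ref_dose, phantom, structures, scale, config.bin_width_gy)

        case_rows.append({
            "case_id": spec.case_id, "site": spec.site,
            "tps_profile": spec.tps_profile, "fractionation": spec.fractionation,
            "beam_type": spec.beam_type, "case_seed": spec.case_seed,
            "modulation": spec.modulation, "total_mu": plan.total_mu(),
            "mu_per_gy": cx.mu_per_gy, "pi": cx.pi,
            "ref_target_geud_gy": geud(ref_dvh["target"],
                                       registry.for_structure(spec.site, "target")),
        })

        deltas: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for mode in config.systematic_modes:
            for mag in config.error_grid:
                res = apply_systematic(plan, ErrorSpec(mode, mag))
                err_dose = compute_dose(res.plan, phantom, config.engine,
                                        calibration=ref_dose.calibration)
                err_dvh = _dvhs(err_dose, phantom, structures, scale,
                                config.bin_width_gy)
                for s in structures:
                    ch = geud_change(ref_dvh[s], err_dvh[s],
                                     registry.for_structure(spec.site, s))
                    delta = ch.delta_percent if s == "target" else ch.delta_gy
                    change_rows.append({
                        "case_id": spec.case_id, "structure": s, "mode": mode,
                        "magnitude_mm": mag, "delta_percent": ch.delta_percent,
                        "delta_gy": ch.delta_gy, "n_clamps": len(res.clamps),
                    })
                    deltas.setdefault((s, _DIRECTION[mode]), [(0.0, 0.0)]) \
                        .append((mag, delta))
        if spec.site in config.random_sites:
            for mi, mag in enumerate(config.error_grid):
                for rep in range(config.random_replicates):
                    seed = int((spec.case_seed + 104_729 * mi + rep + 1) % (2 ** 31))
                    res = apply_random(plan, ErrorSpec("random", mag, seed=seed))
                    err_dose = compute_dose(res.plan, phantom, config.engine,
                                            calibration=ref_dose.calibration)
                    err_dvh = _dvhs(err_dose, phantom, ["target"], scale,
                                    config.bin_width_gy)
                    ch = geud_change(ref_dvh["target"], err_dvh["target"],
                                     registry.for_structure(spec.site, "target"))
                    change_rows.append({
                        "case_id": spec.case_id, "structure": "target",
                        "mode": "random", "magnitude_mm": mag,
                        "delta_percent": ch.delta_percent, "delta_gy": ch.delta_gy,
                        "n_clamps": len(res.clamps),
                    })
                    deltas.setdefault(("target", "random"), [(0.0, 0.0)]) \
                        .append((mag, ch.delta_percent))

        for (s, direction), pts in deltas.items():
            units = "%/mm" if s == "target" else "Gy/mm"
            sens_rows.append(fit_sensitivity(pts, direction, case_id=spec.case_id,
                                             structure=s, units=units))
        # signed combined axis over both systematic directions (close < 0)
        for s in structures:
            pts = [(0.0, 0.0)]
            pts += [(-m, d) for m, d in deltas.get((s, "close"), [])[1:]]
            pts += [(m, d) for m, d in deltas.get((s, "open"), [])[1:]]
            if len(pts) >= 3:
                units = "%/mm" if s == "target" else "Gy/mm"
                sens_rows.append(fit_sensitivity(pts, "combined",
                                                 case_id=spec.case_id,
                                                 structure=s, units=units))

    cases = pd.DataFrame(case_rows)
    changes = pd.DataFrame(change_rows)
    sens = pd.DataFrame([vars(s) for s in sens_rows])

    tol_rows = []
    meta = cases.set_index("case_id")
    systematic_target = [
        s for s in sens_rows
        if s.structure == "target" and s.direction in ("close", "open")
    ]
    scen_of = {cid: (meta.loc[cid, "site"], meta.loc[cid, "tps_profile"],
                     meta.loc[cid, "fractionation"]) for cid in cases["case_id"]}
    for scenario in sorted(set(scen_of.values())):
        group = [s for s in systematic_target if scen_of[s.case_id] == scenario]
        if not group:
            continue
        t = derive_tolerance(group, config.threshold_pct,
                             scenario="/".join(scenario),
                             aggregation=config.aggregation)
        tol_rows.append({"site": scenario[0], "tps_profile": scenario[1],
                         "fractionation": scenario[2],
                         "tolerance_mm": t.tolerance_mm,
                         "threshold_pct": t.threshold_pct, "n_cases": t.n_cases})
    tolerances = pd.DataFrame(tol_rows)

    correlations = _correlation_table(cases, sens)
    comparisons = _comparison_table(cases, sens)

    manifest = {
        "design": ({k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(design).items()} if design else None),
        "config": {
            "error_grid": list(config.error_grid),
            "systematic_modes": list(config.systematic_modes),
            "random_sites": list(config.random_sites),
            "random_replicates": config.random_replicates,
            "threshold_pct": config.threshold_pct,
            "aggregation": config.aggregation,
            "n_control_points": config.n_control_points,
            "bin_width_gy": config.bin_width_gy,
            "dose_scale": config.dose_scale,
            "penumbra_sigma_mm": config.engine.penumbra_sigma_mm,
        },
        "n_cases": len(cases),
        "case_seeds": cases["case_seed"].tolist(),
    }
    return StudyResult(cases, changes, sens, tolerances, correlations,
                       comparisons, manifest)


def _mean_abs_target_slope(sens: pd.DataFrame) -> pd.Series:
    sel = sens[(sens["structure"] == "target")
               & sens["direction"].isin(["close", "open"])]
    return sel.groupby("case_id")["slope"].apply(lambda s: s.abs().mean())


def _correlation_table(cases: pd.DataFrame, sens: pd.DataFrame) -> pd.DataFrame:
    """Complexity-vs-sensitivity correlations, pooled and per TPS profile."""
    slope = _mean_abs_target_slope(sens)
    merged = cases.set_index("case_id").join(slope.rename("sensitivity"))
    rows = []
    groups = [("pooled", merged)] + [
        (profile, g) for profile, g in merged.groupby("tps_profile")
    ]
    for label, g in groups:
        if len(g) < 3:
            continue
        for x, y in (("mu_per_gy", "sensitivity"), ("pi", "sensitivity"),
                     ("mu_per_gy", "pi")):
            try:
                c = correlate(g[x], g[y], x_metric=x, y_metric=y)
            except ValueError:
                continue
            rows.append({"group": label, "x_metric": x, "y_metric": y,
                         "method": c.method, "coefficient": c.coefficient,
                         "p_value": c.p_value, "strength_band": c.strength_band,
                         "n": len(g)})
    return pd.DataFrame(rows)


def _comparison_table(cases: pd.DataFrame, sens: pd.DataFrame) -> pd.DataFrame:
    """Close-vs-open (paired) and profile (unpaired) sensitivity comparisons."""
    rows = []
    target = sens[sens["structure"] == "target"]
    close = target[target["direction"] == "close"].set_index("case_id")["slope"].abs()
    open_ = target[target["direction"] == "open"].set_index("case_id")["slope"].abs()
    common = close.index.intersection(open_.index)
    if len(common) >= 3:
        cmp_ = compare_groups(close.loc[common], open_.loc[common], paired=True)
        rows.append({"comparison": "close_vs_open", "test_used": cmp_.test_used,
                     "p_value": cmp_.p_value, "significant": cmp_.significant,
                     "n": len(common)})
    slope = _mean_abs_target_slope(sens)
    merged = cases.set_index("case_id").join(slope.rename("sensitivity"))
    profiles = merged["tps_profile"].unique()
    if len(profiles) == 2:
        a = merged[merged["tps_profile"] == profiles[0]]["sensitivity"]
        b = merged[merged["tps_profile"] == profiles[1]]["sensitivity"]
        if len(a) >= 3 and len(b) >= 3:
            cmp_ = compare_groups(a, b, paired=False)
            rows.append({"comparison": f"{profiles[0]}_vs_{profiles[1]}",
                         "test_used": cmp_.test_used, "p_value": cmp_.p_value,
                         "significant": cmp_.significant, "n": len(a) + len(b)})
    return pd.DataFrame(rows)


def evaluate_constraints(dvh_by_structure, template, fractionation: str,
                         prescription_gy: float) -> pd.DataFrame:
    """Evaluate the template's DVH reporting constraints on computed DVHs.

    Target percent-type limits are interpreted relative to the prescription;
    volume-type limits are reported as percent volume or absolute cm^3.
    """
    rows = []
    for c in template.dose_constraints:
        if c.fractionation not in ("any", fractionation):
            continue
        if c.structure not in dvh_by_structure:
            continue
        dvh = dvh_by_structure[c.structure]
        if c.kind in ("D_percent", "D_cc", "D_max"):
            val = dvh_query(dvh, c.kind, c.arg)
            if c.units == "%":
                val = 100.0 * val / prescription_gy
        else:  # V_gy
            frac = dvh_query(dvh, "V_gy", c.arg)
            val = frac * 100.0 if c.units == "%" else frac * dvh.total_volume_cc
        rows.append({"structure": c.structure, "kind": c.kind, "arg": c.arg,
                     "value": val, "limit": c.limit, "units": c.units,
                     "within": val <= c.limit if not (c.kind == "D_percent"
                                                      and c.arg <= 50) else None})
    return pd.DataFrame(rows)
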