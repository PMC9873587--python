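"""Posterior effect curves: how each covariate moves occupancy or detection.

Reads the draws written by 03_fit_occupancy_model.py and traces the
posterior mean and 95% BCI of the target probability along each covariate
(others held at their means), writing one CSV per curve under
results/effect_curves/.
"""

import os

import pandas as pd

import bombus_occupancy as bo
from bombus_occupancy.occupancy_model import MCMCConfig, ModelSpec, PosteriorSamples

ROOT = os.path.join(os.path.dirname(__file__), "..")
OUT = os.path.join(ROOT, "results", "effect_curves")


def load_samples() -> PosteriorSamples:
    draws_path = os.path.join(ROOT, "results", "draws.csv")
    if not os.path.exists(draws_path):
        raise SystemExit("run 03_fit_occupancy_model.py first")
    wide = pd.read_csv(draws_path)
    names = [c for c in wide.columns if c not in ("chain", "draw")]
    n_chains = wide["chain"].nunique()
    draws = wide[names].to_numpy().reshape(n_chains, -1, len(names))
    return PosteriorSamples(draws, names, MCMCConfig(), ModelSpec())


def main() -> None:
    samples = load_samples()
    survey_dir = os.path.join(ROOT, "results", "synthetic_survey")
    survey = bo.read_survey_csv(
        os.path.join(survey_dir, "sites.csv"),
        os.path.join(survey_dir, "visits.csv"),
        os.path.join(survey_dir, "detections.csv"),
    )
    design = bo.build_design(survey, ModelSpec())
    os.makedirs(OUT, exist_ok=True)
    jobs = [("occupancy", c) for c in design.occ_names if ":" not in c] + [
        ("detection", c) for c in design.det_names
    ]
    for target, covariate in jobs:
        curve = bo.effect_curve(samples, design, target, covariate)
        name = f"{target}_{covariate.replace(':', '_x_')}.csv"
        curve.to_frame().to_csv(os.path.join(OUT, name), index=False)
        swing = curve.mean[-1] - curve.mean[0]
        print(f"{target:9s} ~ {covariate:22s} mean probability moves "
              f"{curve.mean[0]:.2f} -> {curve.mean[-1]:.2f} (swing {swing:+.2f})")
    print(f"\nwrote {len(jobs)} curves to {OUT}")


if __name__ == "__main__":
    main()
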