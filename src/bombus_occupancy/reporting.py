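"""Posterior effect curves, model-variant sweeps and species accumulation.

Effect curves trace the posterior of occupancy or detection probability
along one covariate with every other covariate held at its mean (0 on the
standardized scale; burn status at a chosen stratum, default unburned) and
the species intercept at 0; interaction columns are recomputed as the
product of their parents at each grid point.  The grid is reported on the
original covariate scale via the recorded standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc_diagnostics import RHAT_THRESHOLD, summarize_posterior
from .occupancy_model import MCMCConfig, ModelSpec, PosteriorSamples, run_mcmc
from .survey_data import DesignInputs, DetectionTensor, SurveyData

__all__ = [
    "EffectCurve",
    "effect_curve",
    "run_model_variants",
    "species_accumulation",
]


@dataclass
class EffectCurve:
    """Posterior mean and 95% BCI of a probability along one covariate."""

    covariate: str
    target: str
    grid: np.ndarray  # original covariate scale
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grid": self.grid, "mean": self.mean, "lower": self.lower, "upper": self.upper}
        )


def _interaction_parents(name: str) -> tuple[str, str] | None:
    if ":" in name:
        a, b = name.split(":", 1)
        return a, b
    return None


def effect_curve(
    samples: PosteriorSamples,
    design: DesignInputs,
    target: str,
    covariate: str,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
    burn_status: int = 0,
) -> EffectCurve:
    """Posterior effect of one covariate on occupancy or detection probability.

    ``grid`` is in original covariate units (fraction canopy, raw flower
    count, hours, day of year); by default it spans the observed range.
    ``burn_status`` fixes the burn stratum when curves for a continuous
    covariate are drawn (the covariate itself overrides this when it IS
    burn status).
    """
    if target not in ("occupancy", "detection"):
        raise ValueError("target must be 'occupancy' or 'detection'")
    names = design.occ_names if target == "occupancy" else design.det_names
    records = design.standardization["occ" if target == "occupancy" else "det"]
    if covariate not in names:
        raise ValueError(f"covariate {covariate!r} not in the {target} design")
    rec = records[covariate]

    if grid is None:
        if covariate == "burn_status":
            grid = np.array([0.0, 1.0])
        else:
            X = design.X_occ if target == "occupancy" else design.X_det[design.mask]
            col = X[:, list(names).index(covariate)]
            grid = np.asarray(rec.original(np.linspace(col.min(), col.max(), n_grid)))
    grid = np.asarray(grid, float)
    z_grid = np.asarray(rec.standardize(grid), float)

    # covariate rows: everything at standardized 0, burn at the chosen stratum
    base = {n: 0.0 for n in names}
    if "burn_status" in base:
        base["burn_status"] = float(burn_status)
    rows = np.empty((grid.size, len(names)))
    for g, zval in enumerate(z_grid):
        vals = dict(base)
        vals[covariate] = float(zval)
        for n in names:
            parents = _interaction_parents(n)
            if parents is not None:
                vals[n] = vals[parents[0]] * vals[parents[1]]
        rows[g] = [vals[n] for n in names]

    prefix = "psi" if target == "occupancy" else "p"
    i0 = samples.parameter_names.index(f"{prefix}0")
    coef_idx = [samples.parameter_names.index(f"{prefix}_{n}") for n in names]
    flat = samples.draws.reshape(-1, samples.draws.shape[2])
    eta = flat[:, i0][:, None] + flat[:, coef_idx] @ rows.T  # (draws, grid)
    probs = expit(eta)
    lo, hi = np.quantile(probs, [0.025, 0.975], axis=0)
    return EffectCurve(covariate, target, grid, probs.mean(axis=0), lo, hi)


def run_model_variants(
    survey: SurveyData,
    variants: dict[str, ModelSpec] | list[ModelSpec],
    mcmc: MCMCConfig,
    method: str = "augmented",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Fit each model variant independently and compare shared parameters.

    Each variant gets its own sub-seed derived from ``mcmc.seed``.  The
    comparison frame lists, per (variant, parameter): posterior mean, BCI,
    excludes-zero flag, sign, and whether the variant converged (all
    rhat < 1.1); non-converged variants are flagged, never dropped.
    """
    if not variants:
        raise ValueError("need at least one model variant")
    if isinstance(variants, list):
        variants = {f"variant_{i}": v for i, v in enumerate(variants)}
    sub_seeds = np.random.SeedSequence(mcmc.seed).spawn(len(variants))
    summaries: dict[str, pd.DataFrame] = {}
    rows = []
    for (name, spec), ss in zip(variants.items(), sub_seeds):
        seed = int(ss.generate_state(1)[0] % (2**31))
        fit = run_mcmc(survey, spec, replace(mcmc, seed=seed), method=method)
        summary = summarize_posterior(fit)
        summaries[name] = summary
        converged = bool((summary["rhat"].dropna() < RHAT_THRESHOLD).all())
        for _, r in summary.iterrows():
            rows.append(
                {
                    "variant": name,
                    "parameter": r["parameter"],
                    "mean": r["mean"],
                    "bci_low": r["bci_low"],
                    "bci_high": r["bci_high"],
                    "excludes_zero": r["excludes_zero"],
                    "sign": int(np.sign(r["mean"])),
                    "variant_converged": converged,
                }
            )
    return summaries, pd.DataFrame(rows)


def species_accumulation(
    detections: DetectionTensor,
    n_permutations: int = 100,
    seed: int = 0,
    sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample-based rarefaction over site-visit samples.

    One sample = one (site, visit) that occurred.  For each m, the curve is
    the expected number of distinct species detected in the first m samples
    under a random ordering, averaged over ``n_permutations`` orderings.
    It is non-decreasing and ends at the total observed richness.  ``sites``
    optionally restricts to a subset of site indices (e.g. one burn
    stratum).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    j_idx, k_idx = np.nonzero(detections.mask)
    if sites is not None:
        keep = np.isin(j_idx, np.asarray(sites))
        j_idx, k_idx = j_idx[keep], k_idx[keep]
    n_samples = j_idx.size
    if n_samples == 0:
        raise ValueError("no site-visit samples in the detection tensor")
    sets = detections.values[:, j_idx, k_idx].astype(bool).T  # (samples, species)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_samples)
    for _ in range(n_permutations):
        order = rng.permutation(n_samples)
        seen = np.cumsum(sets[order], axis=0) > 0  # (samples, species)
        acc += seen.sum(axis=1)
    return pd.DataFrame(
        {"n_samples": np.arange(1, n_samples + 1), "expected_richness": acc / n_permutations}
    )
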