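"""Convergence diagnostics and posterior summaries.

Summaries follow the reporting conventions of the source analysis style:
posterior mean, equal-tailed 95% credible interval (empirical quantiles,
linear interpolation), a flag for intervals excluding zero, and the
classic Gelman-Rubin potential scale reduction factor with < 1.1 taken as
converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy_model import PosteriorSamples, occupancy_prob_matrix
from .survey_data import DesignInputs

__all__ = [
    "gelman_rubin",
    "summarize_posterior",
    "stratum_occupancy",
    "stratum_occupancy_draws",
    "mc_standard_errors",
    "RHAT_THRESHOLD",
]

#: Conventional convergence cutoff for the potential scale reduction factor.
RHAT_THRESHOLD = 1.1


def gelman_rubin(draws: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor for one parameter.

    ``draws`` is (chain, draw).  With per-chain length n, within-chain
    variance W (mean of per-chain sample variances) and between-chain
    variance B = n * var(chain means), the pooled variance estimate is
    V = (n-1)/n * W + B/n and rhat = sqrt(V / W).  Two identical
    non-constant chains give sqrt((n-1)/n) < 1; well-separated chains give
    values far above 1.
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("gelman_rubin needs a (chain, draw) array with >= 2 chains")
    m, n = draws.shape
    if n < 10:
        raise ValueError("gelman_rubin needs >= 10 draws per chain")
    W = float(np.mean(np.var(draws, axis=1, ddof=1)))
    if W <= 0.0:
        raise ValueError("degenerate chains: zero within-chain variance")
    B_over_n = float(np.var(np.mean(draws, axis=1), ddof=1))
    V = (n - 1) / n * W + B_over_n
    return float(np.sqrt(V / W))


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter mean, 95% BCI, excludes-zero flag and rhat.

    Chains are pooled for the mean and quantiles; rhat uses the chain
    structure.  ``excludes_zero`` is True iff 0 lies outside
    [2.5%, 97.5%] — the boldface criterion of the reporting convention.
    With a single chain rhat is NaN.
    """
    rows = []
    for idx, name in enumerate(samples.parameter_names):
        chains = samples.draws[:, :, idx]
        pooled = chains.reshape(-1)
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        try:
            rhat = gelman_rubin(chains)
        except ValueError:
            rhat = float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "bci_low": float(lo),
                "bci_high": float(hi),
                "excludes_zero": bool(lo > 0.0 or hi < 0.0),
                "rhat": rhat,
            }
        )
    return pd.DataFrame(rows)


def stratum_occupancy_draws(
    samples: PosteriorSamples, design: DesignInputs, stratum: int
) -> np.ndarray:
    """Community-mean occupancy in one burn stratum, one value per draw.

    For every retained draw, psi_ij is evaluated for each (species, site)
    with the site in the requested stratum and averaged; the result is the
    posterior sample of the stratum's community-mean occupancy.
    """
    in_stratum = design.site_burn == int(stratum)
    if not in_stratum.any():
        raise ValueError(f"no sites with burn_status == {stratum}")
    sub = np.flatnonzero(in_stratum)
    out = np.empty(samples.n_chains * samples.n_draws)
    for d, state in enumerate(samples.states()):
        psi = occupancy_prob_matrix(design, state)
        out[d] = psi[:, sub].mean()
    return out


def stratum_occupancy(
    samples: PosteriorSamples, design: DesignInputs, stratum: int
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and equal-tailed 95% BCI of stratum-mean occupancy."""
    draws = stratum_occupancy_draws(samples, design, stratum)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(draws.mean()), (float(lo), float(hi))


def mc_standard_errors(samples: PosteriorSamples) -> pd.DataFrame:
    """Monte-Carlo standard error of each posterior mean (sd / sqrt(ESS)).

    Effective sample sizes come from arviz; parameters whose chains are
    numerically constant get an SE of 0.
    """
    import arviz as az

    rows = []
    for idx, name in enumerate(samples.parameter_names):
        chains = samples.draws[:, :, idx]
        sd = float(chains.std(ddof=1))
        if sd == 0.0:
            rows.append({"parameter": name, "mean": float(chains.mean()), "mcse": 0.0, "ess": float("inf")})
            continue
        ess = float(np.asarray(az.ess(az.convert_to_dataset(chains))["x"]).item())
        ess = max(ess, 1.0)
        rows.append(
            {"parameter": name, "mean": float(chains.mean()), "mcse": sd / np.sqrt(ess), "ess": ess}
        )
    return pd.DataFrame(rows)
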