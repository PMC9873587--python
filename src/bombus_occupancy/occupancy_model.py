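"""Hierarchical multi-species site-occupancy model and its MCMC samplers.

The model: for species i, site j, visit k,

    x_ijk ~ Bernoulli(p_jk * z_ij)          (detection given presence)
    z_ij  ~ Bernoulli(psi_ij)               (latent occupancy)
    logit(psi_ij) = psi0 + a_i + X_occ[j] . beta_occ
    logit(p_jk)   = p0 + X_det[j,k] . beta_det

with a species random intercept a_i ~ Normal(0, sigma) on occupancy and a
shared detection probability across species (all species, when present,
are assumed equally detectable).  Priors: Normal(0, 10) on intercepts and
coefficients, Uniform(0, 10) on sigma; all configurable.

Two samplers target the same posterior:

* ``method="augmented"`` — data augmentation: exact Gibbs draws of the
  latent z matrix alternate with adaptive random-walk Metropolis updates
  of each parameter against the complete-data posterior.
* ``method="marginal"`` — the latent states are summed out analytically
  per site history and every parameter is updated by Metropolis against
  the marginal likelihood.

The marginal path doubles as a brute-force-verifiable oracle: for a single
history the marginal likelihood is psi * prod p^x (1-p)^(1-x) + (1-psi) *
[history all zero], which equals enumeration over z in {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import expit

from .survey_data import DesignInputs, SurveyData, build_design, DET_COVARIATES, OCC_COVARIATES

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ParamState",
    "MCMCConfig",
    "PosteriorSamples",
    "occupancy_prob",
    "occupancy_prob_matrix",
    "detection_prob",
    "detection_prob_matrix",
    "site_history_marginal_lik",
    "total_log_likelihood",
    "log_prior",
    "sample_latent_z",
    "run_mcmc",
    "center_species_effects",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings: Normal(0, coef_sd) fixed effects, Uniform(0, sigma_upper) sigma."""

    coef_sd: float = 10.0
    sigma_upper: float = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each linear predictor, plus prior settings.

    Variants with covariate subsets (robustness sweeps) are expressed by
    shortening either tuple.  A species-specific detection intercept is
    deliberately unsupported: with two visits per site the data cannot
    separate per-species detectability from occupancy.
    """

    occ_covariates: tuple[str, ...] = OCC_COVARIATES
    det_covariates: tuple[str, ...] = DET_COVARIATES
    species_random_intercept_on_occupancy: bool = True
    species_effects_on_detection: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.species_effects_on_detection:
            raise ValueError("species-specific detection effects are not supported")


@dataclass
class ParamState:
    """One complete set of model parameters."""

    psi0: float
    psi_coefs: np.ndarray
    psi_species: np.ndarray
    sigma_species: float
    p0: float
    p_coefs: np.ndarray

    def __post_init__(self) -> None:
        self.psi_coefs = np.atleast_1d(np.asarray(self.psi_coefs, float))
        self.psi_species = np.atleast_1d(np.asarray(self.psi_species, float))
        self.p_coefs = np.atleast_1d(np.asarray(self.p_coefs, float))
        if self.sigma_species <= 0:
            raise ValueError("sigma_species must be positive")

    @property
    def n_species(self) -> int:
        return self.psi_species.shape[0]

    def validate_against(self, design: DesignInputs) -> None:
        if self.psi_coefs.shape[0] != len(design.occ_names):
            raise ValueError(
                f"psi_coefs length {self.psi_coefs.shape[0]} != "
                f"{len(design.occ_names)} occupancy covariates"
            )
        if self.p_coefs.shape[0] != len(design.det_names):
            raise ValueError(
                f"p_coefs length {self.p_coefs.shape[0]} != "
                f"{len(design.det_names)} detection covariates"
            )


def param_names(spec: ModelSpec, species_names: list[str]) -> list[str]:
    """Flat parameter naming shared by both samplers and all summaries."""
    names = ["psi0"]
    names += [f"psi_{c}" for c in spec.occ_covariates]
    names += ["sigma_species"]
    names += [f"psi_species[{s}]" for s in species_names]
    names += ["p0"]
    names += [f"p_{c}" for c in spec.det_covariates]
    return names


def state_to_vector(params: ParamState) -> np.ndarray:
    return np.concatenate(
        [
            [params.psi0],
            params.psi_coefs,
            [params.sigma_species],
            params.psi_species,
            [params.p0],
            params.p_coefs,
        ]
    )


def vector_to_state(vec: np.ndarray, n_occ: int, n_species: int, n_det: int) -> ParamState:
    i = 0
    psi0 = vec[i]; i += 1
    psi_coefs = vec[i : i + n_occ]; i += n_occ
    sigma = vec[i]; i += 1
    a = vec[i : i + n_species]; i += n_species
    p0 = vec[i]; i += 1
    p_coefs = vec[i : i + n_det]; i += n_det
    return ParamState(psi0, psi_coefs.copy(), a.copy(), float(sigma), float(p0), p_coefs.copy())


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths, thinning, seed and proposal settings.

    Defaults are desk scale (3 chains x 20,000 iterations, 5,000 burn-in,
    thin 10); :meth:`paper_settings` returns the full-analysis protocol
    (3 chains x 1,000,000 iterations, 100,000 burn-in, thin 1000).  When
    ``iterations_include_burnin`` is False, ``n_iterations`` counts
    post-burn-in sweeps instead (both conventions exist in the wild).
    """

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    initial_scale: float = 0.5
    adapt: bool = True
    adapt_batch: int = 50
    target_acceptance: float = 0.44
    iterations_include_burnin: bool = True
    init_location_sd: float = 2.5
    max_init_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")
        if self.iterations_include_burnin and self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")

    @property
    def total_sweeps(self) -> int:
        if self.iterations_include_burnin:
            return self.n_iterations
        return self.burn_in + self.n_iterations

    @property
    def n_retained(self) -> int:
        return (self.total_sweeps - self.burn_in) // self.thin

    @classmethod
    def paper_settings(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_chains=3, n_iterations=1_000_000, burn_in=100_000, thin=1000, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained draws, shaped (chain, draw, parameter)."""

    draws: np.ndarray
    parameter_names: list[str]
    config: MCMCConfig
    spec: ModelSpec
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    method: str = "augmented"

    def __post_init__(self) -> None:
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter names must be unique")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("draw/parameter dimension mismatch")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Chain x draw array for one named parameter."""
        return self.draws[:, :, self.parameter_names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def to_dataframe(self):
        import pandas as pd

        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.parameter_names)
            df.insert(0, "draw", np.arange(self.n_draws))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def states(self):
        """Iterate (chain, draw) -> ParamState over all retained draws."""
        n_occ = len(self.spec.occ_covariates)
        n_det = len(self.spec.det_covariates)
        n_species = len(self.parameter_names) - n_occ - n_det - 3
        for c in range(self.n_chains):
            for d in range(self.n_draws):
                yield vector_to_state(self.draws[c, d], n_occ, n_species, n_det)


def center_species_effects(samples: PosteriorSamples) -> PosteriorSamples:
    """Re-express draws with mean-zero species deviations (post-processing).

    The intercept absorbs the per-draw mean of the species effects; the
    linear predictor, and hence every probability-scale summary, is
    unchanged.  Useful when reporting psi0 and the deviations separately.
    """
    names = samples.parameter_names
    sp_idx = [i for i, n in enumerate(names) if n.startswith("psi_species[")]
    draws = samples.draws.copy()
    mean_a = draws[:, :, sp_idx].mean(axis=2)
    draws[:, :, names.index("psi0")] += mean_a
    draws[:, :, sp_idx] -= mean_a[:, :, None]
    return replace(samples, draws=draws)


# ---------------------------------------------------------------------------
# probabilities and likelihood
# ---------------------------------------------------------------------------


def _occ_eta(design: DesignInputs, params: ParamState) -> np.ndarray:
    """Occupancy linear predictor, (species, site)."""
    base = design.X_occ @ params.psi_coefs  # (J,)
    return params.psi0 + params.psi_species[:, None] + base[None, :]


def _det_eta(design: DesignInputs, params: ParamState) -> np.ndarray:
    """Detection linear predictor, (site, visit); shared across species."""
    return params.p0 + design.X_det @ params.p_coefs


def occupancy_prob_matrix(design: DesignInputs, params: ParamState) -> np.ndarray:
    """psi_ij for every (species, site)."""
    return expit(_occ_eta(design, params))


def occupancy_prob(design: DesignInputs, params: ParamState, species: int, site: int) -> float:
    """psi for one (species, site): inverse-logit of the occupancy predictor."""
    eta = params.psi0 + params.psi_species[species] + design.X_occ[site] @ params.psi_coefs
    return float(expit(eta))


def detection_prob_matrix(design: DesignInputs, params: ParamState) -> np.ndarray:
    """p_jk for every (site, visit); identical for all species."""
    return expit(_det_eta(design, params))


def detection_prob(design: DesignInputs, params: ParamState, site: int, visit: int) -> float:
    eta = params.p0 + design.X_det[site, visit] @ params.p_coefs
    return float(expit(eta))


def site_history_marginal_lik(history, psi: float, p) -> float:
    """Marginal likelihood of one detection history, z summed out.

    Equals psi * prod_k p_k^x_k (1-p_k)^(1-x_k) + (1-psi) * [all x_k = 0],
    i.e. exact enumeration over the latent state z in {0, 1}.
    """
    x = np.asarray(history, float)
    p = np.asarray(p, float)
    if x.shape != p.shape:
        raise ValueError("history and per-visit detection probabilities differ in length")
    bern = np.prod(np.where(x > 0, p, 1.0 - p))
    return float(psi * bern + (1.0 - psi) * (1.0 if not x.any() else 0.0))


def total_log_likelihood(
    survey: SurveyData, design: DesignInputs, params: ParamState
) -> float:
    """Marginal log-likelihood summed over (species, site); masked visits excluded."""
    params.validate_against(design)
    x = survey.detections.values.astype(float)  # (S, J, K)
    mask = design.mask
    psi = occupancy_prob_matrix(design, params)  # (S, J)
    eta = _det_eta(design, params)  # (J, K)
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    per_visit = x * log_p[None] + (1.0 - x) * log_q[None]
    log_bern = (per_visit * mask[None]).sum(axis=2)  # (S, J)
    all_zero = (x * mask[None]).sum(axis=2) == 0
    lik = psi * np.exp(log_bern) + (1.0 - psi) * all_zero
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(lik)))


def log_prior(params: ParamState, spec: ModelSpec) -> float:
    """Joint prior log-density; -inf when sigma leaves its support."""
    pr = spec.priors
    if not (0.0 < params.sigma_species < pr.sigma_upper):
        return -np.inf
    fixed = np.concatenate([[params.psi0, params.p0], params.psi_coefs, params.p_coefs])
    lp = float(np.sum(_normal_logpdf(fixed, pr.coef_sd)))
    lp += -math.log(pr.sigma_upper)  # Uniform(0, upper)
    lp += float(np.sum(_normal_logpdf(params.psi_species, params.sigma_species)))
    return lp


def _normal_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * (np.asarray(x) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI


def sample_latent_z(history, psi: float, p, rng: np.random.Generator) -> int:
    """Draw the latent occupancy state given one detection history.

    Any detection implies presence; otherwise z ~ Bernoulli of the
    conditional P(z=1 | all-zero history) = psi*prod(1-p) / (psi*prod(1-p)
    + 1 - psi).
    """
    x = np.asarray(history, float)
    p = np.asarray(p, float)
    if x.shape != p.shape:
        raise ValueError("history and per-visit detection probabilities differ in length")
    if x.any():
        return 1
    q = psi * np.prod(1.0 - p)
    denom = q + (1.0 - psi)
    if denom <= 0.0:
        return 0
    return int(rng.random() < q / denom)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


class _AdaptiveScales:
    """Per-block random-walk scales, Robbins-Monro adapted during burn-in."""

    def __init__(self, blocks: list[str], initial: float, batch: int, target: float):
        self.scale = {b: initial for b in blocks}
        self.accepted = {b: 0 for b in blocks}
        self.proposed = {b: 0 for b in blocks}
        self.total_accepted = {b: 0 for b in blocks}
        self.total_proposed = {b: 0 for b in blocks}
        self.batch = batch
        self.target = target
        self.n_batches = 0

    def record(self, block: str, accepted: int, proposed: int = 1) -> None:
        self.accepted[block] += accepted
        self.proposed[block] += proposed
        self.total_accepted[block] += accepted
        self.total_proposed[block] += proposed

    def maybe_adapt(self, sweep: int) -> None:
        if sweep == 0 or sweep % self.batch:
            return
        self.n_batches += 1
        delta = min(0.25, 2.0 / math.sqrt(self.n_batches))
        for b, n in self.proposed.items():
            if n == 0:
                continue
            rate = self.accepted[b] / n
            self.scale[b] *= math.exp(delta if rate > self.target else -delta)
            self.accepted[b] = 0
            self.proposed[b] = 0

    def rates(self) -> dict[str, float]:
        return {
            b: (self.total_accepted[b] / n if (n := self.total_proposed[b]) else float("nan"))
            for b in self.scale
        }


def _initial_state(
    spec: ModelSpec, n_species: int, cfg: MCMCConfig, rng: np.random.Generator
) -> ParamState:
    sd = cfg.init_location_sd
    sigma = float(rng.uniform(0.25, min(4.0, spec.priors.sigma_upper)))
    return ParamState(
        psi0=float(rng.normal(0, sd)),
        psi_coefs=rng.normal(0, sd, len(spec.occ_covariates)),
        psi_species=rng.normal(0, sigma, n_species),
        sigma_species=sigma,
        p0=float(rng.normal(0, sd)),
        p_coefs=rng.normal(0, sd, len(spec.det_covariates)),
    )


def _occ_cdll(z: np.ndarray, eta: np.ndarray) -> float:
    """Complete-data occupancy log-likelihood sum z*eta - log(1+e^eta)."""
    return float(np.sum(z * eta - np.logaddexp(0.0, eta)))


class _AugmentedChain:
    """One data-augmented chain: Gibbs on z, Metropolis-within-Gibbs on params."""

    def __init__(self, survey, design, spec, cfg, rng):
        self.design = design
        self.spec = spec
        self.rng = rng
        self.x = survey.detections.values.astype(float)
        self.mask = design.mask
        self.any_det = (self.x * self.mask[None]).sum(axis=2) > 0  # (S, J)
        self.S, self.J, self.K = self.x.shape
        self.coef_sd = spec.priors.coef_sd
        blocks = (
            ["psi0"]
            + [f"psi_{c}" for c in spec.occ_covariates]
            + ["psi_species", "log_sigma", "p0"]
            + [f"p_{c}" for c in spec.det_covariates]
        )
        self.scales = _AdaptiveScales(blocks, cfg.initial_scale, cfg.adapt_batch, cfg.target_acceptance)
        for attempt in range(cfg.max_init_retries):
            self.state = _initial_state(spec, self.S, cfg, rng)
            if np.isfinite(log_prior(self.state, spec)):
                break
        else:  # pragma: no cover - prior support is wide
            raise RuntimeError("could not find a finite-posterior initial state")
        self.z = self.any_det.astype(float)
        self._update_z()

    # -- latent state ------------------------------------------------------
    def _update_z(self) -> None:
        st = self.state
        eta_det = _det_eta(self.design, st)
        log_q = np.where(self.mask, -np.logaddexp(0.0, eta_det), 0.0)
        q_all_miss = np.exp(log_q.sum(axis=1))  # (J,) prod over observed visits of 1-p
        psi = occupancy_prob_matrix(self.design, st)  # (S, J)
        num = psi * q_all_miss[None, :]
        denom = num + (1.0 - psi)
        cond = np.divide(num, denom, out=np.ones_like(num), where=denom > 0)
        draw = self.rng.random((self.S, self.J)) < cond
        self.z = np.where(self.any_det, 1.0, draw.astype(float))

    # -- occupancy block ---------------------------------------------------
    def _occ_eta(self) -> np.ndarray:
        return _occ_eta(self.design, self.state)

    def _update_occ_scalar(self, block: str, getter, setter) -> None:
        st = self.state
        cur = getter()
        eta = self._occ_eta()
        ll_cur = _occ_cdll(self.z, eta)
        prop = cur + self.scales.scale[block] * self.rng.normal()
        setter(prop)
        ll_prop = _occ_cdll(self.z, self._occ_eta())
        dprior = (cur * cur - prop * prop) / (2.0 * self.coef_sd**2)
        if math.log(self.rng.random()) < ll_prop - ll_cur + dprior:
            self.scales.record(block, 1)
        else:
            setter(cur)
            self.scales.record(block, 0)

    def _update_species_effects(self) -> None:
        st = self.state
        scale = self.scales.scale["psi_species"]
        base = self.design.X_occ @ st.psi_coefs  # (J,)
        eta = st.psi0 + st.psi_species[:, None] + base[None, :]
        prop_a = st.psi_species + scale * self.rng.normal(size=self.S)
        eta_prop = st.psi0 + prop_a[:, None] + base[None, :]
        ll_cur = np.sum(self.z * eta - np.logaddexp(0.0, eta), axis=1)
        ll_prop = np.sum(self.z * eta_prop - np.logaddexp(0.0, eta_prop), axis=1)
        sig2 = 2.0 * st.sigma_species**2
        dprior = (st.psi_species**2 - prop_a**2) / sig2
        accept = np.log(self.rng.random(self.S)) < ll_prop - ll_cur + dprior
        st.psi_species = np.where(accept, prop_a, st.psi_species)
        self.scales.record("psi_species", int(accept.sum()), self.S)

    def _update_sigma(self) -> None:
        st = self.state
        cur = st.sigma_species
        prop = cur * math.exp(self.scales.scale["log_sigma"] * self.rng.normal())
        if prop >= self.spec.priors.sigma_upper:
            self.scales.record("log_sigma", 0)
            return
        a = st.psi_species
        def logpost(s: float) -> float:
            return float(np.sum(_normal_logpdf(a, s))) + math.log(s)  # + Jacobian
        if math.log(self.rng.random()) < logpost(prop) - logpost(cur):
            st.sigma_species = prop
            self.scales.record("log_sigma", 1)
        else:
            self.scales.record("log_sigma", 0)

    # -- detection block ---------------------------------------------------
    def _det_counts(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.z[:, :, None] * self.mask[None]).sum(axis=0)  # occupied species per (j,k)
        s = (self.x * self.mask[None]).sum(axis=0)
        return s, m

    def _det_cdll(self, s, m) -> float:
        eta = _det_eta(self.design, self.state)
        return float(np.sum((s * eta - m * np.logaddexp(0.0, eta))[self.mask]))

    def _update_det_scalar(self, block: str, getter, setter, s, m) -> None:
        cur = getter()
        ll_cur = self._det_cdll(s, m)
        prop = cur + self.scales.scale[block] * self.rng.normal()
        setter(prop)
        ll_prop = self._det_cdll(s, m)
        dprior = (cur * cur - prop * prop) / (2.0 * self.coef_sd**2)
        if math.log(self.rng.random()) < ll_prop - ll_cur + dprior:
            self.scales.record(block, 1)
        else:
            setter(cur)
            self.scales.record(block, 0)

    # -- one sweep ---------------------------------------------------------
    def sweep(self, sweep_idx: int, adapting: bool) -> None:
        st = self.state
        self._update_z()
        self._update_occ_scalar(
            "psi0", lambda: st.psi0, lambda v: setattr(st, "psi0", v)
        )
        for idx, name in enumerate(self.spec.occ_covariates):
            self._update_occ_scalar(
                f"psi_{name}",
                lambda i=idx: st.psi_coefs[i],
                lambda v, i=idx: st.psi_coefs.__setitem__(i, v),
            )
        self._update_species_effects()
        self._update_sigma()
        s, m = self._det_counts()
        self._update_det_scalar(
            "p0", lambda: st.p0, lambda v: setattr(st, "p0", v), s, m
        )
        for idx, name in enumerate(self.spec.det_covariates):
            self._update_det_scalar(
                f"p_{name}",
                lambda i=idx: st.p_coefs[i],
                lambda v, i=idx: st.p_coefs.__setitem__(i, v),
                s,
                m,
            )
        if adapting:
            self.scales.maybe_adapt(sweep_idx)


class _MarginalChain:
    """One marginalized chain: scalar Metropolis on the z-summed likelihood."""

    def __init__(self, survey, design, spec, cfg, rng):
        self.survey = survey
        self.design = design
        self.spec = spec
        self.rng = rng
        self.S = survey.detections.n_species
        blocks = (
            ["psi0"]
            + [f"psi_{c}" for c in spec.occ_covariates]
            + [f"psi_species[{i}]" for i in range(self.S)]
            + ["log_sigma", "p0"]
            + [f"p_{c}" for c in spec.det_covariates]
        )
        self.scales = _AdaptiveScales(blocks, cfg.initial_scale, cfg.adapt_batch, cfg.target_acceptance)
        for attempt in range(cfg.max_init_retries):
            self.state = _initial_state(spec, self.S, cfg, rng)
            if np.isfinite(self._logpost()):
                break
        else:
            raise RuntimeError("could not find a finite-posterior initial state")
        self._lp = self._logpost()

    def _logpost(self) -> float:
        lp = log_prior(self.state, self.spec)
        if not np.isfinite(lp):
            return -np.inf
        return lp + total_log_likelihood(self.survey, self.design, self.state)

    def _try(self, block: str, getter, setter) -> None:
        cur = getter()
        prop = cur + self.scales.scale[block] * self.rng.normal()
        setter(prop)
        lp_prop = self._logpost()
        if math.log(self.rng.random()) < lp_prop - self._lp:
            self._lp = lp_prop
            self.scales.record(block, 1)
        else:
            setter(cur)
            self.scales.record(block, 0)

    def _update_sigma(self) -> None:
        st = self.state
        cur = st.sigma_species
        prop = cur * math.exp(self.scales.scale["log_sigma"] * self.rng.normal())
        st.sigma_species = prop
        lp_prop = self._logpost()
        # Jacobian of the log-scale walk: q(cur->prop)/q(prop->cur) = prop/cur
        if math.log(self.rng.random()) < lp_prop - self._lp + math.log(prop / cur):
            self._lp = lp_prop
            self.scales.record("log_sigma", 1)
        else:
            st.sigma_species = cur
            self.scales.record("log_sigma", 0)

    def sweep(self, sweep_idx: int, adapting: bool) -> None:
        st = self.state
        self._try("psi0", lambda: st.psi0, lambda v: setattr(st, "psi0", v))
        for idx in range(len(self.spec.occ_covariates)):
            self._try(
                f"psi_{self.spec.occ_covariates[idx]}",
                lambda i=idx: st.psi_coefs[i],
                lambda v, i=idx: st.psi_coefs.__setitem__(i, v),
            )
        for i in range(self.S):
            self._try(
                f"psi_species[{i}]",
                lambda i=i: st.psi_species[i],
                lambda v, i=i: st.psi_species.__setitem__(i, v),
            )
        self._update_sigma()
        self._try("p0", lambda: st.p0, lambda v: setattr(st, "p0", v))
        for idx in range(len(self.spec.det_covariates)):
            self._try(
                f"p_{self.spec.det_covariates[idx]}",
                lambda i=idx: st.p_coefs[i],
                lambda v, i=idx: st.p_coefs.__setitem__(i, v),
            )
        if adapting:
            self.scales.maybe_adapt(sweep_idx)


def run_mcmc(
    survey: SurveyData,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    method: Literal["augmented", "marginal"] = "augmented",
    design: DesignInputs | None = None,
) -> PosteriorSamples:
    """Fit the occupancy model by MCMC and return retained draws.

    Chains are initialized independently (overdispersed relative to the
    posterior) from sub-seeds derived deterministically from
    ``mcmc.seed``; proposal scales adapt during burn-in only, so retained
    draws form a valid Markov chain.  Acceptance rates far outside
    [0.05, 0.95] produce a logged warning, never a failure.
    """
    import warnings

    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    if design is None:
        design = build_design(survey, spec)
    names = param_names(spec, survey.species_names)
    n_ret = mcmc.n_retained
    if n_ret < 1:
        raise ValueError("config retains no draws")
    draws = np.empty((mcmc.n_chains, n_ret, len(names)))
    chain_cls = _AugmentedChain if method == "augmented" else _MarginalChain
    if method not in ("augmented", "marginal"):
        raise ValueError(f"unknown sampler method {method!r}")
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    rates_acc: dict[str, float] = {}
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain = chain_cls(survey, design, spec, mcmc, rng)
        kept = 0
        for t in range(1, mcmc.total_sweeps + 1):
            chain.sweep(t, adapting=mcmc.adapt and t <= mcmc.burn_in)
            if t > mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thin == 0 and kept < n_ret:
                draws[c, kept] = state_to_vector(chain.state)
                kept += 1
        rates = chain.scales.rates()
        for b, r in rates.items():
            rates_acc[f"chain{c}:{b}"] = r
        bad = {b: r for b, r in rates.items() if np.isfinite(r) and not 0.05 <= r <= 0.95}
        if bad:
            warnings.warn(f"chain {c}: acceptance rate outside [0.05, 0.95] for {sorted(bad)}")
    return PosteriorSamples(draws, names, mcmc, spec, rates_acc, method)
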