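"""Likelihood, priors and latent-state machinery against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import norm

import bombus_occupancy as bo
from bombus_occupancy.occupancy_model import occupancy_prob_matrix

from conftest import make_params


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)
# ---------------------------------------------------------------------------


def enumerate_history_lik(history, psi, p):
    """Sum over z in {0, 1} of P(z) * prod_k P(x_k | z)."""
    total = 0.0
    for z in (0, 1):
        term = psi if z else 1.0 - psi
        for x, pk in zip(history, p):
            prob = pk * z
            term *= prob if x else 1.0 - prob
        total += term
    return total


def enumerate_total_loglik(x, mask, psi, p):
    """Brute force over all joint z configurations of the complete-data likelihood.

    x: (S, J, K) detections; psi: (S, J); p: (J, K).  Sums the complete-data
    likelihood over every z in {0,1}^(S*J).
    """
    S, J, K = x.shape
    total = 0.0
    for zs in itertools.product((0, 1), repeat=S * J):
        z = np.array(zs).reshape(S, J)
        term = 1.0
        for i in range(S):
            for j in range(J):
                term *= psi[i, j] if z[i, j] else 1.0 - psi[i, j]
                for k in range(K):
                    if not mask[j, k]:
                        continue
                    prob = p[j, k] * z[i, j]
                    term *= prob if x[i, j, k] else 1.0 - prob
        total += term
    return math.log(total)


def random_instance(rng, S, J, K):
    """Random small survey + design + params for oracle comparisons."""
    import pandas as pd

    sites = pd.DataFrame(
        {
            "site_id": [f"s{j}" for j in range(J)],
            "burn_status": rng.integers(0, 2, J) if J > 1 else [1],
            "canopy_openness": rng.uniform(0.05, 0.95, J),
        }
    )
    rows = []
    for j in range(J):
        for k in range(K):
            rows.append(
                (f"s{j}", k + 1, int(rng.integers(0, 200)), int(rng.integers(0, 12)),
                 float(rng.uniform(281, 508)), int(rng.integers(150, 250)))
            )
    visits = pd.DataFrame(
        rows, columns=["site_id", "visit_index", "floral_abundance", "floral_richness",
                       "trap_hours", "julian_day"],
    )
    values = rng.integers(0, 2, (S, J, K)).astype(np.int8)
    mask = np.ones((J, K), bool)
    survey = bo.SurveyData(sites, visits, bo.DetectionTensor(values, mask, [f"sp{i}" for i in range(S)]))
    spec = bo.ModelSpec(occ_covariates=("burn_status",), det_covariates=("trap_hours",))
    design = bo.build_design(survey, spec)
    params = bo.ParamState(
        psi0=rng.normal(0, 1),
        psi_coefs=rng.normal(0, 1, 1),
        psi_species=rng.normal(0, 1, S),
        sigma_species=float(rng.uniform(0.5, 2)),
        p0=rng.normal(0, 1),
        p_coefs=rng.normal(0, 1, 1),
    )
    return survey, design, params


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------


class TestLinkFunctions:
    def test_all_zero_covariates_give_half(self, toy_survey):
        design = bo.build_design(toy_survey)
        params = make_params()
        # force exact zeros in the design row by zeroing the coefficients
        assert bo.occupancy_prob(design, params, 0, 0) == pytest.approx(0.5)
        assert bo.detection_prob(design, params, 0, 0) == pytest.approx(0.5)

    def test_fitted_intercepts_map_through_inverse_logit(self, toy_survey):
        """The study's reported intercepts land at the expected probabilities."""
        design = bo.build_design(toy_survey)
        occ = make_params(psi0=1.92)
        det = make_params(p0=-0.56)
        assert bo.occupancy_prob(design, occ, 0, 0) == pytest.approx(expit(1.92), abs=1e-12)
        assert bo.occupancy_prob(design, occ, 0, 0) == pytest.approx(0.8722, abs=2e-4)
        assert bo.detection_prob(design, det, 0, 0) == pytest.approx(expit(-0.56), abs=1e-12)
        assert bo.detection_prob(design, det, 0, 0) == pytest.approx(0.3635, abs=5e-5)

    def test_burned_site_linear_predictor_by_hand(self, small_sim):
        survey, _, _ = small_sim
        design = bo.build_design(survey)
        params = make_params(
            n_species=len(survey.species_names),
            psi_coefs=np.array([1.5, 0.8, -0.4, 0.0, 0.0]),
        )
        names = list(design.occ_names)
        site = int(np.flatnonzero(design.site_burn == 1)[0])
        c = design.X_occ[site, names.index("canopy_openness")]
        expected = expit(1.5 + 0.8 * c + (-0.4) * c)  # burn + (canopy + interaction)*c
        assert bo.occupancy_prob(design, params, 0, site) == pytest.approx(expected, rel=1e-12)

    def test_detection_identical_across_species(self, small_sim):
        survey, _, truth = small_sim
        design = bo.build_design(survey)
        p = bo.detection_prob_matrix(design, truth)
        # the matrix has no species dimension at all; scalar accessor agrees
        assert p.shape == (len(survey.sites), survey.detections.n_visits)
        assert bo.detection_prob(design, truth, 3, 1) == pytest.approx(p[3, 1])

    def test_psi_strictly_increasing_in_intercept(self, small_sim):
        survey, _, truth = small_sim
        design = bo.build_design(survey)
        lo = occupancy_prob_matrix(design, truth)
        bumped = make_params(
            n_species=truth.n_species,
            psi0=truth.psi0 + 0.7,
            psi_coefs=truth.psi_coefs,
            psi_species=truth.psi_species,
            sigma_species=truth.sigma_species,
            p_coefs=truth.p_coefs,
        )
        hi = occupancy_prob_matrix(design, bumped)
        assert (hi > lo).all()


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


class TestMarginalLikelihood:
    @pytest.mark.parametrize(
        "history, psi, p, expected",
        [
            ((0, 0), 0.5, (0.5, 0.5), 0.625),
            ((1, 0), 0.5, (0.5, 0.5), 0.125),
            ((1, 1), 1.0, (1.0, 1.0), 1.0),
        ],
    )
    def test_frozen_enumeration_values(self, history, psi, p, expected):
        assert bo.site_history_marginal_lik(history, psi, p) == pytest.approx(expected, abs=1e-12)
        assert enumerate_history_lik(history, psi, p) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bo.site_history_marginal_lik((0, 1), 0.5, (0.5,))

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=5),
        st.floats(0.0, 1.0),
        st.data(),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_z_enumeration_everywhere(self, history, psi, data):
        p = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=len(history), max_size=len(history))
        )
        got = bo.site_history_marginal_lik(history, psi, p)
        assert got == pytest.approx(enumerate_history_lik(history, psi, p), abs=1e-12)

    def test_total_loglik_single_term(self, rng=np.random.default_rng(5)):
        survey, design, params = random_instance(rng, 1, 1, 3)
        psi = occupancy_prob_matrix(design, params)
        p = bo.detection_prob_matrix(design, params)
        single = math.log(
            bo.site_history_marginal_lik(survey.detections.values[0, 0], psi[0, 0], p[0])
        )
        assert bo.total_log_likelihood(survey, design, params) == pytest.approx(single, rel=1e-12)

    def test_total_loglik_additive_over_sites(self):
        rng = np.random.default_rng(11)
        survey, design, params = random_instance(rng, 2, 3, 2)
        total = bo.total_log_likelihood(survey, design, params)
        psi = occupancy_prob_matrix(design, params)
        p = bo.detection_prob_matrix(design, params)
        by_hand = sum(
            math.log(bo.site_history_marginal_lik(survey.detections.values[i, j], psi[i, j], p[j]))
            for i in range(2)
            for j in range(3)
        )
        assert total == pytest.approx(by_hand, rel=1e-10)

    def test_total_loglik_vs_exhaustive_enumeration(self):
        """3 species x 4 sites x 2 visits: brute force over all 2^12 z configs."""
        rng = np.random.default_rng(77)
        survey, design, params = random_instance(rng, 3, 4, 2)
        psi = occupancy_prob_matrix(design, params)
        p = bo.detection_prob_matrix(design, params)
        brute = enumerate_total_loglik(
            survey.detections.values, design.mask, psi, p
        )
        assert bo.total_log_likelihood(survey, design, params) == pytest.approx(brute, abs=1e-10)

    def test_masked_visits_are_excluded(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        survey, design, params = random_instance(rng, 2, 2, 2)
        # drop site s1's second visit
        visits = survey.visits[~((survey.visits.site_id == "s1") & (survey.visits.visit_index == 2))]
        values = survey.detections.values.copy()
        mask = survey.detections.mask.copy()
        mask[1, 1] = False
        values[:, 1, 1] = 0
        trimmed = bo.SurveyData(
            survey.sites, visits.reset_index(drop=True),
            bo.DetectionTensor(values, mask, survey.species_names),
        )
        spec = bo.ModelSpec(occ_covariates=("burn_status",), det_covariates=("trap_hours",))
        design2 = bo.build_design(trimmed, spec)
        psi = occupancy_prob_matrix(design2, params)
        p = bo.detection_prob_matrix(design2, params)
        brute = enumerate_total_loglik(values, mask, psi, p)
        assert bo.total_log_likelihood(trimmed, design2, params) == pytest.approx(brute, abs=1e-10)


# ---------------------------------------------------------------------------
# prior and latent state
# ---------------------------------------------------------------------------


class TestPrior:
    def test_closed_form_at_zero(self):
        params = make_params()  # all zero, sigma = 1
        spec = bo.ModelSpec()
        expected = (
            13 * norm.logpdf(0.0, scale=10.0)  # psi0, p0, 5 occ + 6 det coefs
            + math.log(1 / 10)  # Uniform(0, 10) on sigma
            + 2 * norm.logpdf(0.0, scale=1.0)  # two species effects
        )
        assert bo.log_prior(params, spec) == pytest.approx(expected, rel=1e-12)

    def test_sigma_outside_support(self):
        spec = bo.ModelSpec()
        with pytest.raises(ValueError):
            make_params(sigma_species=-1.0)
        params = make_params(sigma_species=11.0)
        assert bo.log_prior(params, spec) == -np.inf

    def test_doubling_a_coefficient_decreases_density(self):
        spec = bo.ModelSpec()
        near = make_params(psi_coefs=np.array([1.0, 0, 0, 0, 0.0]))
        far = make_params(psi_coefs=np.array([2.0, 0, 0, 0, 0.0]))
        assert bo.log_prior(far, spec) < bo.log_prior(near, spec)


class TestLatentState:
    def test_detection_implies_presence(self):
        rng = np.random.default_rng(0)
        assert all(
            bo.sample_latent_z((1, 0), 0.1, (0.5, 0.5), rng) == 1 for _ in range(50)
        )

    def test_psi_zero_implies_absence(self):
        rng = np.random.default_rng(0)
        assert all(
            bo.sample_latent_z((0, 0), 0.0, (0.5, 0.5), rng) == 0 for _ in range(50)
        )

    def test_conditional_probability_by_bayes_rule(self):
        """(0,0) history with psi=p=0.5: P(z=1 | x) = 0.125 / 0.625 = 0.2."""
        rng = np.random.default_rng(42)
        n = 20_000
        draws = sum(bo.sample_latent_z((0, 0), 0.5, (0.5, 0.5), rng) for _ in range(n))
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(draws / n - 0.2) < 4 * se
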