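"""State-probability links, observation matrices and the marginal likelihood."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdom import likelihood as lk
from msdom.params import MSDOMParams


def brute_force_history_prob(y, psi, thetas):
    """Independent oracle: enumerate latent states in plain probability space."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim == 2:
        thetas = np.broadcast_to(thetas, (len(y), 4, 4))
    total = 0.0
    for s in range(4):
        prob = psi[s]
        for j, obs in enumerate(y):
            if obs is None:
                continue
            prob *= thetas[j][s, obs - 1]
        total += prob
    return total


def random_params(rng, parameterization):
    if parameterization == "full":
        return lk.occupancy_probs_full(rng.normal(0, 1.2, (3, 1)), np.ones((1, 1)))[0], \
            lk.observation_matrix(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
                                  rng.normal(0, 1.2, 3))
    psi = lk.occupancy_probs_reduced(rng.normal(0, 1.2, 1), rng.normal(0, 1.2, 1),
                                     np.ones((1, 1)))[0]
    return psi, lk.observation_matrix(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95))


class TestFullLink:
    def test_zero_coefficients_give_uniform_simplex(self):
        psi = lk.occupancy_probs_full(np.zeros((3, 2)), np.array([[1.0, 0.3]]))
        np.testing.assert_allclose(psi, 0.25)

    def test_intercepts_match_softmax_evaluation(self):
        # softmax(0, 1, 0, -1), frozen from direct evaluation
        psi = lk.occupancy_probs_full(np.array([[1.0], [0.0], [-1.0]]), np.ones((1, 1)))
        np.testing.assert_allclose(
            psi[0], [0.196612, 0.534447, 0.196612, 0.072329], atol=5e-7)

    def test_dominant_state_in_the_limit(self):
        psi = lk.occupancy_probs_full(np.array([[50.0], [0.0], [0.0]]), np.ones((1, 1)))
        assert psi[0, 1] > 1 - 1e-12 and psi[0, [0, 2, 3]].max() < 1e-12


class TestReducedLink:
    def test_independent_bernoulli_products(self):
        # theta_D = 0.3, theta_N = 0.4
        from scipy.special import logit
        psi = lk.occupancy_probs_reduced(np.array([logit(0.3)]), np.array([logit(0.4)]),
                                         np.ones((1, 1)))
        np.testing.assert_allclose(psi[0], [0.42, 0.18, 0.28, 0.12], atol=1e-12)

    def test_zero_day_use_kills_day_states(self):
        psi = lk.occupancy_probs_reduced(np.array([-60.0]), np.array([0.5]), np.ones((1, 1)))
        assert psi[0, 1] < 1e-20 and psi[0, 3] < 1e-20

    @given(st.floats(-4, 4), st.floats(-4, 4))
    @settings(deadline=None, max_examples=50)
    def test_daynight_state_is_product_of_marginals(self, bd, bn):
        psi = lk.occupancy_probs_reduced(np.array([bd]), np.array([bn]), np.ones((1, 1)))[0]
        assert abs(psi.sum() - 1) < 1e-12
        assert abs(psi[3] - (psi[1] + psi[3]) * (psi[2] + psi[3])) < 1e-12


class TestObservationMatrix:
    def test_structural_zeros_and_row_sums(self, rng):
        for _ in range(20):
            Theta = lk.observation_matrix(rng.uniform(0, 1), rng.uniform(0, 1),
                                          rng.normal(0, 2, 3))
            np.testing.assert_allclose(Theta.sum(axis=1), 1, atol=1e-12)
            np.testing.assert_allclose(Theta[0], [1, 0, 0, 0])
            assert Theta[1, 2] == Theta[1, 3] == 0
            assert Theta[2, 1] == Theta[2, 3] == 0

    def test_reduced_row4_half_half(self):
        Theta = lk.observation_matrix(0.5, 0.5)
        np.testing.assert_allclose(Theta[3], 0.25)

    def test_full_row4_symmetric_at_zero_logits(self):
        Theta = lk.observation_matrix(0.7, 0.2, np.zeros(3))
        np.testing.assert_allclose(Theta[3], 0.25)


class TestSiteLikelihood:
    def test_all_missing_is_uninformative(self):
        psi = np.array([0.1, 0.2, 0.3, 0.4])
        Theta = lk.observation_matrix(0.6, 0.7)
        assert lk.site_loglik([None, None, None], psi, Theta) == pytest.approx(0.0)

    def test_hand_enumerated_single_occasion(self):
        # y = (2), psi uniform, reduced detection p_D = p_N = 0.5:
        # only states 2 and 4 contribute: 0.25*0.5 + 0.25*0.25 = 0.1875
        psi = np.full(4, 0.25)
        Theta = lk.observation_matrix(0.5, 0.5)
        assert lk.site_loglik([2], psi, Theta) == pytest.approx(np.log(0.1875), abs=1e-12)

    def test_day_and_night_in_different_occasions_needs_state4(self):
        psi = np.full(4, 0.25)
        Theta = lk.observation_matrix(0.6, 0.7)
        expected = 0.25 * Theta[3, 1] * Theta[3, 2]
        assert lk.site_loglik([2, 3], psi, Theta) == pytest.approx(np.log(expected), abs=1e-12)

    def test_impossible_history_has_zero_likelihood(self):
        psi = np.array([0.5, 0.5, 0.0, 0.0])
        Theta = lk.observation_matrix(0.5, 0.5)
        Theta[3] = [1, 0, 0, 0]  # state 4 unreachable and undetectable
        assert lk.site_loglik([3], psi, Theta) == -np.inf

    @pytest.mark.parametrize("parameterization", ["full", "reduced"])
    def test_matches_brute_force_enumeration(self, rng, parameterization):
        for _ in range(300):
            psi, Theta = random_params(rng, parameterization)
            J = rng.integers(1, 5)
            y = [None if rng.random() < 0.2 else int(rng.integers(1, 5)) for _ in range(J)]
            expected = brute_force_history_prob(y, psi, Theta)
            got = lk.site_loglik(y, psi, Theta)
            assert np.exp(got) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("parameterization", ["full", "reduced"])
    def test_all_histories_sum_to_one(self, rng, parameterization):
        for _ in range(5):
            psi, Theta = random_params(rng, parameterization)
            for J in (1, 2, 3):
                total = sum(
                    np.exp(lk.site_loglik(list(y), psi, Theta))
                    for y in itertools.product([1, 2, 3, 4], repeat=J)
                )
                assert total == pytest.approx(1.0, abs=1e-10)


def test_full_model_can_reproduce_reduced_likelihood(rng):
    """Constraining the full links to the reduced composition gives the same
    marginal likelihood on arbitrary histories."""
    from scipy.special import expit
    for _ in range(20):
        bd, bn = rng.normal(0, 1.2, 2)
        th_d, th_n = expit(bd), expit(bn)
        psi_red = lk.occupancy_probs_reduced(np.array([bd]), np.array([bn]), np.ones((1, 1)))[0]
        beta_full = np.log(psi_red[1:] / psi_red[0]).reshape(3, 1)
        psi_full = lk.occupancy_probs_full(beta_full, np.ones((1, 1)))[0]
        p_day, p_night = rng.uniform(0.1, 0.9, 2)
        Theta_red = lk.observation_matrix(p_day, p_night)
        logits4 = np.log(Theta_red[3, 1:] / Theta_red[3, 0])
        Theta_full = lk.observation_matrix(p_day, p_night, logits4)
        y = [int(rng.integers(1, 5)) for _ in range(4)]
        assert lk.site_loglik(y, psi_full, Theta_full) == pytest.approx(
            lk.site_loglik(y, psi_red, Theta_red), abs=1e-10)
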