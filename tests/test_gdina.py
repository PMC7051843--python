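"""G-DINA response function and EM calibration against brute-force oracles."""

import itertools

import numpy as np
import pytest

import dcmscreen as dc
from dcmscreen import (
    FitOptions,
    ItemParams,
    QMatrix,
    e_step,
    eap_marginals,
    fit_em,
    irf,
    m_step,
    map_profile,
    marginal_loglik,
)
from dcmscreen.gdina import CalibrationResult, design_matrix

from conftest import small_population


def brute_force_posterior(X, probs_per_item, q_rows, nu):
    """Direct-summation oracle: plain-python loops over classes and items.

    ``probs_per_item[j]`` maps a reduced-profile tuple to P(X_j=1).
    Returns (posterior matrix, total marginal log-likelihood).
    """
    K = len(q_rows[0])
    classes = list(itertools.product((0, 1), repeat=K))
    N = len(X)
    post = np.zeros((N, len(classes)))
    total = 0.0
    for i in range(N):
        joint = []
        for l, alpha in enumerate(classes):
            lik = nu[l]
            for j, q in enumerate(q_rows):
                x = X[i][j]
                if x is None:
                    continue
                red = tuple(a for a, qq in zip(alpha, q) if qq)
                p = probs_per_item[j][red]
                lik *= p if x == 1 else (1 - p)
            joint.append(lik)
        s = sum(joint)
        total += np.log(s)
        post[i] = np.array(joint) / s
    return post, total


class TestIrf:
    @pytest.mark.parametrize(
        "deltas,reduced,expected",
        [
            ([0.2, 0.5], [1], 0.7),
            ([0.1, 0.2, 0.3, 0.2], [1, 1], 0.8),
            ([0.1, 0.2, 0.3, 0.2], [0, 0], 0.1),  # baseline: no required symptom
        ],
    )
    def test_identity_link_sum(self, deltas, reduced, expected):
        p = irf(ItemParams("j", np.array(deltas)), np.array(reduced))
        assert p == pytest.approx(expected, abs=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            irf(ItemParams("j", np.array([0.2, 0.5])), np.array([1, 0]))

    def test_delta_prob_bijection(self):
        rng = np.random.default_rng(0)
        for kstar in (1, 2, 3):
            p = rng.uniform(0.05, 0.95, size=2**kstar)
            ip = ItemParams.from_probs("j", p)
            np.testing.assert_allclose(ip.probs, p, atol=1e-12)
            M = design_matrix(kstar)
            np.testing.assert_allclose(M @ ip.deltas, p, atol=1e-12)


class TestMarginalLoglik:
    def test_single_item_hand_value(self):
        Q = QMatrix(np.array([[1]]))
        items = [ItemParams("1", np.array([0.2, 0.6]))]
        ll = marginal_loglik(np.array([[1.0]]), items, Q, np.array([0.5, 0.5]))
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_all_missing_is_zero(self):
        Q = QMatrix(np.array([[1], [1]]))
        items = [ItemParams(str(j), np.array([0.2, 0.6])) for j in (1, 2)]
        X = np.full((3, 2), np.nan)
        assert marginal_loglik(X, items, Q, np.array([0.5, 0.5])) == pytest.approx(0.0)

    def test_matches_brute_force_k2(self):
        rng = np.random.default_rng(7)
        q = np.array([[1, 0], [0, 1], [1, 1]])
        Q = QMatrix(q)
        items = [
            ItemParams("1", np.array([0.2, 0.5])),
            ItemParams("2", np.array([0.15, 0.6])),
            ItemParams.from_probs("3", np.array([0.1, 0.3, 0.4, 0.85])),
        ]
        nu = np.array([0.4, 0.1, 0.2, 0.3])
        X = rng.integers(0, 2, size=(20, 3)).astype(float)
        X[3, 1] = np.nan  # missing cells are skipped item-wise
        probs = [
            {(0,): 0.2, (1,): 0.7},
            {(0,): 0.15, (1,): 0.75},
            {(0, 0): 0.1, (0, 1): 0.3, (1, 0): 0.4, (1, 1): 0.85},
        ]
        Xl = [[None if np.isnan(v) else int(v) for v in row] for row in X]
        _, ll_oracle = brute_force_posterior(Xl, probs, q.tolist(), nu)
        assert marginal_loglik(X, items, Q, nu) == pytest.approx(ll_oracle, abs=1e-10)

    def test_non_binary_cell_rejected(self):
        Q = QMatrix(np.array([[1]]))
        items = [ItemParams("1", np.array([0.2, 0.6]))]
        with pytest.raises(ValueError):
            marginal_loglik(np.array([[2.0]]), items, Q, np.array([0.5, 0.5]))


class TestEStep:
    def test_single_item_bayes(self):
        Q = QMatrix(np.array([[1]]))
        items = [ItemParams("1", np.array([0.2, 0.6]))]
        post, counts, _ = e_step(np.array([[1.0]]), items, Q, np.array([0.5, 0.5]))
        np.testing.assert_allclose(post[0], [0.2, 0.8], atol=1e-12)
        Nbar, Rbar = counts[0]
        np.testing.assert_allclose(Nbar, [0.2, 0.8], atol=1e-12)
        np.testing.assert_allclose(Rbar, [0.2, 0.8], atol=1e-12)

    def test_uninformative_items_leave_prior(self):
        Q = QMatrix(np.array([[1], [1]]))
        items = [ItemParams(str(j), np.array([0.5, 0.0])) for j in (1, 2)]
        prior = np.array([0.3, 0.7])
        post, _, _ = e_step(np.array([[1.0, 0.0]]), items, Q, prior)
        np.testing.assert_allclose(post[0], prior, atol=1e-12)

    def test_matches_brute_force_k2(self):
        rng = np.random.default_rng(11)
        q = np.array([[1, 0], [0, 1], [1, 1], [1, 0]])
        Q = QMatrix(q)
        items = [
            ItemParams("1", np.array([0.2, 0.5])),
            ItemParams("2", np.array([0.15, 0.6])),
            ItemParams.from_probs("3", np.array([0.1, 0.3, 0.4, 0.85])),
            ItemParams("4", np.array([0.25, 0.5])),
        ]
        nu = np.array([0.25, 0.25, 0.3, 0.2])
        X = rng.integers(0, 2, size=(50, 4)).astype(float)
        probs = [
            {(0,): 0.2, (1,): 0.7},
            {(0,): 0.15, (1,): 0.75},
            {(0, 0): 0.1, (0, 1): 0.3, (1, 0): 0.4, (1, 1): 0.85},
            {(0,): 0.25, (1,): 0.75},
        ]
        Xl = [[int(v) for v in row] for row in X]
        post_oracle, ll_oracle = brute_force_posterior(Xl, probs, q.tolist(), nu)
        post, _, ll = e_step(X, items, Q, nu)
        np.testing.assert_allclose(post, post_oracle, atol=1e-10)
        assert ll == pytest.approx(ll_oracle, abs=1e-10)


class TestMStep:
    def test_closed_form_ratio(self):
        old = [ItemParams("1", np.array([0.5, 0.0]))]
        counts = [(np.array([50.0, 50.0]), np.array([10.0, 40.0]))]
        posterior = np.array([[1.0, 0.0]])
        new, nu = m_step(counts, old, posterior)
        np.testing.assert_allclose(new[0].probs, [0.2, 0.8], atol=1e-10)
        np.testing.assert_allclose(new[0].deltas, [0.2, 0.6], atol=1e-10)

    def test_point_mass_posterior_gives_point_mass_nu(self):
        old = [ItemParams("1", np.array([0.5, 0.0]))]
        counts = [(np.array([3.0, 0.0]), np.array([1.0, 0.0]))]
        posterior = np.tile([1.0, 0.0], (3, 1))
        _, nu = m_step(counts, old, posterior, monotone=False)
        np.testing.assert_allclose(nu, [1.0, 0.0])

    def test_two_attribute_delta_round_trip(self):
        counts = [(np.array([40.0, 30.0, 20.0, 10.0]),
                   np.array([4.0, 12.0, 9.0, 8.5]))]
        old = [ItemParams.from_probs("1", np.full(4, 0.5))]
        new, _ = m_step(counts, old, np.array([[0.25, 0.25, 0.25, 0.25]]),
                        monotone=False)
        np.testing.assert_allclose(new[0].probs, [0.1, 0.4, 0.45, 0.85], atol=1e-10)


class TestFitEm:
    def test_loglik_monotone_nondecreasing(self, small_fit):
        diffs = np.diff(small_fit.loglik_path)
        assert (diffs >= -1e-8).all()

    def test_posterior_and_nu_normalized(self, small_fit):
        np.testing.assert_allclose(small_fit.posterior.sum(axis=1), 1.0, atol=1e-8)
        assert small_fit.class_dist.sum() == pytest.approx(1.0, abs=1e-10)
        assert (small_fit.eap >= 0).all() and (small_fit.eap <= 1).all()

    def test_parameter_recovery_k3(self):
        Q = dc.default_qmatrix(20, 3)
        ds = dc.simulate_dataset(small_population(2000),
                                 dc.InstrumentSpec(Q=Q), seed=21)
        res = fit_em(ds.responses, Q, compute_covariance=False)
        true_p = np.array([p.probs for p in ds.true_params])
        est_p = np.array([p.probs for p in res.item_params])
        assert np.abs(true_p - est_p).mean() <= 0.05

    def test_beats_dense_grid_oracle(self):
        """EM log-likelihood dominates a 0.05-step grid over each item block."""
        Q = dc.default_qmatrix(4, 2)
        ds = dc.simulate_dataset(
            dc.PopulationSpec(N=50, K=2, prevalences=np.array([0.4, 0.5]),
                              latent_correlation=np.array([[1, 0.3], [0.3, 1.0]])),
            dc.InstrumentSpec(Q=Q), seed=5)
        res = fit_em(ds.responses, Q, compute_covariance=False)
        grid = np.arange(0.05, 1.0, 0.05)
        best = -np.inf
        for j in range(4):
            for p0 in grid:
                for p1 in grid:
                    items = list(res.item_params)
                    items[j] = ItemParams.from_probs(items[j].item_id,
                                                     np.array([p0, p1]))
                    ll = marginal_loglik(ds.responses, items, Q, res.class_dist)
                    best = max(best, ll)
        # true-parameter benchmark as a global sanity point
        ll_truth = marginal_loglik(
            ds.responses, ds.true_params, Q,
            np.full(4, 0.25))
        assert res.loglik >= best - 1e-6
        assert res.loglik >= ll_truth

    def test_single_attribute_matches_independent_latent_class_em(self):
        """K=1: the model is a plain 2-class latent-class model; compare with
        an independently coded EM oracle on the same data."""
        Q = dc.default_qmatrix(4, 1)
        rng = np.random.default_rng(9)
        alpha = (rng.random(300) < 0.4).astype(int)
        p0 = np.array([0.2, 0.15, 0.25, 0.1])
        p1 = np.array([0.7, 0.8, 0.65, 0.75])
        X = (rng.random((300, 4)) < np.where(alpha[:, None] == 1, p1, p0)).astype(float)

        res = fit_em(X, Q, FitOptions(monotone=False, tol=1e-7, loglik_tol=1e-10,
                                      max_iter=3000), compute_covariance=False)

        # oracle: textbook 2-class EM, written without the package machinery
        q = np.full(2, 0.5)
        P = np.array([[0.3, 0.3, 0.3, 0.3], [0.6, 0.6, 0.6, 0.6]])
        for _ in range(3000):
            lik = np.stack([
                np.prod(np.where(X == 1, P[c], 1 - P[c]), axis=1) * q[c]
                for c in (0, 1)], axis=1)
            w = lik / lik.sum(axis=1, keepdims=True)
            q = w.mean(axis=0)
            P = np.clip((w.T @ X) / w.sum(axis=0)[:, None], 1e-4, 1 - 1e-4)
        ll_oracle = np.log(np.stack([
            np.prod(np.where(X == 1, P[c], 1 - P[c]), axis=1) * q[c]
            for c in (0, 1)], axis=1).sum(axis=1)).sum()
        assert res.loglik == pytest.approx(ll_oracle, abs=1e-6)

    def test_missing_responses_handled(self, small_dataset):
        X = small_dataset.responses.copy()
        rng = np.random.default_rng(2)
        X[rng.random(X.shape) < 0.05] = np.nan
        res = fit_em(X, small_dataset.qmatrix, compute_covariance=False)
        assert res.converged
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_input_guards(self, small_dataset):
        Q = small_dataset.qmatrix
        with pytest.raises(ValueError):
            fit_em(small_dataset.responses[:1], Q)
        X = small_dataset.responses[:5].copy()
        X[0] = np.nan
        with pytest.raises(ValueError):
            fit_em(X, Q)


class TestPosteriorSummaries:
    def _fake_result(self, posterior, K):
        Q = dc.default_qmatrix(max(2, K), K)
        return CalibrationResult(
            item_params=[], class_dist=np.full(2**K, 2.0**-K),
            posterior=posterior, eap=None, loglik=0.0,
            loglik_path=np.zeros(1), n_iter=0, converged=True,
            covariance=[], qmatrix=Q, options=FitOptions())

    def test_point_mass_and_uniform_eap(self):
        K = 3
        post = np.zeros((2, 8))
        post[0, 4] = 1.0  # profile (1,0,0)
        post[1] = 1 / 8
        res = self._fake_result(post, K)
        P = eap_marginals(res)
        np.testing.assert_allclose(P[0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(P[1], [0.5, 0.5, 0.5], atol=1e-12)

    def test_eap_matches_exhaustive_sum(self):
        rng = np.random.default_rng(4)
        post = rng.dirichlet(np.ones(8), size=5)
        res = self._fake_result(post, 3)
        P = eap_marginals(res)
        A = dc.enumerate_profiles(3)
        for i in range(5):
            for k in range(3):
                expected = sum(post[i, l] for l in range(8) if A[l, k] == 1)
                assert P[i, k] == pytest.approx(expected, abs=1e-12)

    def test_map_profile_tie_breaks_low_index(self):
        post = np.zeros((1, 8))
        post[0, 2] = post[0, 6] = 0.5
        res = self._fake_result(post, 3)
        assert map_profile(res)[0].tolist() == [0, 1, 0]  # index 2 wins

    def test_map_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(6)
        post = rng.dirichlet(np.ones(8), size=10)
        res = self._fake_result(post, 3)
        A = dc.enumerate_profiles(3)
        np.testing.assert_array_equal(map_profile(res),
                                      A[post.argmax(axis=1)])
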