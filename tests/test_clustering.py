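import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from aucseg import (
    AucsegError,
    fit_fcm,
    fit_gmm,
    fit_kmeans,
    highest_intensity_cluster_mask,
)
from aucseg.clustering import fcm_memberships, fit_backend, BACKENDS

from _oracles import kmeans_bruteforce_objective


def three_triplets(rng=None):
    """12 samples in three well-separated triplets."""
    base = np.repeat([0.1, 0.5, 0.9], 4)
    jitter = np.array([-0.01, 0.0, 0.01, 0.02] * 3)
    return base + jitter


class TestKMeans:
    def test_perfectly_separable_pairs(self):
        result = fit_kmeans(np.array([0.1, 0.1, 0.9, 0.9]), k=2)
        np.testing.assert_allclose(np.sort(result.centroids), [0.1, 0.9])
        assert result.objective_trace[-1] == pytest.approx(0.0, abs=1e-12)

    def test_k1_is_sample_mean(self):
        x = np.array([0.2, 0.4, 0.9])
        result = fit_kmeans(x, k=1)
        assert result.centroids[0] == pytest.approx(x.mean())

    def test_recovers_generating_partition_and_global_objective(self):
        x = three_triplets()
        result = fit_kmeans(x, k=3)
        expected_labels = np.repeat([0, 1, 2], 4)
        np.testing.assert_array_equal(result.labels, expected_labels)
        assert result.objective_trace[-1] == pytest.approx(
            kmeans_bruteforce_objective(x, 3), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_bruteforce_and_is_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(1, 4))
        x = rng.uniform(0, 1, n)
        result = fit_kmeans(x, k, seed=seed)
        trace = result.objective_trace
        assert np.all(np.diff(trace) <= 1e-12)
        assert trace[-1] == pytest.approx(kmeans_bruteforce_objective(x, k), rel=1e-9)

    def test_matches_sklearn_inertia_on_moderate_instance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.2, 300)
        ours = fit_kmeans(x, 4, seed=0).objective_trace[-1]
        ref = KMeans(n_clusters=4, n_init=10, random_state=0).fit(x[:, None]).inertia_
        # our stop rule is a relative-objective tolerance, so allow a small
        # convergence gap either way
        assert ours == pytest.approx(ref, rel=5e-3)

    def test_excess_k_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reducing"):
            result = fit_kmeans(np.array([0.3, 0.3, 0.7]), k=5)
        assert result.k == 2

    def test_empty_samples_rejected(self):
        with pytest.raises(AucsegError, match="no samples"):
            fit_kmeans(np.array([]), k=2)

    def test_minibatch_variant_on_separable_data(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.2, 0.01, 2000), rng.normal(0.8, 0.01, 2000)])
        result = fit_kmeans(x, 2, batch_size=256, seed=0)
        assert result.method == "minibatch_kmeans"
        np.testing.assert_allclose(np.sort(result.centroids), [0.2, 0.8], atol=0.01)


class TestFCM:
    def test_hand_computed_membership(self):
        # d(0, 0.25)=0.25, d(0, 0.75)=0.75 -> u = 1/(1+(0.25/0.75)^2) = 0.9
        u = fcm_memberships(np.array([0.0, 1.0]), np.array([0.25, 0.75]), m=2.0)
        assert u[0, 0] == pytest.approx(0.9)
        assert u[0, 1] == pytest.approx(0.1)
        assert u[1, 1] == pytest.approx(0.9)

    def test_zero_distance_gives_full_membership(self):
        u = fcm_memberships(np.array([0.25]), np.array([0.25, 0.75]), m=2.0)
        np.testing.assert_allclose(u[0], [1.0, 0.0])

    def test_equidistant_sample_splits_evenly(self):
        u = fcm_memberships(np.array([0.5]), np.array([0.25, 0.75]), m=2.0)
        np.testing.assert_allclose(u[0], [0.5, 0.5])

    def test_rows_sum_to_one_every_iteration(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 500)
        result, membership = fit_fcm(x, c=3, seed=0)
        assert membership.row_sum_error_trace.max() < 1e-9
        np.testing.assert_allclose(membership.memberships.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(result.labels, membership.hard_labels())

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(AucsegError, match="m must be > 1"):
            fit_fcm(np.array([0.1, 0.9]), c=2, m=1.0)

    def test_nonconvergence_warns_and_flags(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="did not converge"):
            result, _ = fit_fcm(rng.uniform(0, 1, 200), c=3, max_iter=1)
        assert not result.converged

    def test_small_fuzzifier_agrees_with_kmeans_on_separable_data(self):
        x = three_triplets()
        fcm_labels = fit_fcm(x, c=3, m=1.05, seed=0)[0].labels
        km_labels = fit_kmeans(x, 3, seed=0).labels
        np.testing.assert_array_equal(fcm_labels, km_labels)


class TestGMM:
    def test_single_component_closed_form(self):
        x = np.array([0.1, 0.2, 0.6])
        result, params = fit_gmm(x, k=1)
        assert params.means[0] == pytest.approx(x.mean())
        assert params.variances[0] == pytest.approx(x.var())
        assert params.weights[0] == pytest.approx(1.0)

    def test_two_separated_groups(self):
        x = np.array([0.00, 0.01, 0.02, 0.98, 0.99, 1.00])
        result, params = fit_gmm(x, k=2)
        np.testing.assert_allclose(params.means, [0.01, 0.99], atol=0.005)
        np.testing.assert_allclose(params.weights, [0.5, 0.5], atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_log_likelihood_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 0.2, 400)
        _, params = fit_gmm(x, k=3, seed=seed)
        trace = params.log_likelihood_trace
        slack = 1e-7 * np.maximum(1.0, np.abs(trace[:-1]))
        assert np.all(np.diff(trace) >= -slack)
        assert params.weights.sum() == pytest.approx(1.0)

    def test_recovers_known_two_component_mixture(self):
        rng = np.random.default_rng(42)
        x = np.concatenate(
            [rng.normal(0.2, 0.05, 5000), rng.normal(0.8, 0.05, 5000)]
        )
        _, params = fit_gmm(x, k=2, seed=0)
        np.testing.assert_allclose(params.means, [0.2, 0.8], atol=0.02)

    def test_agrees_with_sklearn_mixture_oracle(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.3, 0.04, 3000), rng.normal(0.7, 0.04, 3000)])
        _, params = fit_gmm(x, k=2, seed=0)
        ref = GaussianMixture(n_components=2, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(
            params.means, np.sort(ref.means_.ravel()), atol=0.005
        )

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(AucsegError, match="exceeds"):
            fit_gmm(np.array([0.1, 0.9]), k=3)

    def test_variance_floor_clamped_with_warning(self):
        x = np.array([0.2] * 5 + [0.8] * 5)
        with pytest.warns(UserWarning, match="clamped"):
            _, params = fit_gmm(x, k=2, var_floor=1e-6)
        assert np.all(params.variances >= 1e-6)


class TestSubclassSelection:
    def test_selects_highest_centroid(self):
        support = np.zeros((1, 1, 4), dtype=bool)
        support[0, 0, :] = True
        result = fit_kmeans(np.array([0.2, 0.2, 0.8, 0.8]), 2)
        mask = highest_intensity_cluster_mask(result, support)
        np.testing.assert_array_equal(mask[0, 0], [False, False, True, True])

    def test_single_subclass_selects_entire_support(self):
        support = np.zeros((1, 1, 3), dtype=bool)
        support[0, 0, :] = True
        result = fit_kmeans(np.array([0.5, 0.5, 0.5]), 1)
        with pytest.warns(UserWarning, match="entire support"):
            mask = highest_intensity_cluster_mask(result, support)
        np.testing.assert_array_equal(mask, support)

    def test_centroid_tie_broken_toward_larger_subclass(self):
        from aucseg.clustering import ClusterResult

        result = ClusterResult(
            labels=np.array([0, 1, 1]),
            k=2,
            centroids=np.array([0.5, 0.5]),
            method="kmeans",
            n_iter=1,
            converged=True,
        )
        support = np.ones((1, 1, 3), dtype=bool)
        mask = highest_intensity_cluster_mask(result, support)
        np.testing.assert_array_equal(mask[0, 0], [False, True, True])

    def test_sample_count_mismatch_rejected(self):
        result = fit_kmeans(np.array([0.1, 0.9]), 2)
        with pytest.raises(AucsegError, match="support"):
            highest_intensity_cluster_mask(result, np.ones((2, 2, 2), dtype=bool))


@pytest.mark.parametrize("method", BACKENDS)
def test_backends_deterministic_given_seed(method):
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 1500)
    a = fit_backend(method, x, 3, seed=5)
    b = fit_backend(method, x, 3, seed=5)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.centroids, b.centroids)
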