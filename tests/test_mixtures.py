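"""Mixture back-ends: recovery of planted components, automatic component
pruning, axial invariance, determinism and the shared fit contract."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score as ari

from methclust.distributions import (
    VmfParams,
    WatsonParams,
    sample_vmf,
    sample_watson,
    sample_uniform_sphere,
)
from methclust.mixtures import (
    fit_vbgmm,
    fit_vbbmm,
    fit_rpbmm,
    fit_vbvmm,
    fit_vbwmm,
    BetaMixture,
)


def check_contract(fit):
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)
    assert fit.labels.min() >= 1 and fit.labels.max() <= fit.M_effective
    assert fit.responsibilities.shape[1] == fit.M_effective


class TestVbgmm:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(0)
        Y = np.vstack([rng.normal(i * 10, 1.0, (100, 3)) for i in range(3)])
        truth = np.repeat([0, 1, 2], 100)
        fit = fit_vbgmm(Y.T, M_init=10, prune=0.01, seed=0)
        check_contract(fit)
        assert fit.M_effective == 3
        assert ari(truth, fit.labels) >= 0.95

    def test_single_gaussian_prunes_to_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 1, (200, 3))
        fit = fit_vbgmm(Y.T, M_init=10, prune=0.01, seed=0)
        assert fit.M_effective == 1

    def test_degenerate_dimension_error(self):
        with pytest.raises(ValueError, match="reduce"):
            fit_vbgmm(np.random.default_rng(0).normal(size=(10, 5)), M_init=3, seed=0)


class TestVbbmm:
    def test_three_beta_components(self, beta_blobs):
        Y, truth = beta_blobs()
        fit = fit_vbbmm(Y, M_init=15, prune=0.01, seed=0)
        check_contract(fit)
        assert fit.M_effective == 3
        assert ari(truth, fit.labels) >= 0.9
        # parameter recovery: component means within 0.05
        means = np.sort(fit.component_params["means"].mean(axis=1))
        np.testing.assert_allclose(means, [0.1, 0.5, 0.9], atol=0.05)

    def test_single_component_not_split(self, beta_blobs):
        Y, _ = beta_blobs(means=(0.4,), n_each=200)
        fit = fit_vbbmm(Y, M_init=15, prune=0.01, seed=0)
        assert fit.M_effective == 1

    def test_elbo_surrogate_monotone(self, beta_blobs):
        Y, _ = beta_blobs()
        fit = fit_vbbmm(Y, M_init=15, prune=0.01, seed=0)
        assert np.all(np.diff(fit.elbo_trace) >= -1e-8)

    def test_pruning_monotone_in_threshold(self, beta_blobs):
        Y, _ = beta_blobs()
        m = [fit_vbbmm(Y, 15, prune, seed=0).M_effective for prune in (0.005, 0.01, 0.05)]
        assert m[0] >= m[1] >= m[2]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fit_vbbmm(np.array([[0.0, 0.5], [0.5, 0.5]]), seed=0)


class TestRpbmm:
    def test_unimodal_no_split(self, beta_blobs):
        Y, _ = beta_blobs(means=(0.4,), n_each=200)
        fit = fit_rpbmm(Y, seed=0)
        assert fit.M_effective == 1
        assert fit.leaf_paths == ["r"]

    def test_bimodal_single_split(self, beta_blobs):
        Y, truth = beta_blobs(means=(0.1, 0.9), n_each=100)
        fit = fit_rpbmm(Y, seed=0)
        assert fit.M_effective == 2
        assert sorted(fit.leaf_paths) == ["rL", "rR"]
        assert ari(truth, fit.labels) == 1.0

    def test_three_components_recovered(self, beta_blobs):
        Y, truth = beta_blobs()
        fit = fit_rpbmm(Y, seed=0)
        check_contract(fit)
        assert fit.M_effective == 3
        assert ari(truth, fit.labels) >= 0.9
        assert all(p.startswith("r") for p in fit.leaf_paths)

    def test_deterministic(self, beta_blobs):
        Y, _ = beta_blobs()
        a = fit_rpbmm(Y, seed=0)
        b = fit_rpbmm(Y, seed=0)
        assert np.array_equal(a.labels, b.labels)
        assert a.leaf_paths == b.leaf_paths


class TestVbvmm:
    def test_three_vmf_clusters(self):
        mus = np.eye(3)
        Z = np.vstack([sample_vmf(VmfParams(mus[i], 400.0), 100, seed=10 + i) for i in range(3)])
        truth = np.repeat([0, 1, 2], 100)
        fit = fit_vbvmm(Z, M_init=10, prune=0.01, seed=0)
        check_contract(fit)
        assert fit.M_effective == 3
        assert ari(truth, fit.labels) >= 0.95
        # recovered directions within 5 degrees of the planted axes
        est = fit.component_params["directions"]
        for mu in mus:
            best = np.max(np.abs(est @ mu))
            assert np.degrees(np.arccos(np.clip(best, -1, 1))) < 5.0

    def test_uniform_sphere_collapses(self):
        Z = sample_uniform_sphere(3, 200, np.random.default_rng(5))
        fit = fit_vbvmm(Z, M_init=10, prune=0.01, seed=0)
        assert fit.M_effective <= 2

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_vbvmm(np.ones((10, 3)), seed=0)


@pytest.fixture(scope="module")
def axial_data():
    mus = np.eye(3)
    Z = np.vstack([sample_watson(WatsonParams(mus[i], 40.0), 100, seed=20 + i)
                   for i in range(2)])
    return Z, np.repeat([0, 1], 100)


class TestVbwmm:

    def test_two_axial_clusters(self, axial_data):
        Z, truth = axial_data
        fit = fit_vbwmm(Z, M_init=10, prune=0.01, seed=0)
        check_contract(fit)
        assert fit.M_effective == 2
        assert ari(truth, fit.labels) >= 0.9

    def test_sign_flip_invariance(self, axial_data):
        Z, _ = axial_data
        fit = fit_vbwmm(Z, M_init=10, prune=0.01, seed=0)
        flip = np.random.default_rng(9).random(len(Z)) < 0.5
        Z2 = Z.copy()
        Z2[flip] *= -1.0
        fit2 = fit_vbwmm(Z2, M_init=10, prune=0.01, seed=0)
        assert np.array_equal(fit.labels, fit2.labels)

    def test_antipodal_pair_one_cluster_where_vmf_sees_two(self):
        rng = np.random.default_rng(3)
        Z = np.vstack([np.tile([0, 0, 1.0], (50, 1)), np.tile([0, 0, -1.0], (50, 1))])
        Z += rng.normal(0, 0.01, Z.shape)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        assert fit_vbwmm(Z, M_init=5, prune=0.01, seed=0).M_effective == 1
        assert fit_vbvmm(Z, M_init=5, prune=0.01, seed=0).M_effective == 2


class TestSummary:
    def test_summary_mentions_components_and_sizes(self, beta_blobs):
        Y, _ = beta_blobs()
        text = fit_vbbmm(Y, 15, 0.01, seed=0).summary()
        assert "components kept   : 3" in text
        assert "cluster sizes" in text
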