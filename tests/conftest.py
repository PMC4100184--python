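import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln


@pytest.fixture(scope="session")
def sphere_integral():
    """Integrate a log-density depending only on t = mu.x over S^{K-1}."""

    def compute(log_density_of_t, K):
        log_area_sub = np.log(2.0) + ((K - 1) / 2.0) * np.log(np.pi) - gammaln((K - 1) / 2.0)

        def integrand(t):
            return np.exp(log_density_of_t(t)) * (1.0 - t**2) ** ((K - 3) / 2.0)

        val, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
        return np.exp(log_area_sub) * val

    return compute


@pytest.fixture(scope="session")
def beta_blobs():
    """3 well-separated 2-D beta clusters (means 0.1/0.5/0.9, concentration 50)."""

    def make(means=(0.1, 0.5, 0.9), n_each=100, conc=50.0, seed=3):
        rng = np.random.default_rng(seed)
        chunks, labels = [], []
        for i, m in enumerate(means):
            chunks.append(rng.beta(m * conc, (1 - m) * conc, size=(n_each, 2)))
            labels += [i] * n_each
        X = np.clip(np.vstack(chunks), 1e-6, 1 - 1e-6)
        return X, np.array(labels)

    return make


@pytest.fixture(scope="session")
def cohort_matrix():
    """Default synthetic methylation cohort (23 normals + 3 cancer subgroups)."""
    from methclust import gen_group_methylation

    truth = gen_group_methylation(P=1000, T=136, group_sizes=(23, 40, 40, 33),
                                  delta=0.3, seed=7)
    classes = np.where(truth.group_labels == 0, "normal", "cancer")
    return truth, classes
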