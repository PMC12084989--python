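import numpy as np
import pytest

from healthspace import CohortSpec, SyntheticCohort, TrainConfig, generate_cohort
from healthspace.cohort import _latent_predictor


@pytest.fixture(scope="session")
def fast_config() -> TrainConfig:
    """Reduced-epoch training settings for unit tests."""
    return TrainConfig(max_epochs=25, early_stopping_patience=5, seed=0)


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """Default-parameter cohort, large enough for every category."""
    return generate_cohort(CohortSpec(n_samples=1200, seed=42))


def make_separable_cohort(seed: int = 0, n: int = 3000, margin: float = 4.0):
    """A linearly separable cohort: the shared age analogue dominates both
    axes and rows near the latent group boundaries are trimmed away, so
    the four groups form disjoint bands."""
    spec = CohortSpec(
        n_samples=n,
        seed=seed,
        alpha_true=(15.0, 0.0, -15.0),
        beta_oxi_true=(10.0, 0.05, 0.05, 0.05, 0.05),
        beta_meta_true=(10.0, 0.05, 0.05, 0.05, -0.05, 0.05),
        noise_scale=0.2,
    )
    c = generate_cohort(spec)
    g = _latent_predictor(spec, c.X_oxi, c.X_meta)
    keep = np.all(
        np.abs(g[:, None] + np.asarray(spec.alpha_true)[None, :]) > margin, axis=1
    )
    return SyntheticCohort(c.X_oxi[keep], c.X_meta[keep], c.y[keep], spec)


@pytest.fixture(scope="session")
def separable_cohort() -> SyntheticCohort:
    return make_separable_cohort()


def make_far_clusters_cohort(n_per: int = 60, gap: float = 20.0, seed: int = 0):
    """Four groups at distant covariate locations with tiny spread: any
    monotone score separates them perfectly, so every group pair's HSI
    is exactly 1."""
    rng = np.random.default_rng(seed)
    X_oxi = np.vstack([rng.normal(gap * g, 0.05, (n_per, 5)) for g in range(4)])
    X_meta = np.vstack([rng.normal(gap * g, 0.05, (n_per, 6)) for g in range(4)])
    y = np.repeat(np.arange(4), n_per)
    order = rng.permutation(4 * n_per)
    spec = CohortSpec(n_samples=4 * n_per, seed=seed)
    return SyntheticCohort(X_oxi[order], X_meta[order], y[order], spec)
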