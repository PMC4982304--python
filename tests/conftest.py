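import numpy as np
import pytest

from ppvtrack.model import CoefficientLayout, ModelConfig


@pytest.fixture
def small_cfg():
    """Compact model: 3 cardiac / 2 respiratory harmonics, explicit scales."""
    return ModelConfig(
        n_cardiac_harmonics=3,
        n_resp_harmonics=2,
        n_particles_per_space=5,
        meas_noise_var=1.0,
        q_resp_coeff=1e-4,
        q_card_coeff=1e-4,
        q_mod_coeff=1e-6,
        init_resp_amp=1.0,
        init_card_amp=1.0,
        init_mod_amp=0.01,
        rng_seed=0,
    )


@pytest.fixture
def small_layout(small_cfg):
    return small_cfg.layout


def random_coeff_vecs(layout: CoefficientLayout, n: int, rng: np.random.Generator,
                      scale: float = 1.0, mod_scale: float = 0.1) -> np.ndarray:
    """Random flat coefficient vectors with physiological-ish magnitudes."""
    vecs = np.zeros((n, layout.size))
    vecs[:, layout.r1] = rng.normal(0, scale, (n, layout.n_resp))
    vecs[:, layout.r2] = rng.normal(0, scale, (n, layout.n_resp))
    vecs[:, layout.c1] = rng.normal(0, scale, (n, layout.n_card))
    vecs[:, layout.c2] = rng.normal(0, scale, (n, layout.n_card))
    vecs[:, layout.m1] = rng.normal(0, mod_scale, (n, layout.n_card * layout.n_resp))
    vecs[:, layout.m2] = rng.normal(0, mod_scale, (n, layout.n_card * layout.n_resp))
    return vecs
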