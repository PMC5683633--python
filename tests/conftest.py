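import numpy as np
import pytest

from plasmir import simdata
from plasmir.counts_io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm():
    """10 features x 6 samples of moderately overdispersed counts."""
    r = np.random.default_rng(7)
    mu = np.exp(r.normal(4.0, 1.0, size=(10, 1)))
    counts = simdata.nb_draw(r, np.tile(mu, (1, 6)), np.full((10, 6), 0.2))
    return CountMatrix(
        counts, [f"miR-{i:02d}" for i in range(10)], [f"s{j}" for j in range(6)]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size simulated cohort with injected DE, shared across tests."""
    cfg = simdata.SimConfig(
        seed=11,
        de_spec=simdata.default_de_spec(seed=11),
        surv_spec=simdata.SurvSpec(
            feature_coefs={10: 1.0, 20: -0.8}, baseline_hazard=0.1
        ),
    )
    return simdata.simulate_cohort(cfg)


def null_nb_cohort(rng, nf=159, n1=20, n2=14, phi=0.2, mean_log=5.5):
    """Two-group NB counts with no group effect (shared null simulator)."""
    mu_f = np.exp(rng.normal(mean_log, 1.5, nf))
    n = n1 + n2
    mu = np.tile(mu_f[:, None], (1, n))
    counts = simdata.nb_draw(rng, mu, np.full_like(mu, phi))
    cm = CountMatrix(
        counts, [f"f{i:03d}" for i in range(nf)], [f"s{j:02d}" for j in range(n)]
    )
    groups = ["control"] * n1 + ["DLBCL"] * n2
    return cm, groups
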