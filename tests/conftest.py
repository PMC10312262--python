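import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import connpls.synthetic as syn

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: 10-parcel / 45-edge atlas used for fast six-network tests
TINY_NETWORKS = (
    ("visual", 2),
    ("dorsal attention", 2),
    ("ventral attention", 1),
    ("limbic", 1),
    ("fronto-parietal control", 2),
    ("default", 2),
)


@pytest.fixture(scope="session")
def planted_scaled():
    """Study-sized (128/92) planted dataset on the 25-parcel atlas,
    noise calibrated so the signal singular value is 5x the null scale."""
    cfg = syn.default_config(networks=syn.SCALED_NETWORKS, planted_s=5.0, seed=0)
    cfg = syn.calibrate_noise_sd(cfg, target_ratio=5.0)
    ds, behavior, truth = syn.simulate_dataset(cfg)
    return cfg, ds, behavior, truth


@pytest.fixture(scope="session")
def noiseless_flat():
    """Noiseless single-LV dataset whose planted saliences have
    constant-magnitude entries, so the correlation-scale SVD recovers them
    exactly (z-scoring erases per-column magnitudes otherwise)."""
    E = syn.SyntheticConfig(networks=TINY_NETWORKS).n_edges
    rng = np.random.default_rng(11)
    v = rng.choice([-1.0, 1.0], size=E) / np.sqrt(E)
    u = np.array([1.0, -1.0, 1.0, -1.0, 1.0]) / np.sqrt(5)
    lv = syn.PlantedLV(s=3.0, u_by_group={"young": u, "old": -u}, v=v)
    cfg = syn.SyntheticConfig(
        n_young=24, n_old=16, networks=TINY_NETWORKS,
        planted_lvs=(lv,), noise_sd=0.0, seed=5,
    )
    ds, behavior, truth = syn.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
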