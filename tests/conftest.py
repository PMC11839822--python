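import numpy as np
import pytest

import eggwdi as e


@pytest.fixture(scope="session")
def default_flock():
    """Default study-condition flock (n = 8, seed 42) plus latent truth."""
    return e.simulate_flock(e.FlockSimConfig(seed=42))


@pytest.fixture(scope="session")
def yolk_series(default_flock):
    """Post-final-dose yolk series per hen, non-detects excluded."""
    flock, _ = default_flock
    filtered = e.apply_blq_policy(flock, e.BlqPolicy.EXCLUDE_BELOW_LOD)
    out = {}
    for hen in filtered.hen_ids:
        s = e.build_series(filtered, hen, e.Matrix.YOLK).after(0.0)
        if len(s) >= 4:
            out[hen] = s
    return out


@pytest.fixture(scope="session")
def nca_results(yolk_series):
    return [e.run_nca(s) for s in yolk_series.values()]


@pytest.fixture()
def noise_free_config():
    """Deterministic single-curve study: no noise, no inter-hen spread,
    daily laying, nobody ceases lay."""
    return e.FlockSimConfig(
        seed=0,
        ke_gsd=1.0,
        ka_gsd=1.0,
        amplitude_gsd=1.0,
        lay_interval_mean=1.0,
        lay_interval_hen_gsd=1.0,
        assay_cv=0.0,
        bio_cv=0.0,
        n_cease_lay=0,
        calibrate_observed_cmax=False,
    )
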