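import numpy as np
import pytest

from ensorc import FeatureConfig, SyntheticSpec, build_features, gen_planted_sparse

# d = 1 + 11 = 12: a planted sparse *linear* readout (constant + 11 inputs),
# small enough for exhaustive support checks
LINEAR12 = FeatureConfig(n_delays=1, spacing=1, poly_order=1, include_constant=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_linear12(seed: int, noise: float, n: int = 500):
    """Planted sparse system over a 12-feature linear library, with features/targets aligned."""
    ds, truth = gen_planted_sparse(
        SyntheticSpec(
            kind="planted_sparse",
            n=n,
            n_aux=11,
            n_targets=2,
            density=0.2,
            noise_sigma=noise,
            seed=seed,
            feature=LINEAR12,
        )
    )
    fm = build_features(ds, LINEAR12)
    Y = ds.y[:, fm.valid_times]
    return fm, Y, truth


@pytest.fixture
def planted_quadratic():
    """Noiseless planted system over the full quadratic NG-RC library (d=45)."""
    cfg = FeatureConfig(n_delays=2, spacing=1, poly_order=2)
    ds, truth = gen_planted_sparse(
        SyntheticSpec(
            kind="planted_sparse",
            n=300,
            n_aux=4,
            n_targets=2,
            density=0.2,
            noise_sigma=0.0,
            seed=11,
            feature=cfg,
        )
    )
    fm = build_features(ds, cfg)
    return fm, ds.y[:, fm.valid_times], truth
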