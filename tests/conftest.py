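import numpy as np
import pytest

from placenet.geometry import ENV_NAMES, all_environments, make_environment

SCALED_SEED = 2024


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scaled_run():
    """Dataset, untrained baseline, and trained model of the desk-scale preset.

    Trained once per session and shared by every test that needs a model
    with learned representations (several minutes of compute).
    """
    from placenet.trajectory import build_dataset
    from placenet.training import TrainConfig, train, untrained_baseline

    ds = build_dataset(all_environments(), n_total=1200, T=250,
                       rng=np.random.default_rng(SCALED_SEED))
    cfg = TrainConfig.scaled(seed=SCALED_SEED)
    base = untrained_baseline(ds, cfg)
    params, log = train(ds, cfg=cfg)
    return {"dataset": ds, "cfg": cfg, "baseline": base, "params": params,
            "log": log, "seed": SCALED_SEED}


@pytest.fixture(params=ENV_NAMES)
def env(request):
    return make_environment(request.param)


@pytest.fixture
def square():
    return make_environment("square")


@pytest.fixture
def square_hole():
    return make_environment("square_hole")
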