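import numpy as np
import pandas as pd
import pytest

from alstrack.pipeline import ExperimentConfig, run_experiment


def mini_config(seed: int, out_dir=None) -> ExperimentConfig:
    """Small but complete LOPO experiment: 3 participants, all paradigms,
    linear + cubic interpolation, three scales plus the composite."""
    return ExperimentConfig(
        cohort="homogeneous",
        scales=("swallowing", "walking", "composite"),
        interpolations=("linear", "cubic"),
        seed=seed,
        n_draws=0,
        bootstrap_B=100,
        out_dir=str(out_dir) if out_dir else None,
    )


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One shared full synthetic LOPO run (written to disk), reused by the
    evaluation-geometry, integrity and determinism checks."""
    out = tmp_path_factory.mktemp("mini_run")
    result = run_experiment(mini_config(seed=5, out_dir=out))
    return result, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_assessments(rng, n_anchors=6, cadence=30, lo=0, hi=4):
    dates = pd.date_range("2023-01-01", periods=n_anchors, freq=f"{cadence}D")
    scores = rng.integers(lo, hi + 1, size=n_anchors)
    return pd.DataFrame({"date": dates, "speech": scores})
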