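import numpy as np
import pytest

from duospot.codebook import build_default_panel
from duospot.pipeline import PipelineParams, run_pipeline
from duospot.registration import SamplePair
from duospot.simgen import SimConfig, simulate_sample


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def spotty_image():
    """A reproducible image of bright Gaussian blobs for registration tests."""
    rng = np.random.default_rng(7)
    img = np.zeros((256, 256))
    yy, xx = np.mgrid[0:256, 0:256]
    for _ in range(40):
        y, x = rng.uniform(40, 216, 2)
        img += rng.uniform(500, 2000) * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * 3.0**2)
        )
    return img


@pytest.fixture(scope="session")
def e2e():
    """Default simulated sample (seed 1) run through the full pipeline.

    Session-scoped: the pipeline run takes a few seconds and several tests
    inspect different aspects of the same result.
    """
    config = SimConfig(seed=1)
    original, background, truth = simulate_sample(config)
    pair = SamplePair(original=original, background=background)
    result = run_pipeline(pair, params=PipelineParams())
    return config, truth, result


def match_signals(truth_signals, accepted, tol=3.0):
    """Greedy one-to-one matching of accepted calls to ground-truth signals.

    Returns (n_matched, n_spurious); a call is spurious if no unclaimed
    ground-truth signal of the same marker lies within ``tol`` px.
    """
    from scipy.spatial import cKDTree

    matched = 0
    spurious = 0
    for marker in truth_signals["marker"].unique():
        t_m = truth_signals[truth_signals["marker"] == marker]
        a_m = accepted[accepted["marker"] == marker]
        if a_m.empty:
            continue
        tree = cKDTree(t_m[["y", "x"]].to_numpy())
        used = set()
        for _, row in a_m.iterrows():
            d, j = tree.query([row["y"], row["x"]])
            if d <= tol and j not in used:
                used.add(j)
                matched += 1
            else:
                spurious += 1
    extra = accepted[~accepted["marker"].isin(truth_signals["marker"].unique())]
    spurious += len(extra)
    return matched, spurious
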