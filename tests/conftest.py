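import numpy as np
import pytest

from buds import (DissimilarityMatrix, GradientParams, NoiseScales, fit,
                  generate_gradient, generate_model_draw, orient, summarize)


def euclidean_dissimilarity(points) -> DissimilarityMatrix:
    """1-D or k-D Euclidean distances as a DissimilarityMatrix."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DissimilarityMatrix(values=d, metric_tag="euclidean")


@pytest.fixture(scope="session")
def model_draw():
    """One exact-model draw at the default study conditions (n=50)."""
    D, tau, params = generate_model_draw(n=50, seed=7)
    return D, tau, params


@pytest.fixture(scope="session")
def fitted(model_draw):
    """An oriented posterior fit of the exact-model draw."""
    D, tau, _ = model_draw
    samples = orient(fit(D, seed=7, draws=300), D)
    return D, tau, samples, summarize(samples)


@pytest.fixture(scope="session")
def counts_gradient():
    return generate_gradient(GradientParams(n=40, p=120, mode="counts", seed=3))
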