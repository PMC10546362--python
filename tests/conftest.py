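import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rgpl import Volume3D

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_blob_map(shape, blobs, spacing=(1.0, 1.0, 1.0), support_rel=0.45):
    """Confidence map from compact-support Gaussian blobs.

    ``blobs`` is a list of (center, sigma, peak); each blob contributes
    ``peak * exp(-0.5 * sum(((x-c)/s)^2))`` zeroed below ``support_rel`` of
    its peak; blobs merge by voxel-wise maximum.
    """
    out = np.zeros(shape, dtype=np.float64)
    for center, sigma, peak in blobs:
        axes = [
            np.exp(-0.5 * ((np.arange(n) - c) / s) ** 2)
            for n, c, s in zip(shape, center, sigma)
        ]
        g = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        g[g < support_rel] = 0.0
        np.maximum(out, peak * g, out=out)
    return Volume3D(out, spacing)


@pytest.fixture
def blob_map_factory():
    return make_blob_map
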