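import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctnoise import CTVolume, PhantomSpec, generate_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(noise_sigma_hu=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(noise_sigma_hu=33.0, seed=42))


@pytest.fixture(scope="session")
def make_cylinder():
    """Factory for a straight vertical air cylinder in tissue."""

    def build(
        shape=(41, 41, 41),
        spacing=(1.0, 1.0, 1.0),
        radius_mm=12.0,
        lumen_hu=-1000.0,
        background_hu=0.0,
        axis=None,
    ) -> CTVolume:
        ci = shape[0] // 2 if axis is None else axis[0]
        cj = shape[1] // 2 if axis is None else axis[1]
        x = (np.arange(shape[0]) - ci) * spacing[0]
        y = (np.arange(shape[1]) - cj) * spacing[1]
        xx, yy = np.meshgrid(x, y, indexing="ij")
        inside = xx**2 + yy**2 <= radius_mm**2
        values = np.full(shape, background_hu, dtype=float)
        values[inside, :] = lumen_hu
        return CTVolume(values=values, spacing=spacing)

    return build
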