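import numpy as np
import pytest

from goldcal import SyntheticSceneConfig, generate_micrograph, reflection_for

#: fcc gold (111) spacing at 81 K — the spacing a cryo foil actually shows
GOLD_D81 = reflection_for("gold_fcc", (1, 1, 1), 81.0).d
TRUE_PIXEL = 0.6484


def small_scene(seed: int = 0, **overrides) -> SyntheticSceneConfig:
    """A 512-pixel scene that keeps unit tests fast; spacing matches the
    81 K assumption the calibration pipeline uses by default."""
    params = dict(
        image_size=512,
        true_pixel_size=TRUE_PIXEL,
        spacings=((GOLD_D81, 1.0),),
        n_crystallites=80,
        crystallite_scale=36.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSceneConfig(**params)


@pytest.fixture(scope="session")
def small_micrographs():
    """Six fast synthetic gold micrographs with default noise."""
    return [generate_micrograph(small_scene(seed=s)) for s in range(6)]


@pytest.fixture(scope="session")
def ring_image():
    """Analytic isotropic Gaussian ring at radius 150 in a 512 spectrum."""
    L, R = 512, 150.0
    y = np.arange(L) - L // 2
    r = np.hypot(y[:, None], y[None, :])
    values = 1.0 + 60.0 * np.exp(-0.5 * ((r - R) / 3.0) ** 2)
    return values, L, R
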