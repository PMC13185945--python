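import numpy as np
import pytest

from climbfocus.niqe import load_default_model


@pytest.fixture(scope="session")
def default_model():
    """The bundled NIQE model (trained on seeded synthetic textures)."""
    return load_default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class ParabolaScope:
    """Microscope stub whose image sharpness follows an exact parabola in z.

    An N x N zero canvas with a single centre pixel of amplitude ``a`` has
    variance-of-Laplacian exactly ``20 a^2 / (N-2)^2``, so any prescribed
    sharpness profile S(z) >= 0 can be realised exactly by inverting that
    relation.  Used to test controller behaviour on an ideal quadratic
    sharpness landscape.
    """

    def __init__(self, z_peak_um: float, s_peak: float = 1.0e4,
                 curvature: float = 100.0, size: int = 33,
                 z_limits_um=(-1e6, 1e6)):
        self.z_peak = z_peak_um
        self.s_peak = s_peak
        self.curv = curvature
        self.size = size
        self._z_limits = z_limits_um
        self.current_z = 0.0

    @property
    def z_limits_um(self):
        return self._z_limits

    def move_to(self, z_um: float) -> None:
        self.current_z = float(z_um)

    def sharpness_at(self, z: float) -> float:
        return max(1.0, self.s_peak - self.curv * (z - self.z_peak) ** 2)

    def capture(self) -> np.ndarray:
        n_int = (self.size - 2) ** 2
        a = np.sqrt(self.sharpness_at(self.current_z) * n_int / 20.0)
        img = np.zeros((self.size, self.size))
        img[self.size // 2, self.size // 2] = a
        return img


@pytest.fixture()
def parabola_scope_factory():
    return ParabolaScope
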