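"""Virtual microscope: phantoms with a known focus plane, defocus blur, noise.

The simulator closes the autofocus control loop in tests.  A phantom is a set
of emitters (y, x, z, intensity) with a known true focus plane z*.  Each
emitter is rendered as a 2-D Gaussian whose width grows hyperbolically with
defocus,

    sigma(dz) = sqrt(sigma_e^2 + sigma_0^2 (1 + (dz / z_R)^2)),

where ``sigma_0 = 0.21 lambda / NA`` is the in-focus diffraction-limited spot
size, ``z_R = n lambda / NA^2`` the axial scale, and ``sigma_e`` the emitter's
physical size.  Peak amplitude falls as the inverse squared width so photon
flux is conserved under defocus; the resulting sharpness-vs-z curve is
unimodal and locally quadratic around z*, which is the regime the search
controller is designed for.  The camera adds a constant offset, Poisson shot
noise on the signal and Gaussian read noise, then clips to its bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .metrics import sharpness
from .search import StageTravelError

__all__ = [
    "Optics",
    "Camera",
    "Phantom",
    "VirtualMicroscope",
    "make_phantom",
    "render",
    "theoretical_dof",
    "natural_texture",
    "sharpness_curve",
    "standard_scene",
    "STANDARD_SHAPE",
    "STANDARD_DENSITY_PER_UM2",
    "DEFAULT_OPTICS",
    "WIDEFIELD_LOWMAG_OPTICS",
    "DEFAULT_CAMERA",
    "BRIGHT_CAMERA",
]

PHANTOM_KINDS = ("bead_monolayer", "filament", "two_layer_beads",
                 "uniform_lowcontrast")


@dataclass(frozen=True)
class Optics:
    """Objective and sampling parameters of the simulated imaging system."""

    na: float
    wavelength_um: float = 0.52
    refr_index: float = 1.0
    magnification: float = 20.0
    camera_pixel_um: float = 6.5

    def __post_init__(self) -> None:
        if not (0 < self.na < self.refr_index):
            raise ValueError("need 0 < NA < refractive index")

    @property
    def sample_pixel_um(self) -> float:
        return self.camera_pixel_um / self.magnification

    @property
    def sigma0_um(self) -> float:
        """In-focus Gaussian spot size (diffraction limit 0.21 lambda/NA)."""
        return 0.21 * self.wavelength_um / self.na

    @property
    def z_r_um(self) -> float:
        """Axial defocus scale n lambda / NA^2."""
        return self.refr_index * self.wavelength_um / self.na**2


@dataclass(frozen=True)
class Camera:
    """Camera/noise model: counts = Poisson(signal*photon_scale) + offset + read."""

    photon_scale: float = 110.0  # counts per unit emitter amplitude at focus
    read_sigma: float = 2.0
    offset: float = 100.0
    bit_depth: int = 16

    @property
    def max_count(self) -> float:
        return float(2**self.bit_depth - 1)


# Study conditions used throughout the test suite (see docs/methods.md):
# a 10x detection path with a 0.2 NA objective and a 2x2-binned camera
# (13 um pixels) gives an axial scale z_R = 13 um, so a 1 um coarse step
# samples the sharpness peak densely; the 4x low-mag path (z_R = 52 um)
# covers millimetre-scale re-focusing after objective switching.  The
# default camera gives ~10 peak pixel SNR; the bright camera ~30 (typical
# bead exposures).
DEFAULT_OPTICS = Optics(na=0.2, magnification=10.0, camera_pixel_um=13.0)
WIDEFIELD_LOWMAG_OPTICS = Optics(na=0.1, magnification=4.0, camera_pixel_um=13.0)
DEFAULT_CAMERA = Camera(photon_scale=110.0, read_sigma=2.0)
BRIGHT_CAMERA = Camera(photon_scale=1000.0, read_sigma=2.0)
STANDARD_SHAPE = (384, 384)
STANDARD_DENSITY_PER_UM2 = 0.072  # confluent but resolvable bead field


@dataclass
class Phantom:
    """Ground-truth scene: emitters plus the true focus plane z*."""

    kind: str
    emitters: np.ndarray  # (n, 4): y_um, x_um, z_um, intensity
    true_focus_um: float
    extent_um: float
    emitter_sigma_um: np.ndarray = field(default=None)  # physical size per emitter

    def __post_init__(self) -> None:
        self.emitters = np.atleast_2d(np.asarray(self.emitters, dtype=float))
        if self.emitters.shape[1] != 4:
            raise ValueError("emitters must be (n, 4): y, x, z, intensity")
        if self.emitter_sigma_um is None:
            self.emitter_sigma_um = np.full(self.emitters.shape[0], 0.1)
        self.emitter_sigma_um = np.asarray(self.emitter_sigma_um, dtype=float)
        if self.emitter_sigma_um.size != self.emitters.shape[0]:
            raise ValueError("one emitter size per emitter required")


def make_phantom(
    kind: str,
    n_emitters: int = 500,
    seed: int = 0,
    extent_um: float = 80.0,
    true_focus_um: float = 0.0,
    emitter_sigma_um: Optional[float] = None,
) -> Phantom:
    """Reproducible phantom construction.

    Kinds
    -----
    ``bead_monolayer``
        sparse sub-diffraction beads, all exactly in the z* plane.
    ``filament``
        points strung along a few random smooth curves in the z* plane,
        emulating cytoskeletal / ER structure.
    ``two_layer_beads``
        beads split between z* - 1 um and z* + 1 um, emulating structure
        distributed over adjacent planes.
    ``uniform_lowcontrast``
        dim, large, dense emitters: a nearly featureless field whose
        sharpness curve is almost flat.

    ``emitter_sigma_um`` overrides the kind's default physical emitter size:
    larger structures widen the sharpness-vs-z curve (the effective axial
    scale grows with sqrt(1 + sigma_e^2/sigma_0^2)), emulating tissue-scale
    features for wide-range searches.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if n_emitters < 1:
        raise ValueError("n_emitters must be >= 1")
    rng = np.random.default_rng(seed)
    margin = 0.05 * extent_um
    yx = rng.uniform(margin, extent_um - margin, size=(n_emitters, 2))
    intensity = rng.uniform(0.6, 1.0, size=n_emitters)
    z = np.full(n_emitters, true_focus_um)
    sigma_e = np.full(n_emitters, 0.1)  # 200 nm beads
    if kind == "two_layer_beads":
        half = n_emitters // 2
        z = np.where(np.arange(n_emitters) < half,
                     true_focus_um - 1.0, true_focus_um + 1.0)
    elif kind == "filament":
        n_curves = max(1, n_emitters // 150)
        pts = []
        per = int(np.ceil(n_emitters / n_curves))
        for _ in range(n_curves):
            t = np.linspace(0.0, 1.0, per)
            p0 = rng.uniform(margin, extent_um - margin, 2)
            p1 = rng.uniform(margin, extent_um - margin, 2)
            ctrl = rng.uniform(margin, extent_um - margin, 2)
            curve = ((1 - t) ** 2)[:, None] * p0 + (2 * t * (1 - t))[:, None] * ctrl \
                + (t**2)[:, None] * p1
            pts.append(curve)
        yx = np.concatenate(pts)[:n_emitters]
        intensity = rng.uniform(0.5, 1.0, size=n_emitters)
        sigma_e = np.full(n_emitters, 0.15)
    elif kind == "uniform_lowcontrast":
        intensity = rng.uniform(0.02, 0.05, size=n_emitters)
        sigma_e = np.full(n_emitters, 3.0)
    if emitter_sigma_um is not None:
        sigma_e = np.full(n_emitters, float(emitter_sigma_um))
    emitters = np.column_stack([yx[:, 0], yx[:, 1], z, intensity])
    return Phantom(kind=kind, emitters=emitters, true_focus_um=true_focus_um,
                   extent_um=extent_um, emitter_sigma_um=sigma_e)


def _splat_bilinear(canvas: np.ndarray, y_px: np.ndarray, x_px: np.ndarray,
                    w: np.ndarray) -> None:
    """Deposit weights onto the pixel grid with bilinear interpolation."""
    ny, nx = canvas.shape
    y0 = np.floor(y_px).astype(int)
    x0 = np.floor(x_px).astype(int)
    fy = y_px - y0
    fx = x_px - x0
    for dy, dx, ww in (
        (0, 0, (1 - fy) * (1 - fx)),
        (1, 0, fy * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 1, fy * fx),
    ):
        yy = (y0 + dy) % ny
        xx = (x0 + dx) % nx
        np.add.at(canvas, (yy, xx), w * ww)


def render(
    phantom: Phantom,
    z_um: float,
    optics: Optics = DEFAULT_OPTICS,
    camera: Camera = DEFAULT_CAMERA,
    rng: Optional[np.random.Generator] = None,
    shape: tuple[int, int] = (256, 256),
) -> np.ndarray:
    """Simulated acquisition at stage position ``z_um``.

    With ``rng=None`` the expected (noise-free) camera counts are returned;
    otherwise Poisson shot noise and Gaussian read noise are drawn from the
    given generator.  Blurring is periodic across the field so photon flux is
    conserved exactly under defocus.
    """
    px = optics.sample_pixel_um
    sigma0 = optics.sigma0_um
    z_r = optics.z_r_um
    dz = z_um - phantom.emitters[:, 2]
    sigma_um = np.sqrt(
        phantom.emitter_sigma_um**2 + sigma0**2 * (1.0 + (dz / z_r) ** 2)
    )
    sigma_px = sigma_um / px
    sigma_focus_px = np.sqrt(phantom.emitter_sigma_um**2 + sigma0**2) / px
    # flux such that the in-focus peak amplitude equals the emitter intensity
    flux = phantom.emitters[:, 3] * 2.0 * np.pi * sigma_focus_px**2
    # blur per quantised width bin (flux is conserved regardless of binning)
    img = np.zeros(shape, dtype=np.float64)
    bins = np.round(sigma_px / 0.1).astype(int)
    y_px = phantom.emitters[:, 0] / px
    x_px = phantom.emitters[:, 1] / px
    for b in np.unique(bins):
        sel = bins == b
        layer = np.zeros(shape, dtype=np.float64)
        _splat_bilinear(layer, y_px[sel], x_px[sel], flux[sel])
        img += gaussian_filter(layer, sigma=float(sigma_px[sel].mean()),
                               mode="wrap")
    expected = img * camera.photon_scale
    if rng is None:
        out = expected + camera.offset
    else:
        out = (rng.poisson(expected).astype(np.float64) + camera.offset
               + rng.normal(0.0, camera.read_sigma, size=shape))
    return np.clip(out, 0.0, camera.max_count)


class VirtualMicroscope:
    """Stage + camera test double implementing the acquisition protocol.

    One top-level seed plus a per-capture counter makes every acquisition in
    a run reproducible; ``move_to`` outside the travel limits raises
    :class:`StageTravelError`.
    """

    def __init__(
        self,
        phantom: Phantom,
        optics: Optics = DEFAULT_OPTICS,
        camera: Camera = DEFAULT_CAMERA,
        noisy: bool = True,
        seed: int = 0,
        z_limits_um: tuple[float, float] = (-1200.0, 1200.0),
        shape: tuple[int, int] = (256, 256),
    ) -> None:
        self.phantom = phantom
        self.optics = optics
        self.camera = camera
        self.noisy = noisy
        self.seed = seed
        self._z_limits = (float(min(z_limits_um)), float(max(z_limits_um)))
        self.shape = shape
        self.current_z_um = 0.0
        self.capture_count = 0

    @property
    def z_limits_um(self) -> tuple[float, float]:
        return self._z_limits

    def move_to(self, z_um: float) -> None:
        lo, hi = self._z_limits
        if not (lo <= z_um <= hi):
            raise StageTravelError(
                f"commanded z={z_um:.3f} um outside travel limits [{lo}, {hi}]"
            )
        self.current_z_um = float(z_um)

    def capture(self) -> np.ndarray:
        rng = None
        if self.noisy:
            rng = np.random.default_rng([self.seed, self.capture_count])
        self.capture_count += 1
        return render(self.phantom, self.current_z_um, self.optics,
                      self.camera, rng=rng, shape=self.shape)


def standard_scene(
    seed: int,
    kind: str = "bead_monolayer",
    noisy: bool = True,
    optics: Optics = DEFAULT_OPTICS,
    camera: Camera = DEFAULT_CAMERA,
    shape: tuple[int, int] = STANDARD_SHAPE,
    density_per_um2: float = STANDARD_DENSITY_PER_UM2,
    intensity_scale: float = 1.0,
    true_focus_um: float = 0.0,
    z_limits_um: tuple[float, float] = (-1200.0, 1200.0),
    emitter_sigma_um: Optional[float] = None,
) -> VirtualMicroscope:
    """The package's standard simulated specimen + microscope.

    The phantom extent matches the camera field of view and the emitter
    density is fixed, so the scene statistics are independent of the chosen
    sensor size.  ``intensity_scale`` rescales every emitter (used to emulate
    dim and bright fields of view of the same structure).
    """
    fov = shape[0] * optics.sample_pixel_um
    n = max(1, int(density_per_um2 * fov * fov))
    phantom = make_phantom(kind, n_emitters=n, seed=seed, extent_um=fov,
                           true_focus_um=true_focus_um,
                           emitter_sigma_um=emitter_sigma_um)
    if intensity_scale != 1.0:
        phantom.emitters[:, 3] *= intensity_scale
    return VirtualMicroscope(phantom, optics=optics, camera=camera,
                             noisy=noisy, seed=seed, shape=shape,
                             z_limits_um=z_limits_um)


def theoretical_dof(
    na: float,
    wavelength_um: float,
    refr_index: float,
    magnification: float,
    camera_pixel_um: float,
) -> float:
    """Depth of field: ``lambda n / NA^2 + e / (M NA)``.

    The first (wave-optical) term is the diffraction-limited axial range; the
    second (geometrical) term accounts for the finite camera pixel ``e``
    referred to the sample through the magnification ``M``.  For a 100x/1.49
    oil objective with 6.5 um pixels this gives 0.399 um.
    """
    if not (0 < na < refr_index):
        raise ValueError("need 0 < NA < refractive index")
    if wavelength_um <= 0 or magnification <= 0 or camera_pixel_um <= 0:
        raise ValueError("optical parameters must be positive")
    return (wavelength_um * refr_index / na**2
            + camera_pixel_um / (magnification * na))


def natural_texture(shape: tuple[int, int] = (384, 384), seed: int = 0,
                    beta: float = 1.2, scale: float = 1000.0) -> np.ndarray:
    """Seeded synthetic natural texture with a 1/f^beta amplitude spectrum.

    Natural scenes have approximately power-law spectra; these textures serve
    as the pristine corpus for training the bundled NIQE model and as
    fixtures for blur-ordering tests.  Values span [0, scale].
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    f = np.fft.fftn(white)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    k = np.sqrt(fy * fy + fx * fx)
    k[0, 0] = 1.0
    f *= k**-beta
    f[0, 0] = 0.0
    tex = np.fft.ifftn(f).real
    tex -= tex.min()
    tex /= tex.max()
    return tex * scale


def sharpness_curve(
    phantom: Phantom,
    z_grid,
    optics: Optics = DEFAULT_OPTICS,
    camera: Camera = DEFAULT_CAMERA,
    shape: tuple[int, int] = (256, 256),
    denoise: bool = False,
) -> np.ndarray:
    """Noise-free sharpness values over a z grid (for curve diagnostics)."""
    return np.array([
        sharpness(render(phantom, z, optics, camera, rng=None, shape=shape),
                  denoise=denoise)
        for z in np.asarray(z_grid, dtype=float)
    ])
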