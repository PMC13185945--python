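"""Post-focus stack restoration: Born-Wolf PSF, 3-D Richardson-Lucy, projection.

The evenly spaced frames recorded around the focus during the climb form a
z-stack.  An aberration-free widefield point spread function is computed from
the scalar Born-Wolf diffraction integral,

    h(r, z) = | int_0^1 J0(k NA r rho) exp(-(i/2) k rho^2 z NA^2 / n) rho drho |^2,

with k = 2 pi / lambda, evaluated by Simpson quadrature and normalised to unit
sum.  Richardson-Lucy deconvolution then sharpens the stack (multiplicative
maximum-likelihood updates appropriate for Poisson-noise imaging), and a
maximum intensity projection merges the in-focus structure of every plane
into a single all-in-focus image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy.integrate import simpson
from scipy.special import j0

from .metrics import SharpnessSample

__all__ = [
    "PsfParams",
    "ZStack",
    "born_wolf_psf",
    "richardson_lucy_3d",
    "rl_iterations",
    "max_projection",
    "zstack_from_trace",
    "restore_stack",
]


@dataclass(frozen=True)
class PsfParams:
    """Optical parameters and grid for the theoretical PSF.

    All lengths in micrometres; grid dimensions must be odd so the PSF is
    centred on a pixel.
    """

    na: float
    wavelength_um: float
    refr_index: float
    pixel_um: float
    z_step_um: float
    shape: tuple[int, int, int] = (9, 33, 33)

    def __post_init__(self) -> None:
        if not (0 < self.na < self.refr_index):
            raise ValueError("need 0 < NA < refractive index")
        if self.wavelength_um <= 0 or self.pixel_um <= 0 or self.z_step_um <= 0:
            raise ValueError("wavelength, pixel and z-step must be positive")
        if len(self.shape) != 3 or any(n < 1 or n % 2 == 0 for n in self.shape):
            raise ValueError("PSF grid dimensions must be odd and positive")


@dataclass
class ZStack:
    """Ordered stack of planes with strictly monotone, evenly spaced z."""

    planes: np.ndarray
    z_positions_um: np.ndarray
    pixel_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a 3-D array (nz, ny, nx)")
        if self.z_positions_um.size != self.planes.shape[0]:
            raise ValueError("one z position per plane required")
        if self.planes.shape[0] > 1:
            dz = np.diff(self.z_positions_um)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ValueError("z positions must be strictly monotone")
            if np.ptp(np.abs(dz)) > 1e-3 * np.abs(dz).mean():
                raise ValueError("z positions must be evenly spaced")

    @property
    def z_step_um(self) -> float:
        if self.planes.shape[0] < 2:
            raise ValueError("z step undefined for a single plane")
        return float(abs(np.diff(self.z_positions_um)).mean())


def born_wolf_psf(params: PsfParams, n_quad: int = 257) -> np.ndarray:
    """Born-Wolf widefield PSF on the requested grid, normalised to unit sum.

    The aperture integral is evaluated with Simpson quadrature over ``n_quad``
    nodes on rho in [0, 1] (257 nodes resolve the default optics well beyond
    the grid's sampling).  The model is even in z, so defocus planes at +z
    and -z are identical.
    """
    nz, ny, nx = params.shape
    k = 2.0 * np.pi / params.wavelength_um
    rho = np.linspace(0.0, 1.0, n_quad)
    y = (np.arange(ny) - ny // 2) * params.pixel_um
    x = (np.arange(nx) - nx // 2) * params.pixel_um
    r = np.sqrt(y[:, None] ** 2 + x[None, :] ** 2)
    bessel = j0(k * params.na * r[..., None] * rho)  # (ny, nx, n_quad)
    psf = np.empty(params.shape, dtype=np.float64)
    for iz in range(nz):
        z = (iz - nz // 2) * params.z_step_um
        phase = np.exp(-0.5j * k * rho**2 * z * params.na**2 / params.refr_index)
        integrand = bessel * (phase * rho)
        amp = simpson(integrand, x=rho, axis=-1)
        psf[iz] = np.abs(amp) ** 2
    return psf / psf.sum()


def _pad_psf_to(psf: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Embed a centred PSF into an array of the data's shape, origin-centred."""
    if any(p > s for p, s in zip(psf.shape, shape)):
        raise ValueError(f"PSF {psf.shape} larger than data {shape}")
    out = np.zeros(shape, dtype=np.float64)
    out[tuple(slice(0, p) for p in psf.shape)] = psf
    shifts = [-(p // 2) for p in psf.shape]
    return np.roll(out, shifts, axis=tuple(range(len(shape))))


def rl_iterations(data: np.ndarray, psf: np.ndarray,
                  eps: float = 1e-12) -> Iterator[np.ndarray]:
    """Yield successive Richardson-Lucy estimates (periodic convolution).

    The update is ``e <- e * (PSF* (x) (d / (PSF (x) e)))`` with circular
    convolution in the frequency domain and a floor ``eps`` in the divisor.
    With a unit-sum PSF the total intensity of every iterate equals the
    total intensity of the data, and iterates stay non-negative.
    """
    d = np.asarray(data, dtype=np.float64)
    h = np.asarray(psf, dtype=np.float64)
    if np.any(h < 0) or np.any(d < 0):
        raise ValueError("PSF and data must be non-negative")
    if not np.isclose(h.sum(), 1.0, rtol=1e-6):
        raise ValueError("PSF must be normalised to unit sum")
    if h.ndim != d.ndim:
        raise ValueError("PSF and data dimensionality must match")
    otf = np.fft.rfftn(_pad_psf_to(h, d.shape))
    axes = tuple(range(d.ndim))
    est = d.copy()
    while True:
        blurred = np.fft.irfftn(np.fft.rfftn(est) * otf, s=d.shape, axes=axes)
        ratio = d / np.maximum(blurred, eps)
        est = est * np.fft.irfftn(np.fft.rfftn(ratio) * np.conj(otf),
                                  s=d.shape, axes=axes)
        est = np.clip(est, 0.0, None)
        yield est


def richardson_lucy_3d(stack, psf: np.ndarray, n_iter: int = 20,
                       eps: float = 1e-12):
    """Richardson-Lucy deconvolution of a z-stack with a known 3-D PSF.

    ``stack`` may be a :class:`ZStack` (returned as one) or a bare 3-D array.
    The default 20 iterations balance restoration against noise
    amplification for autofocus stacks.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    zstack = stack if isinstance(stack, ZStack) else None
    data = stack.planes if zstack is not None else np.asarray(stack, dtype=float)
    it = rl_iterations(data, psf, eps=eps)
    est = data
    for _ in range(n_iter):
        est = next(it)
    if zstack is not None:
        return ZStack(planes=est, z_positions_um=zstack.z_positions_um.copy(),
                      pixel_um=zstack.pixel_um)
    return est


def max_projection(stack) -> np.ndarray:
    """Per-pixel maximum across the stack planes (all-in-focus merge)."""
    planes = stack.planes if isinstance(stack, ZStack) else np.asarray(stack, dtype=float)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("max_projection needs a non-empty 3-D stack")
    return planes.max(axis=0)


def zstack_from_trace(samples: list, frames: list, pixel_um: Optional[float] = None,
                      max_planes: int = 10) -> ZStack:
    """Assemble the restoration stack from the tail of an autofocus trace.

    Takes the trailing run of frames acquired at the finest (constant) step in
    effect, up to ``max_planes`` (the fit window).  Unevenly spaced trailing
    frames are rejected rather than interpolated.
    """
    if len(samples) != len(frames):
        raise ValueError("need one frame per trace sample (run with keep_frames)")
    if len(samples) < 2:
        raise ValueError("need at least 2 frames to form a stack")
    z = np.array([s.z_um if isinstance(s, SharpnessSample) else float(s)
                  for s in samples])
    dz = np.diff(z)
    step = dz[-1]
    if step == 0:
        raise ValueError("trailing frames have zero z spacing")
    # walk backwards while spacing stays constant
    k = len(dz)
    while k > 0 and abs(dz[k - 1] - step) <= 1e-6 * abs(step):
        k -= 1
    first = max(k, len(z) - max_planes)
    sel = slice(first, len(z))
    zz = z[sel]
    if zz.size < 2:
        raise ValueError("no evenly spaced trailing run of frames")
    planes = np.stack([np.asarray(f, dtype=float) for f in frames[sel]])
    if zz[0] > zz[-1]:  # store ascending
        zz = zz[::-1].copy()
        planes = planes[::-1].copy()
    return ZStack(planes=planes, z_positions_um=zz, pixel_um=pixel_um)


def restore_stack(stack: ZStack, na: float, wavelength_um: float,
                  refr_index: float, n_iter: int = 20,
                  psf_lateral: int = 33) -> tuple[ZStack, np.ndarray]:
    """Deconvolve an autofocus stack and return (restored stack, projection)."""
    if stack.pixel_um is None:
        raise ValueError("stack needs pixel_um for PSF generation")
    nz = stack.planes.shape[0]
    psf_nz = nz if nz % 2 == 1 else nz - 1
    params = PsfParams(na=na, wavelength_um=wavelength_um, refr_index=refr_index,
                       pixel_um=stack.pixel_um, z_step_um=stack.z_step_um,
                       shape=(psf_nz, psf_lateral, psf_lateral))
    psf = born_wolf_psf(params)
    restored = richardson_lucy_3d(stack, psf, n_iter=n_iter)
    return restored, max_projection(restored)
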