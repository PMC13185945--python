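"""Focus evaluation function: background subtraction and variance of the Laplacian.

The sharpness of an image is quantified by applying a discrete Laplacian to the
(optionally background-subtracted) image and taking the population variance of
the filtered interior:

    sigma^2 = (1/N) * sum_i (L(x_i, y_i) - mu)^2,   mu = (1/N) * sum_i L(x_i, y_i)

where ``L`` is the Laplacian image and ``N`` counts interior pixels (the
one-pixel border, where the stencil would run off the image, is excluded).
The Laplacian responds strongly to fine structure near focus while the
variance pooling retains sensitivity far from focus, which is what makes the
combination a good hill-climbing objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaplacianImage",
    "SharpnessSample",
    "subtract_background",
    "laplacian",
    "sharpness",
]


@dataclass(frozen=True)
class SharpnessSample:
    """One (stage position, sharpness) measurement of the search trace."""

    z_um: float
    sharpness: float

    def __post_init__(self) -> None:
        if self.sharpness < 0:
            raise ValueError("sharpness must be >= 0")


@dataclass(frozen=True)
class LaplacianImage:
    """Laplacian-filtered interior of an image plus its summary statistics.

    ``values`` holds the filtered interior only; ``n_pixels`` and ``mean`` are
    the N and mu entering the variance, kept explicit so the statistics are
    auditable.
    """

    values: np.ndarray
    n_pixels: int
    mean: float


def _as_float_image(image) -> np.ndarray:
    """Validate a 2-D image and promote to float64 (avoids integer wraparound)."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(
            f"image must be at least 3x3 for the Laplacian interior, got {arr.shape}"
        )
    return arr.astype(np.float64, copy=False)


def subtract_background(image, enabled: bool = True, percentile: float = 10.0):
    """Constant-background denoising: subtract a percentile estimate, clip at zero.

    The background level ``b`` is estimated as the ``percentile``-th percentile
    of the pixel intensities (robust to sparse bright signal); the output is
    ``max(0, pixel - b)``.  With ``enabled=False`` (brightfield mode) the input
    is returned unchanged.
    """
    arr = _as_float_image(image)
    if not enabled:
        return arr
    b = float(np.percentile(arr, percentile))
    return np.clip(arr - b, 0.0, None)


_STENCILS = {4, 8}


def laplacian(image, neighbours: int = 4) -> LaplacianImage:
    """Discrete Laplacian of the image interior.

    ``neighbours=4`` uses the standard [[0,1,0],[1,-4,1],[0,1,0]] stencil;
    ``neighbours=8`` the 8-connected variant with centre weight -8.  The
    one-pixel border is excluded from the output.
    """
    if neighbours not in _STENCILS:
        raise ValueError(f"neighbours must be one of {_STENCILS}")
    a = _as_float_image(image)
    c = a[1:-1, 1:-1]
    vals = a[2:, 1:-1] + a[:-2, 1:-1] + a[1:-1, 2:] + a[1:-1, :-2] - 4.0 * c
    if neighbours == 8:
        vals = vals + (
            a[2:, 2:] + a[2:, :-2] + a[:-2, 2:] + a[:-2, :-2] - 4.0 * c
        )
    n = vals.size
    return LaplacianImage(values=vals, n_pixels=n, mean=float(vals.mean()))


def sharpness(
    image,
    denoise: bool = False,
    background_percentile: float = 10.0,
    neighbours: int = 4,
) -> float:
    """Variance-of-Laplacian sharpness value (population variance, divisor N)."""
    arr = _as_float_image(image)
    if denoise:
        arr = subtract_background(arr, enabled=True, percentile=background_percentile)
    lap = laplacian(arr, neighbours=neighbours)
    d = lap.values - lap.mean
    return float(np.mean(d * d))
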