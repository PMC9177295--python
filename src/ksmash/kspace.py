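"""Image/K-space data model and the Fourier encoding operators.

MRI raw data live in K-space, the 2D spatial-frequency domain: each
phase-encode step fills one row of a Cartesian grid, and the image is the
inverse Fourier transform of the filled grid.  This module fixes the
discrete conventions used throughout the package:

* unitary (``norm="ortho"``) transforms on both directions, so Parseval's
  identity holds symmetrically;
* the zero-frequency sample sits at row ``N_y // 2``, column ``N_x // 2``
  (``fftshift`` convention);
* the forward transform carries the physics sign ``e^{-2*pi*j k.r}``;
* the y-grid underlying the spatial harmonics is ``y_n = n / N_y`` in
  field-of-view units, so ``e^{-2*pi*j m dk_y y}`` is periodic over the grid
  and multiplying an image by it shifts its K-space by exactly ``m`` rows.

Images are complex throughout; magnitude is taken only at display/metric
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ImagePlane",
    "KSpaceGrid",
    "CoilArray",
    "MultiCoilKSpace",
    "kspace_spacing",
    "forward_encode",
    "encode_array",
    "inverse_recon",
]


class ValidationError(ValueError):
    """An input violated a documented precondition or type invariant."""


def _as_complex_2d(arr, what: str) -> np.ndarray:
    out = np.asarray(arr, dtype=complex)
    if out.ndim != 2:
        raise ValidationError(f"{what} must be a 2D grid, got ndim={out.ndim}")
    if out.shape[0] < 2 or out.shape[1] < 2:
        raise ValidationError(f"{what} must be at least 2x2, got {out.shape}")
    return out


@dataclass
class ImagePlane:
    """A complex 2D image rho(x, y) with its physical field of view.

    Rows index y (phase-encode direction), columns index x (frequency-encode
    direction).  ``fov_x``/``fov_y`` are the physical extents in cm.
    """

    pixels: np.ndarray
    fov_x: float = 1.0
    fov_y: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = _as_complex_2d(self.pixels, "ImagePlane.pixels")
        if not (self.fov_x > 0 and self.fov_y > 0):
            raise ValidationError(
                f"field of view must be positive, got ({self.fov_x}, {self.fov_y})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("ImagePlane.pixels must be finite")

    @property
    def n_y(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_x(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.pixels)


def kspace_spacing(fov_x: float, fov_y: float) -> tuple[float, float]:
    """Spatial-frequency spacing (cycles/cm) paired with a field of view.

    The Cartesian K-space sample spacing is the reciprocal of the physical
    extent on each axis: ``dk = 1 / FOV``.
    """
    if not (fov_x > 0 and fov_y > 0):
        raise ValidationError(
            f"field of view must be positive, got ({fov_x}, {fov_y})"
        )
    return 1.0 / fov_x, 1.0 / fov_y


@dataclass
class KSpaceGrid:
    """A Cartesian K-space grid with a per-row phase-encode sampling mask.

    ``samples[i, j]`` is the complex signal at ``k_y = (i - N_y//2) dk_y``,
    ``k_x = (j - N_x//2) dk_x``.  ``mask[i]`` is True iff row ``i`` was
    acquired; unacquired rows are identically zero.
    """

    samples: np.ndarray
    dk_x: float
    dk_y: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = _as_complex_2d(self.samples, "KSpaceGrid.samples")
        if not (self.dk_x > 0 and self.dk_y > 0):
            raise ValidationError("K-space spacing must be positive")
        if self.mask is None:
            self.mask = np.ones(self.samples.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.samples.shape[0],):
            raise ValidationError(
                f"mask length {self.mask.shape} does not match "
                f"{self.samples.shape[0]} phase-encode rows"
            )
        if np.any(self.samples[~self.mask] != 0):
            raise ValidationError("unsampled rows must be exactly zero")

    @property
    def n_y(self) -> int:
        return self.samples.shape[0]

    @property
    def n_x(self) -> int:
        return self.samples.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    @property
    def fov_x(self) -> float:
        return 1.0 / self.dk_x

    @property
    def fov_y(self) -> float:
        return 1.0 / self.dk_y


@dataclass
class CoilArray:
    """Per-coil complex sensitivity maps S_i(x, y), stacked (N_c, N_y, N_x)."""

    sensitivities: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=complex)
        if s.ndim != 3 or s.shape[0] < 1:
            raise ValidationError(
                "sensitivities must be a stack of >=1 2D maps (N_c, N_y, N_x)"
            )
        if not np.all(np.isfinite(s)):
            raise ValidationError("sensitivity maps must be finite")
        if np.any(np.abs(s).max(axis=0) == 0):
            raise ValidationError(
                "at every pixel at least one coil must have nonzero sensitivity"
            )
        self.sensitivities = s

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.sensitivities.shape[1:]

    def __iter__(self):
        return iter(self.sensitivities)


@dataclass
class MultiCoilKSpace:
    """Per-coil K-space grids sharing one sampling mask and spacing."""

    coils: list[KSpaceGrid]

    def __post_init__(self) -> None:
        if len(self.coils) < 1:
            raise ValidationError("need at least one coil grid")
        first = self.coils[0]
        for g in self.coils[1:]:
            if g.shape != first.shape:
                raise ValidationError("all coil grids must share one shape")
            if not np.array_equal(g.mask, first.mask):
                raise ValidationError("all coil grids must share one mask")
            if (g.dk_x, g.dk_y) != (first.dk_x, first.dk_y):
                raise ValidationError("all coil grids must share one spacing")

    @property
    def n_coils(self) -> int:
        return len(self.coils)

    @property
    def mask(self) -> np.ndarray:
        return self.coils[0].mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.coils[0].shape

    @property
    def dk_x(self) -> float:
        return self.coils[0].dk_x

    @property
    def dk_y(self) -> float:
        return self.coils[0].dk_y

    def stack(self) -> np.ndarray:
        """All coil samples as one (N_c, N_y, N_x) array."""
        return np.stack([g.samples for g in self.coils])


def forward_encode(image: ImagePlane, coil) -> KSpaceGrid:
    """Encode an image through one coil: centered DFT of ``S_i * rho``.

    The signal received by coil ``i`` is the Fourier transform of the
    sensitivity-weighted spin density.  The returned grid is fully sampled
    (mask all-true) with ``dk = 1/FOV`` spacing.
    """
    coil = _as_complex_2d(coil, "coil sensitivity")
    if coil.shape != image.shape:
        raise ValidationError(
            f"coil shape {coil.shape} does not match image {image.shape}"
        )
    weighted = coil * image.pixels
    samples = np.fft.fftshift(np.fft.fft2(weighted, norm="ortho"))
    dk_x, dk_y = kspace_spacing(image.fov_x, image.fov_y)
    return KSpaceGrid(samples=samples, dk_x=dk_x, dk_y=dk_y)


def encode_array(image: ImagePlane, coils: CoilArray) -> MultiCoilKSpace:
    """Vectorize :func:`forward_encode` over a coil array."""
    if coils.shape != image.shape:
        raise ValidationError(
            f"coil maps {coils.shape} do not match image {image.shape}"
        )
    return MultiCoilKSpace([forward_encode(image, s) for s in coils])


def inverse_recon(kspace: KSpaceGrid) -> ImagePlane:
    """Centered inverse DFT of a K-space grid (zero-filled where unsampled)."""
    pixels = np.fft.ifft2(np.fft.ifftshift(kspace.samples), norm="ortho")
    return ImagePlane(pixels=pixels, fov_x=kspace.fov_x, fov_y=kspace.fov_y)
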