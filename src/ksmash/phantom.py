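"""Synthetic phantoms, coil sensitivity maps, noise and undersampling.

Everything downstream (calibration, line synthesis, combination, metrics)
is exercised on data from this module, so its defaults define the
package's benchmark acquisition: a 64x64 ellipse phantom, 8 Gaussian-profile
coils, twofold phase-encode undersampling with 4 autocalibration (ACS)
rows, and complex Gaussian receiver noise at 2% of the K-space peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspace import (
    CoilArray,
    ImagePlane,
    KSpaceGrid,
    MultiCoilKSpace,
    ValidationError,
)

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "UndersamplingScheme",
    "NoiseModel",
    "default_phantom_spec",
    "make_phantom",
    "make_coil_array",
    "undersample",
    "acs_rows",
    "add_noise",
]

COIL_PROFILES = ("harmonic_exact", "gaussian")


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse; geometry in field-of-view fractions."""

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float
    rotation: float = 0.0  # degrees, counter-clockwise
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.semi_axis_x > 0 and self.semi_axis_y > 0):
            raise ValidationError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    ellipses: tuple[Ellipse, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        if len(self.ellipses) == 0:
            raise ValidationError("phantom spec needs at least one ellipse")


def default_phantom_spec() -> PhantomSpec:
    """Benchmark phantom: one large background ellipse plus two inserts."""
    return PhantomSpec(
        ellipses=(
            Ellipse(0.5, 0.5, 0.40, 0.35, 0.0, 1.0),
            Ellipse(0.38, 0.45, 0.12, 0.16, 20.0, 0.6),
            Ellipse(0.64, 0.58, 0.08, 0.10, -15.0, 0.3),
        )
    )


@dataclass(frozen=True)
class UndersamplingScheme:
    """Regular phase-encode undersampling with central ACS rows.

    ``r`` is the acceleration factor (every r-th row acquired), ``offset``
    the index of the first sampled row in each period, and ``n_acs`` the
    number of fully sampled central autocalibration rows kept in addition.
    """

    r: int
    n_acs: int = 0
    offset: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValidationError("acceleration factor must be >= 1")
        if not (0 <= self.offset < self.r):
            raise ValidationError("offset must satisfy 0 <= offset < r")
        if self.n_acs < 0:
            raise ValidationError("n_acs must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian noise per real/imaginary K-space component."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")


def make_phantom(
    spec: PhantomSpec,
    n_y: int,
    n_x: int,
    fov_x: float = 1.0,
    fov_y: float = 1.0,
) -> ImagePlane:
    """Rasterize an additive ellipse phantom.

    A pixel's value is the sum of intensities of every ellipse containing
    the pixel center.  Pixel centers sit at ``(j + 0.5)/N_x, (i + 0.5)/N_y``
    in FOV fractions.  Deterministic: same spec, same image.
    """
    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(tuple(spec))
    xs = (np.arange(n_x) + 0.5) / n_x
    ys = (np.arange(n_y) + 0.5) / n_y
    gx, gy = np.meshgrid(xs, ys)
    img = np.zeros((n_y, n_x))
    for e in spec.ellipses:
        dx = gx - e.center_x
        dy = gy - e.center_y
        theta = np.deg2rad(e.rotation)
        # rotate into the ellipse frame
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / e.semi_axis_x) ** 2 + (v / e.semi_axis_y) ** 2 <= 1.0
        img[inside] += e.intensity
    return ImagePlane(pixels=img, fov_x=fov_x, fov_y=fov_y)


def make_coil_array(
    n_c: int,
    n_y: int,
    n_x: int,
    profile: str = "gaussian",
) -> CoilArray:
    """Build a phased-array sensitivity stack.

    ``harmonic_exact``: x-independent complex exponentials
    ``S_i = (1/N_c) e^{-2*pi*j c_i n/N_y}`` with ``c_i = i - N_c//2``
    (0-based i), so every harmonic order present among the ``c_i`` is
    represented *exactly* by some weight vector — the idealized geometry
    under which SMASH line synthesis is error-free.

    ``gaussian``: real Gaussian bumps of width FOV/N_c centered at N_c
    evenly spaced y-positions — a smooth stand-in for a surface-coil array,
    under which the harmonic fit has a nonzero residual.
    """
    if n_c < 1:
        raise ValidationError("need at least one coil")
    y = np.arange(n_y) / n_y  # FOV fraction, matches the harmonic grid
    if profile == "harmonic_exact":
        orders = np.arange(n_c) - n_c // 2
        cols = np.exp(-2j * np.pi * orders[:, None] * y[None, :]) / n_c
    elif profile == "gaussian":
        centers = (np.arange(n_c) + 0.5) / n_c
        width = 1.0 / n_c
        cols = np.exp(-((y[None, :] - centers[:, None]) ** 2) / (2 * width**2))
        cols = cols.astype(complex)
    else:
        raise ValidationError(
            f"unknown coil profile {profile!r}; expected one of {COIL_PROFILES}"
        )
    maps = np.repeat(cols[:, :, None], n_x, axis=2)
    return CoilArray(sensitivities=maps)


def acs_rows(n_y: int, n_acs: int) -> np.ndarray:
    """Indices of the ``n_acs`` autocalibration rows centered on k_y = 0."""
    if n_acs > n_y:
        raise ValidationError("n_acs cannot exceed the number of rows")
    center = n_y // 2
    start = center - n_acs // 2
    return np.arange(start, start + n_acs)


def undersample(data: MultiCoilKSpace, scheme: UndersamplingScheme) -> MultiCoilKSpace:
    """Apply a regular undersampling mask (plus ACS rows) to all coils.

    Rows congruent to ``offset`` (mod r) and the central ACS rows are kept
    bit-identical; every other row is zeroed and flagged unsampled.
    Idempotent for a fixed scheme.
    """
    n_y = data.shape[0]
    if scheme.r > n_y:
        raise ValidationError(
            f"acceleration {scheme.r} exceeds the {n_y} phase-encode rows"
        )
    mask = np.zeros(n_y, dtype=bool)
    mask[scheme.offset :: scheme.r] = True
    mask[acs_rows(n_y, scheme.n_acs)] = True
    out = []
    for g in data.coils:
        samples = np.where(mask[:, None], g.samples, 0.0)
        out.append(
            KSpaceGrid(samples=samples, dk_x=g.dk_x, dk_y=g.dk_y, mask=mask & g.mask)
        )
    return MultiCoilKSpace(out)


def add_noise(data: MultiCoilKSpace, noise: NoiseModel) -> MultiCoilKSpace:
    """Add complex Gaussian receiver noise to every *acquired* sample.

    Noise of standard deviation ``sigma`` is drawn independently for the
    real and imaginary part of each sample of each coil; unsampled rows
    stay exactly zero.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(noise.seed)
    out = []
    for g in data.coils:
        n = rng.normal(0.0, noise.sigma or 0.0, size=(2, *g.shape))
        if noise.sigma == 0:
            samples = g.samples
        else:
            samples = g.samples + np.where(
                g.mask[:, None], n[0] + 1j * n[1], 0.0
            )
        out.append(KSpaceGrid(samples=samples, dk_x=g.dk_x, dk_y=g.dk_y, mask=g.mask))
    return MultiCoilKSpace(out)
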