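"""Reconstruction-quality metrics: SNR (dB) and the error image / ERR.

Both metrics compare pixel magnitudes, since a reconstruction may differ
from its reference by a global phase.

SNR is the log-ratio of total reconstructed magnitude to the root of the
summed squared magnitude difference,

    SNR = 20 log10( sum |I_rec| / sqrt( sum (|I_rec| - |I_ref|)^2 ) ),

in decibels; an exact reconstruction maps to +inf.  ERR is the summed
absolute magnitude difference ``sum |I_rec - I_ref|`` together with its
pixelwise error image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kspace import ImagePlane, ValidationError

__all__ = ["ReconReport", "snr", "err", "evaluate"]


def _mag(image) -> np.ndarray:
    if isinstance(image, ImagePlane):
        return image.magnitude
    return np.abs(np.asarray(image))


def _pair(rec, ref) -> tuple[np.ndarray, np.ndarray]:
    a, b = _mag(rec), _mag(ref)
    if a.shape != b.shape:
        raise ValidationError(
            f"image shapes differ: {a.shape} vs {b.shape}"
        )
    return a, b


@dataclass
class ReconReport:
    """Quality summary of one reconstruction against its reference."""

    snr_db: float
    err_total: float
    err_image: np.ndarray

    def __post_init__(self) -> None:
        if self.err_total < 0:
            raise ValidationError("err_total must be nonnegative")


def snr(rec, ref, root: bool = True, normalize: bool = False) -> float:
    """Signal-to-noise ratio of a reconstruction, in dB.

    ``root=False`` reproduces the raw printed form without the square root
    on the denominator; ``normalize=True`` rescales ``rec`` to match the
    reference's total magnitude before comparing.  Returns ``math.inf``
    when the images agree exactly in magnitude.
    """
    a, b = _pair(rec, ref)
    if normalize and a.sum() > 0:
        a = a * (b.sum() / a.sum())
    noise_sq = float(((a - b) ** 2).sum())
    denom = math.sqrt(noise_sq) if root else noise_sq
    if denom == 0:
        return math.inf
    return 20.0 * math.log10(float(a.sum()) / denom)


def err(rec, ref) -> tuple[float, np.ndarray]:
    """Error image and total ERR: pointwise and summed ``| |I_rec| - |I_ref| |``."""
    a, b = _pair(rec, ref)
    err_image = np.abs(a - b)
    return float(err_image.sum()), err_image


def evaluate(rec, ref, **snr_kwargs) -> ReconReport:
    """Bundle SNR and ERR against one reference into a report."""
    total, image = err(rec, ref)
    return ReconReport(snr_db=snr(rec, ref, **snr_kwargs), err_total=total, err_image=image)
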