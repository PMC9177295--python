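"""SMASH calibration and missing-line synthesis.

SMASH (simultaneous acquisition of spatial harmonics) exploits the fact
that a linear combination of phased-array coil sensitivities can
approximate a complex-exponential spatial harmonic,

    sum_i w_i^(m) S_i(x, y)  ~=  e^{-2*pi*j m dk_y y},

so that the same combination applied to the acquired K-space data shifts it
by ``m`` phase-encode rows:

    sum_i w_i^(m) I_i(k_x, k_y)  =  I^comp(k_x, k_y + m dk_y).

Fitting the weights (from known sensitivity maps, or self-calibrated from
central ACS rows) and applying them to the acquired rows therefore fills
the rows skipped by the accelerated acquisition; an inverse Fourier
transform of the completed composite grid yields the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kspace import (
    CoilArray,
    ImagePlane,
    KSpaceGrid,
    MultiCoilKSpace,
    ValidationError,
    inverse_recon,
)
from .phantom import UndersamplingScheme

__all__ = [
    "HarmonicWeights",
    "harmonic_set",
    "target_harmonic",
    "fit_harmonic_weights",
    "fit_weights_from_acs",
    "synthesize_composite",
    "smash_reconstruct",
]


@dataclass
class HarmonicWeights:
    """Fitted coil weights per spatial-harmonic order.

    ``weights[m]`` is the length-N_c complex vector w^(m); ``residuals[m]``
    the attained root-mean-square misfit of the harmonic fit (0 for an
    exactly representable harmonic).  ``rank_deficient`` flags a
    sensitivity matrix solved by the minimum-norm solution.
    """

    weights: dict[int, np.ndarray]
    residuals: dict[int, float]
    harmonics: tuple[int, ...]
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.harmonics = tuple(self.harmonics)
        if 0 not in self.harmonics:
            raise ValidationError("the harmonic set must contain m = 0")
        if any(r < 0 for r in self.residuals.values()):
            raise ValidationError("residuals must be nonnegative")

    @property
    def n_coils(self) -> int:
        return len(self.weights[0])


def harmonic_set(r: int, mode: str = "forward") -> tuple[int, ...]:
    """Harmonic orders used for an acceleration factor ``r``.

    ``forward`` gives ``{0, 1, ..., r-1}``: exactly one synthesis rule per
    missing row offset within each undersampling period.  ``symmetric``
    gives the ``{-r/2, ..., r/2}`` set (r+1 orders, redundant for even
    offsets but closer to the classical presentation).
    """
    if r < 1:
        raise ValidationError("acceleration factor must be >= 1")
    if mode == "forward":
        return tuple(range(r))
    if mode == "symmetric":
        return tuple(range(-(r // 2), r // 2 + 1))
    raise ValidationError(f"unknown harmonic mode {mode!r}")


def target_harmonic(m: int, dk_y: float, y_grid: np.ndarray) -> np.ndarray:
    """The order-``m`` spatial harmonic ``e^{-2*pi*j m dk_y y}`` on a y-grid."""
    y = np.asarray(y_grid, dtype=float)
    return np.exp(-2j * np.pi * m * dk_y * y)


def _harmonic_y_grid(n_y: int) -> np.ndarray:
    # y_n = n/N_y in FOV units with dk_y*FOV = 1, so the phase ramp is
    # exactly periodic and a unit harmonic is a one-row K-space shift.
    return np.arange(n_y) / n_y


def fit_harmonic_weights(
    coils: CoilArray,
    harmonics,
    ridge: float = 0.0,
    average_x: bool = False,
) -> HarmonicWeights:
    """Least-squares fit of coil weights to each target harmonic.

    For each order ``m`` the weight vector minimizes
    ``sum_pixels | sum_i w_i S_i(x,y) - e^{-2*pi*j m dk_y y} |^2``.
    With ``average_x=True`` the fit collapses to the classical 1D
    x-averaged profile fit; ``ridge > 0`` adds Tikhonov damping for
    ill-conditioned arrays.
    """
    harmonics = tuple(int(m) for m in harmonics)
    if 0 not in harmonics:
        harmonics = (0, *harmonics)
    n_c, n_y, n_x = coils.sensitivities.shape
    y = _harmonic_y_grid(n_y)
    if average_x:
        profiles = coils.sensitivities.mean(axis=2)  # (N_c, N_y)
        a = profiles.T  # (N_y, N_c)
        reps = 1
    else:
        a = coils.sensitivities.reshape(n_c, -1).T  # (N_y*N_x, N_c)
        reps = n_x
    rank_deficient = np.linalg.matrix_rank(a) < n_c
    weights: dict[int, np.ndarray] = {}
    residuals: dict[int, float] = {}
    for m in harmonics:
        t = target_harmonic(m, 1.0, y)  # dk_y * y_cm = n / N_y
        b = np.repeat(t[:, None], reps, axis=1).ravel() if reps > 1 else t
        if ridge > 0:
            ata = a.conj().T @ a + ridge * np.eye(n_c)
            w = np.linalg.solve(ata, a.conj().T @ b)
        else:
            w = np.linalg.lstsq(a, b, rcond=None)[0]
        weights[m] = w
        residuals[m] = float(np.sqrt(np.mean(np.abs(a @ w - b) ** 2)))
    return HarmonicWeights(
        weights=weights,
        residuals=residuals,
        harmonics=harmonics,
        rank_deficient=bool(rank_deficient),
    )


def _acs_run(mask: np.ndarray) -> np.ndarray:
    """Contiguous run of sampled rows containing the k_y = 0 row."""
    n_y = len(mask)
    center = n_y // 2
    if not mask[center]:
        return np.arange(0)
    lo = center
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = center
    while hi < n_y - 1 and mask[hi + 1]:
        hi += 1
    return np.arange(lo, hi + 1)


def fit_weights_from_acs(data: MultiCoilKSpace, harmonics) -> HarmonicWeights:
    """Self-calibrate harmonic weights from central ACS rows.

    For each order ``m`` the weights minimize
    ``sum | sum_i w_i I_i(k_x, k_y) - I^comp(k_x, k_y + m dk_y) |^2`` over
    all (k_x, k_y) with both rows inside the fully sampled central block,
    where ``I^comp = sum_i I_i`` is the equal-weight composite used as the
    calibration target.
    """
    harmonics = tuple(int(m) for m in harmonics)
    if 0 not in harmonics:
        harmonics = (0, *harmonics)
    acs = _acs_run(data.mask)
    # need |m|+1 source/target row pairs inside the block for each order m
    need = 2 * max(abs(m) for m in harmonics) + 1
    if len(acs) < need:
        raise ValidationError(
            f"calibration needs >= {need} contiguous central ACS rows for "
            f"harmonics {harmonics}; found {len(acs)}"
        )
    stack = data.stack()  # (N_c, N_y, N_x)
    comp = stack.sum(axis=0)  # (N_y, N_x)
    acs_set = set(int(r) for r in acs)
    weights: dict[int, np.ndarray] = {}
    residuals: dict[int, float] = {}
    n_c = data.n_coils
    rank_deficient = False
    for m in harmonics:
        src = np.array([k for k in acs if (k + m) in acs_set], dtype=int)
        if len(src) == 0:
            raise ValidationError(
                f"no ACS row pairs available for harmonic m={m}"
            )
        a = stack[:, src, :].reshape(n_c, -1).T  # (n_src*N_x, N_c)
        b = comp[src + m, :].ravel()
        rank_deficient = rank_deficient or np.linalg.matrix_rank(a) < n_c
        w = np.linalg.lstsq(a, b, rcond=None)[0]
        weights[m] = w
        residuals[m] = float(np.sqrt(np.mean(np.abs(a @ w - b) ** 2)))
    return HarmonicWeights(
        weights=weights,
        residuals=residuals,
        harmonics=harmonics,
        rank_deficient=bool(rank_deficient),
    )


def synthesize_composite(
    data: MultiCoilKSpace,
    weights: HarmonicWeights,
    scheme: UndersamplingScheme | None = None,
) -> KSpaceGrid:
    """Fill the composite K-space grid from acquired rows and fitted weights.

    Each acquired row contributes its m = 0 composite (data consistency);
    each missing row at index ``t`` is synthesized as
    ``sum_i w_i^(m) I_i(k_x, k_s)`` from an acquired source row ``k_s``
    with ``t = k_s + m`` (row indices mod N_y, exact under the discrete
    Fourier model).  When several (source, m) pairs reach the same row the
    smallest |m| wins, ties broken by the lower source index.
    """
    if weights.n_coils != data.n_coils:
        raise ValidationError(
            f"weights fitted for {weights.n_coils} coils, data has {data.n_coils}"
        )
    stack = data.stack()
    mask = data.mask
    n_y = stack.shape[1]
    acquired = np.flatnonzero(mask)
    if len(acquired) == 0:
        raise ValidationError("no acquired rows to synthesize from")
    comp = np.zeros(stack.shape[1:], dtype=complex)
    w0 = weights.weights[0]
    comp[acquired] = np.tensordot(w0, stack[:, acquired, :], axes=(0, 0))
    missing = np.flatnonzero(~mask)
    unreachable = []
    # candidate harmonics ordered by the collision policy: smallest |m| first
    orders = sorted((m for m in weights.harmonics if m != 0), key=abs)
    for t in missing:
        best = None
        for m in orders:
            s = (t - m) % n_y
            if mask[s]:
                cand = (abs(m), s, m)
                if best is None or cand < best:
                    best = cand
        if best is None:
            unreachable.append(int(t))
            continue
        _, s, m = best
        comp[t] = np.tensordot(weights.weights[m], stack[:, s, :], axes=(0, 0))
    if unreachable:
        raise ValidationError(
            f"rows {unreachable} are unreachable with harmonics "
            f"{weights.harmonics}; acquire more rows or widen the harmonic set"
        )
    return KSpaceGrid(samples=comp, dk_x=data.dk_x, dk_y=data.dk_y)


def smash_reconstruct(
    data: MultiCoilKSpace,
    calibration: CoilArray | None = None,
    scheme: UndersamplingScheme | None = None,
    harmonics=None,
    harmonic_mode: str = "forward",
    ridge: float = 0.0,
) -> ImagePlane:
    """Full SMASH pipeline: calibrate, synthesize missing rows, invert.

    ``calibration`` is a :class:`CoilArray` of known sensitivity maps; if
    None, weights are self-calibrated from the ACS rows of ``data``.  The
    harmonic set defaults to the forward set for the scheme's acceleration
    factor (or for the largest sampling gap when no scheme is given).
    """
    if harmonics is None:
        if scheme is not None:
            harmonics = harmonic_set(scheme.r, harmonic_mode)
        else:
            gaps = np.diff(np.flatnonzero(data.mask))
            r = int(gaps.max()) if len(gaps) else 1
            harmonics = harmonic_set(max(r, 1), harmonic_mode)
    if calibration is not None:
        weights = fit_harmonic_weights(calibration, harmonics, ridge=ridge)
    else:
        weights = fit_weights_from_acs(data, harmonics)
    composite = synthesize_composite(data, weights, scheme)
    return inverse_recon(composite)
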