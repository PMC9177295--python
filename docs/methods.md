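# Methods

## Signal model and discrete conventions

The acquisition model is the standard 2D Cartesian one: the signal
received by coil `i` is the Fourier transform of the sensitivity-weighted
spin density, `I_i(k) = F[S_i · ρ](k)`, on a grid with spacing
`Δk = 1/FOV` per axis (repetition time long and echo time short enough
that relaxation weighting can be ignored; no trajectory, gradient or
motion modeling). The continuous model does not fix the discrete details,
so the package pins them as follows:

* **Normalization** — unitary (`1/√N` per axis) in both directions, so
  Parseval's identity holds symmetrically and K-space and image energies
  are directly comparable.
* **Centering** — the `k = 0` sample sits at row `⌊N_y/2⌋`, column
  `⌊N_x/2⌋` (`fftshift` convention, the even-N standard).
* **Sign** — the forward transform carries `e^(−2πj k·r)`.
* **Harmonic y-grid** — `y_n = n/N_y` in FOV units, 0-based, so the
  order-m harmonic `e^(−2πj m Δk_y y)` is exactly periodic over the grid
  and modulating an image by it is exactly an m-row K-space shift. This
  identity is what makes the noiseless recovery tests exact rather than
  approximate.
* Images are complex throughout; magnitudes are taken only for display
  and metrics.

## SMASH calibration and synthesis

For each harmonic order `m` the coil weights solve the linear
least-squares problem

    min_w  Σ_pixels | Σ_i w_i S_i(x,y) − e^(−2πj m Δk_y y) |²

over all pixels (a 2D fit; the classical x-averaged 1D profile fit is
available via `average_x=True`, and an optional ridge parameter damps
ill-conditioned arrays — default 0, i.e. no regularization). Residuals
are stored per order as root-mean-square misfit; a rank-deficient
sensitivity matrix is solved minimum-norm and flagged.

Self-calibration (`fit_weights_from_acs`) instead regresses the acquired
coil rows onto the equal-weight composite `Σ_i I_i` shifted by `m` rows,
using every (k_x, row) pair inside the contiguous fully sampled central
block — the standard autocalibrating variant when sensitivity maps are
unavailable. Each order `m` requires `|m|+1` source/target row pairs,
i.e. `2|m|+1` contiguous ACS rows. Note the two calibration routes target
different composites: the sensitivity route targets the unit-sensitivity
composite `F[ρ]`, the ACS route the equal-weight composite
`F[ρ · Σ_i S_i]`. They coincide exactly when `Σ_i S_i ≡ 1` (the test
suite constructs such a sum-normalized array to verify the equivalence);
in general each is internally consistent but they reconstruct composites
differing by the fixed modulation `Σ_i S_i(y)`.

Synthesis fills each missing row `t` from an acquired row `s` with
`t = s + m` (row indices taken mod `N_y`, which is exact under the
discrete Fourier model) using the order-m weights; acquired rows keep
their own m = 0 composite (data consistency). The default harmonic set is
the forward set `{0, …, R−1}` — exactly one synthesis rule per missing
offset — with the symmetric set `{−R/2, …, R/2}` available; when a row is
reachable several ways the smallest `|m|` wins, ties broken by the lower
source row (low-order harmonics fit best). Unreachable rows raise a
validation error listing them.

## Coil combination

* **SOS** — `sqrt(Σ_i |I_i|²)`: sensitivity-blind baseline, invariant to
  per-coil phase.
* **Sensitivity-weighted** — each coil image is smoothed with a Gaussian
  filter (real and imaginary parts separately, reflective boundaries,
  default σ = 1 pixel, σ = 0 disables), then combined with the matched
  filter `Σ_i conj(S_i) Ĩ_i / Σ_i |S_i|²`, the optimal-SNR linear
  combiner for known sensitivities; an unnormalized variant (numerator
  only) is available. The magnitude is returned.

## Metrics and references

`SNR = 20·log10(Σ|I_rec| / sqrt(Σ(|I_rec|−|I_ref|)²))` in dB and
`ERR = Σ||I_rec|−|I_ref||` with its pixelwise error image. The root in
the SNR denominator makes the quotient an amplitude ratio, consistent
with the 20× prefactor; an `root=False` variant omits it. Metrics operate
on magnitudes (global phase is not meaningful), no intensity
renormalization is applied by default (`normalize=True` rescales the
reconstruction to the reference's total magnitude first), and an exact
match returns `+inf`.

Because the three pipelines produce images on different intensity scales
(unit composite, `sqrt(Σ|S|²)`-weighted, matched-filtered), each method
is referenced against **its own** fully sampled noiseless output: the
m = 0-weight composite reconstruction for SMASH, SOS of the fully sampled
per-coil images for SOS, and the matched-filter combination (no
smoothing) for the sensitivity-weighted pipeline. The reported SNR/ERR
therefore measure what undersampling and noise cost each method, not
fixed scale offsets between combination formulas.

## Synthetic benchmark

The generator emulates a single-slice Cartesian acquisition:

* **Phantom** — additive ellipses rasterized at pixel centers; default
  64×64, FOV 20 cm: one large background ellipse (intensity 1.0) plus two
  rotated interior ellipses (0.6 and 0.3), giving piecewise-constant
  structure with edges in both axes.
* **Coils** — `gaussian`: 8 real Gaussian-bump profiles of width FOV/N_c
  at evenly spaced y-positions (a smooth surface-array stand-in);
  `harmonic_exact`: complex-exponential profiles
  `(1/N_c)·e^(−2πj c_i Δk_y y)`, `c_i = i − ⌊N_c/2⌋`, for which the
  harmonic fit is exact — the regime where SMASH recovery is provably
  error-free.
* **Sampling** — every R-th phase-encode row (default R = 2, offset 0)
  plus `n_acs` central ACS rows (default 4; even counts occupy rows
  `⌊N_y/2⌋−n/2 … ⌊N_y/2⌋+n/2−1`).
* **Noise** — i.i.d. Gaussian on real and imaginary parts of each
  acquired sample, after undersampling (receiver noise per measured
  line), σ = 0.02·max|K-space| by default, seeded; benchmark comparisons
  average 20 seeds (1…20).

These sizes keep the full suite in seconds while still exhibiting the
qualitative orderings of interest. What the benchmark does **not** show:
realistic anatomy or contrast, measured coil sensitivities (no
Biot–Savart physics, no sensitivity estimation error), motion or flow
artifacts, non-Cartesian sampling, or noise correlation between coils.
Passing tests demonstrate the algebraic correctness of the operators and
the direction of the SNR/ERR orderings under these idealized conditions,
not clinical image quality.

On this benchmark the smoothing + sensitivity-weighted combination beats
SOS on every seed (≈ +5.8 dB mean), reproducing the claimed ordering. The
composite-K-space SMASH pipeline, by contrast, scores slightly below SOS
here: with 8 smooth Gaussian coils the unregularized least-squares
weights are large (`‖w‖² up to ≈ 7`), so synthesized rows amplify
receiver noise — the K-space analog of the g-factor penalty. This is a
property of the fixed benchmark geometry and noise level, not a defect;
with exactly representable harmonics (and in any low-noise setting) SMASH
recovery is exact, and the `ridge` option trades residual artifact for
noise when the geometry is unfavorable.

## Diagnostic statistics

Pearson chi-square on 2×2 positive/negative tables (1 df; Yates
correction off by default — the motivating tables have n ≈ 192 — and
available via flag); independent-samples pooled-variance t-test
(constant-and-equal samples return t = 0, p = 1; constant unequal samples
are rejected); ROC by threshold sweep with ties grouped and trapezoid
AUC, which equals the Mann–Whitney concordance probability with ties
counted one half — for a binary test the curve degenerates to
(0,0)–(FPR,TPR)–(1,1); sensitivity `tp/(tp+fn)` and misdiagnosis rate
`fp/(fp+tn)` (the false-positive rate, 1 − specificity, the standard
reading in this literature); and the anatomical indices
`notch width / bicondylar width` and `eminence width / notch width`.
Standard confusion-matrix definitions are used throughout.

## Degenerate inputs and numerical notes

Validation errors (a `ValueError` subclass) are raised for: non-positive
FOV, shape/mask mismatches, nonzero unsampled rows, dead pixels (all
coils zero), R exceeding the row count, insufficient ACS rows (message
names the needed count), unreachable rows, zero chi-square marginals,
single-class ROC labels, and non-positive ratio denominators. Least
squares uses `lstsq` with default rcond; the smoothing kernel is the
sampled, normalized Gaussian truncated at 4σ; file round trips store
float32 pairs (≈ 1e-7 relative precision) with masks preserved exactly.
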