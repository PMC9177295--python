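# ksmash

Parallel MRI reconstruction in the K-space domain, built around SMASH
(simultaneous acquisition of spatial harmonics), with a synthetic
phantom/coil/noise simulator, image-domain coil combination (sum-of-squares
and sensitivity-weighted), SNR/ERR image-quality metrics, and the small
diagnostic-statistics battery used when an imaging test is compared against
an invasive gold standard (chi-square, t-test, ROC/AUC, sensitivity and
misdiagnosis rate, knee anatomical ratio indices).

## The problem

MRI acquires data in K-space: each phase-encode step fills one row of a
Cartesian spatial-frequency grid, and scan time is proportional to the
number of rows. Parallel imaging trades rows for coils — a phased array of
receivers with distinct spatial sensitivities `S_i(x, y)` measures every
acquired row `N_c` times, and the redundancy is used to restore the rows
that were skipped.

SMASH does this restoration directly in K-space. A linear combination of
coil sensitivities is fitted to a spatial harmonic,

    sum_i w_i^(m) S_i(x, y)  ≈  e^(−2πj m Δk_y y),

and because modulating an image by that harmonic shifts its Fourier
transform by `m` rows, the same weights applied to the acquired data
synthesize the composite signal `m` rows away:

    sum_i w_i^(m) I_i(k_x, k_y)  =  I_comp(k_x, k_y + m Δk_y).

Fitting `w^(m)` for the offsets `m = 0 … R−1` (from known sensitivity maps,
or self-calibrated from central autocalibration (ACS) rows) fills every gap
left by an `R`-fold accelerated acquisition; one inverse FFT then yields the
image. The package also implements the image-domain alternatives the method
is compared against: per-coil zero-filled reconstruction combined by
sum-of-squares `sqrt(sum_i |I_i|²)`, and the improved combination in which
each coil image is denoised with a Gaussian smoothing filter and combined
with the matched filter `sum_i conj(S_i) Ĩ_i / sum_i |S_i|²`.

Reconstruction quality is scored by

    SNR = 20 log10( Σ|I_rec| / sqrt( Σ (|I_rec| − |I_ref|)² ) )   [dB]
    ERR = Σ |I_rec − I_ref|            (on pixel magnitudes)

## Worked example

```python
import ksmash as km
from ksmash.pipeline import RunConfig, compare_methods

# benchmark acquisition: 64x64 ellipse phantom, 8 Gaussian coils,
# R=2 with 4 ACS rows, complex noise at 2% of the K-space peak
table = compare_methods(RunConfig(), seeds=range(1, 21))
print(table.groupby("method")[["snr_db", "err_total"]].mean())
```

prints

```
           snr_db    err_total
method
sens    46.314931   503.781389
smash   37.798400  3171.986927
sos     40.518189  2775.279801
```

Each method is scored against its own fully sampled noiseless output, so
the numbers isolate what undersampling and noise cost that method. The
smoothing + sensitivity-weighted pipeline (`sens`) beats the sum-of-squares
baseline by ≈5.8 dB mean SNR (20 of 20 seeds) and cuts ERR about fivefold;
the composite-K-space SMASH pipeline (`smash`) pays a noise-amplification
penalty through its unregularized harmonic weights on this smooth Gaussian
coil geometry. With coils whose sensitivities represent the needed
harmonics exactly, SMASH recovery is exact to machine precision:

```python
scheme = km.UndersamplingScheme(r=2)
truth  = km.make_phantom(km.default_phantom_spec(), 64, 64, 20.0, 20.0)
coils  = km.make_coil_array(4, 64, 64, "harmonic_exact")
data   = km.undersample(km.encode_array(truth, coils), scheme)
rec    = km.smash_reconstruct(data, coils, scheme)
# relative ERR vs the fully sampled composite: 2.6e-15 (SNR 325.5 dB)
```

The statistics layer works on plain counts and vectors:

```python
from ksmash.stats import DiagnosticCounts, chi_square_2x2
stat, p = chi_square_2x2(DiagnosticCounts(66, 30), DiagnosticCounts(56, 40))
# stat = 2.2483, p = 0.1338
```

A `ksmash` command-line tool exposes the same pipeline as subcommands
`simulate`, `reconstruct`, `evaluate`, `compare` and `stats`; see
`ksmash --help`.

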