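import numpy as np
import pytest

import ksmash as km
from ksmash.pipeline import RunConfig, compare_methods
from ksmash.smash import fit_harmonic_weights, synthesize_composite


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def dft2_double_sum(field):
    """Brute-force centered unitary 2D DFT: the independent encoding oracle."""
    field = np.asarray(field, dtype=complex)
    n_y, n_x = field.shape
    out = np.zeros((n_y, n_x), dtype=complex)
    for p in range(n_y):
        for q in range(n_x):
            acc = 0.0 + 0.0j
            for n in range(n_y):
                for m in range(n_x):
                    phase = (p - n_y // 2) * n / n_y + (q - n_x // 2) * m / n_x
                    acc += field[n, m] * np.exp(-2j * np.pi * phase)
            out[p, q] = acc
    return out / np.sqrt(n_y * n_x)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def benchmark_table():
    """SNR/ERR per seed per method on the 20-seed benchmark acquisition."""
    return compare_methods(RunConfig(), seeds=range(1, 21))


@pytest.fixture(scope="session")
def exact_setup():
    """Noiseless exactly-representable scenario: 4 harmonic coils, R=2.

    Returns the phantom, coils, fully sampled and undersampled data, the
    fitted weights, and the reference image (the weights' own m=0 composite
    of the fully sampled data).
    """
    scheme = km.UndersamplingScheme(r=2, n_acs=0)
    truth = km.make_phantom(km.default_phantom_spec(), 64, 64, 20.0, 20.0)
    coils = km.make_coil_array(4, 64, 64, "harmonic_exact")
    full = km.encode_array(truth, coils)
    und = km.undersample(full, scheme)
    weights = fit_harmonic_weights(coils, (0, 1))
    reference = km.inverse_recon(synthesize_composite(full, weights))
    return {
        "truth": truth,
        "coils": coils,
        "full": full,
        "undersampled": und,
        "scheme": scheme,
        "weights": weights,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def sum_normalized_coils():
    """Three coils with sum_i S_i = 1 and harmonics ±1 exactly representable.

    Built from the harmonic basis f_c = e^{-2*pi*j c y}: the equal-weight
    composite of these coils is the unit-sensitivity composite, so ACS
    self-calibration and sensitivity-based fitting solve the same system.
    """
    n = 64
    y = np.arange(n) / n
    f0 = np.ones(n)
    f1 = np.exp(-2j * np.pi * y)
    fm1 = np.exp(2j * np.pi * y)
    profiles = np.stack([f0 / 3 + f1, f0 / 3 - f1 + fm1, f0 / 3 - fm1])
    return km.CoilArray(np.repeat(profiles[:, :, None], n, axis=2))
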