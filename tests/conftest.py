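import numpy as np
import pytest

from nanosens import ModelParams, PoreSpectrum, SpectrumKind


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def normal_spectrum(params):
    sp = PoreSpectrum.from_kind(SpectrumKind.normal, X=params.X)
    sp.normalize(params.xi_g, params.Png, params.Du0)
    return sp


@pytest.fixture(scope="session")
def abnormal_spectrum(params):
    sp = PoreSpectrum.from_kind(SpectrumKind.abnormal_a, X=params.X)
    sp.normalize(params.xi_g, params.Pag, params.Du0)
    return sp


@pytest.fixture(scope="session")
def all_spectra(params):
    out = {}
    for kind, target in [("n", params.Png), ("a", params.Pag),
                         ("b", params.Pag), ("c", params.Pag)]:
        sp = PoreSpectrum.from_kind(kind, X=params.X)
        sp.normalize(params.xi_g, target, params.Du0)
        out[kind] = sp
    return out


def trapezoid_reference(func, a, b, n=100_000):
    """Brute-force fixed-step trapezoid integral, the quadrature oracle."""
    x = np.linspace(a, b, n)
    return np.trapezoid(func(x), x)
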