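"""Transvascular transport coefficients of nanoparticles.

Capillary walls are perforated by cylindrical pores whose radii follow a
spectrum that differs between preexisting ("normal") capillaries and
VEGF-affected ("abnormal") ones.  A spherical particle of radius ``xi``
entering a pore of radius ``x`` is subject to steric exclusion (only the
pore cross-section at distance > xi from the wall is accessible to its
center) and to hydrodynamic hindrance, approximated by the empirical
Renkin polynomial.  Convolving these single-pore factors with a pore
spectrum yields the capillary-scale coefficients used by the tissue model:
the available-area fraction ``gamma_yu(xi)`` for advective inflow and the
diffusive permeability ``P_yu(xi)``.

The absolute pore count of each capillary type is not observable directly;
it is anchored by requiring that the diffusive permeability evaluated at
the hydrodynamic radius of glucose reproduces the measured glucose
permeability of that capillary type.

Pore and particle radii are handled in nanometres throughout this module;
permeabilities and diffusion coefficients carry the model's internal units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "SpectrumKind",
    "PoreSpectrum",
    "NanoparticleSpec",
    "eval_pore_spectrum",
    "steric_exclusion",
    "renkin_hindrance",
    "size_coefficients",
    "pore_count_norm",
    "diffusive_permeability",
    "available_area_fraction",
    "pore_area_fraction",
    "abnormal_hydraulic_conductivity",
]

_QUAD_OPTS = dict(epsabs=1e-9, epsrel=1e-10, limit=400)


class SpectrumKind(str, Enum):
    normal = "n"
    abnormal_a = "a"
    abnormal_b = "b"
    uniform_c = "c"


def _density_normal(x):
    return x**3.7 * np.exp(-(x**0.9))


def _density_abnormal_a(x):
    return x**11 * np.exp(-(x**0.85))


def _density_abnormal_b(x):
    return x**13 * np.exp(-(x**0.8))


def _density_uniform(x):
    return np.ones_like(np.asarray(x, dtype=float))


_DENSITIES: dict[SpectrumKind, Callable] = {
    SpectrumKind.normal: _density_normal,
    SpectrumKind.abnormal_a: _density_abnormal_a,
    SpectrumKind.abnormal_b: _density_abnormal_b,
    SpectrumKind.uniform_c: _density_uniform,
}


def eval_pore_spectrum(kind: SpectrumKind | str, x, X: float = 100.0):
    """Unnormalized pore-radius density of the named spectrum at ``x`` nm."""
    kind = SpectrumKind(kind)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > X):
        raise ValueError(f"pore radius outside [0, {X}] nm")
    out = _DENSITIES[kind](x)
    return out if out.ndim else float(out)


def steric_exclusion(xi, x):
    """Fraction of a pore cross-section accessible to a particle center.

    ``A(xi, x) = (x - xi)^2 / x^2`` for ``x > xi`` and 0 otherwise; the
    limiting cases are a point particle (A = 1) and a particle too large
    for the pore (A = 0).
    """
    xi = np.asarray(xi, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(xi < 0):
        raise ValueError("particle radius must be nonnegative")
    if np.any(x <= 0):
        raise ValueError("pore radius must be positive")
    out = np.where(x > xi, (x - xi) ** 2 / x**2, 0.0)
    return out if out.ndim else float(out)


def renkin_hindrance(xi, x):
    """Renkin hydrodynamic hindrance of a sphere in a cylindrical pore.

    ``R = 1 - 2.1 l + 2.09 l^3 - 0.95 l^5`` with ``l = xi/x``; decreasing
    from 1 at l = 0 to 0.04 at l = 1.
    """
    lam = np.asarray(xi, dtype=float) / np.asarray(x, dtype=float)
    if np.any(lam < 0) or np.any(lam > 1):
        raise ValueError("Renkin hindrance requires 0 <= xi/x <= 1")
    out = 1.0 - 2.1 * lam + 2.09 * lam**3 - 0.95 * lam**5
    return out if out.ndim else float(out)


def size_coefficients(xi: float, Du0: float, Cu0: float) -> tuple[float, float]:
    """Tissue diffusion coefficient and blood clearance rate of a particle.

    ``Du = Du0/xi`` (Stokes-Einstein scaling) and ``Cu = Cu0*xi`` (larger
    particles are filtered from the blood faster).
    """
    if xi <= 0:
        raise ValueError("particle radius must be positive")
    return Du0 / xi, Cu0 * xi


def _per_pore_permeability(xi: float, x: float, Du0: float) -> float:
    """P(xi, x) = A * Du(xi) * R, defined only where the pore admits the particle."""
    a = steric_exclusion(xi, x)
    if a == 0.0:
        return 0.0
    return a * (Du0 / xi) * renkin_hindrance(xi, x)


@dataclass
class PoreSpectrum:
    """A pore-radius density on [0, X] nm with its pore-count normalization.

    ``Ny`` is set by :meth:`normalize` (or :func:`pore_count_norm`) so that
    the diffusive permeability evaluated at the glucose radius matches the
    glucose permeability target of the capillary type.
    """

    kind: SpectrumKind | None
    density: Callable
    X: float = 100.0
    Ny: float | None = None
    glucose_permeability_target: float | None = None

    @classmethod
    def from_kind(cls, kind: SpectrumKind | str, X: float = 100.0) -> "PoreSpectrum":
        kind = SpectrumKind(kind)
        return cls(kind=kind, density=_DENSITIES[kind], X=X)

    @classmethod
    def from_table(cls, x: np.ndarray, density: np.ndarray,
                   X: float | None = None) -> "PoreSpectrum":
        """Custom spectrum from tabulated (x, density) pairs, linearly interpolated."""
        x = np.asarray(x, dtype=float)
        density = np.asarray(density, dtype=float)
        if np.any(density < 0):
            raise ValueError("pore density must be nonnegative")
        if X is None:
            X = float(x.max())

        def interp(q):
            return np.interp(q, x, density, left=0.0, right=0.0)

        return cls(kind=None, density=interp, X=X)

    # -- evaluation ---------------------------------------------------------

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.X):
            raise ValueError(f"pore radius outside [0, {self.X}] nm")
        out = self.density(x)
        return out if np.ndim(out) else float(out)

    @property
    def normalized(self) -> bool:
        return self.Ny is not None

    def _require_norm(self) -> None:
        if not self.normalized:
            raise RuntimeError(
                "spectrum is not normalized; call normalize() with the "
                "glucose permeability target first")

    def normalize(self, xi_g: float, Pyg: float, Du0: float = 65.0) -> float:
        """Anchor the pore count to the glucose permeability of this capillary type."""
        self.Ny = pore_count_norm(self, xi_g, Pyg, Du0)
        self.glucose_permeability_target = Pyg
        self._Du0 = Du0
        return self.Ny


def pore_count_norm(spectrum: PoreSpectrum, xi_g: float, Pyg: float,
                    Du0: float = 65.0) -> float:
    """Pore-count normalization Ny matching the glucose permeability target.

    ``Ny = (1/Pyg) * int_0^X pi x^2 P(xi_g, x) PS(x) dx``; the integrand is
    identically zero below the particle radius, so the quadrature runs on
    [xi_g, X].
    """
    if Pyg <= 0:
        raise ValueError("glucose permeability target must be positive")
    if xi_g >= spectrum.X:
        raise ValueError("glucose radius must lie below the pore cutoff X")
    integral, _ = quad(
        lambda x: np.pi * x**2 * _per_pore_permeability(xi_g, x, Du0)
        * spectrum.density(x),
        xi_g, spectrum.X, **_QUAD_OPTS)
    if integral <= 0.0:
        raise ValueError("degenerate pore spectrum: permeability integral is 0")
    return integral / Pyg


def diffusive_permeability(spectrum: PoreSpectrum, xi: float,
                           Du0: float = 65.0) -> float:
    """Capillary diffusive permeability P_yu(xi) for particles of radius xi."""
    spectrum._require_norm()
    if xi < 0:
        raise ValueError("particle radius must be nonnegative")
    if xi >= spectrum.X:
        return 0.0
    integral, _ = quad(
        lambda x: np.pi * x**2 * _per_pore_permeability(xi, x, Du0)
        * spectrum.density(x),
        max(xi, 0.0), spectrum.X, **_QUAD_OPTS)
    return integral / spectrum.Ny


def available_area_fraction(spectrum: PoreSpectrum, xi: float) -> float:
    """Pore-area-weighted fraction gamma_yu(xi) available to particles of radius xi."""
    if xi < 0:
        raise ValueError("particle radius must be nonnegative")
    denom, _ = quad(lambda x: np.pi * x**2 * spectrum.density(x),
                    0.0, spectrum.X, **_QUAD_OPTS)
    if denom <= 0.0:
        raise ValueError("degenerate pore spectrum: zero total pore area")
    if xi >= spectrum.X:
        return 0.0
    num, _ = quad(
        lambda x: np.pi * x**2 * steric_exclusion(xi, x) * spectrum.density(x),
        max(xi, 0.0), spectrum.X, **_QUAD_OPTS)
    return num / denom


def pore_area_fraction(spectrum: PoreSpectrum) -> float:
    """Capillary surface area fraction occupied by pores, int pi x^2 PS(x)/Ny dx."""
    spectrum._require_norm()
    integral, _ = quad(lambda x: np.pi * x**2 * spectrum.density(x),
                       0.0, spectrum.X, **_QUAD_OPTS)
    return integral / spectrum.Ny


def abnormal_hydraulic_conductivity(normal: PoreSpectrum,
                                    abnormal: PoreSpectrum,
                                    Ln: float) -> float:
    """Hydraulic conductivity of abnormal capillaries.

    Scales the normal-capillary conductivity by the ratio of the fractions
    of capillary surface area occupied by pores; both spectra must be
    pore-count normalized first.
    """
    return Ln * pore_area_fraction(abnormal) / pore_area_fraction(normal)


@dataclass
class NanoparticleSpec:
    """A nanoparticle size choice with all its derived transport coefficients.

    The particle is a sphere of radius ``xi`` nm whose outer ``psi`` nm are
    an inert polymer coat; only the core volume fraction
    ``((xi - psi)/xi)^3`` is radiosensitizing.  Construction evaluates the
    size-dependent coefficients against one normal and one abnormal pore
    spectrum.
    """

    xi: float
    psi: float
    Du0: float
    Cu0: float
    kappa: float
    Ku: float
    # derived
    Du: float = field(init=False)
    Cu: float = field(init=False)
    gamma_nu: float = field(init=False)
    gamma_au: float = field(init=False)
    Pnu: float = field(init=False)
    Pau: float = field(init=False)

    def __init__(self, xi: float, psi: float,
                 normal_spectrum: PoreSpectrum,
                 abnormal_spectrum: PoreSpectrum,
                 Du0: float = 65.0, Cu0: float = 0.003,
                 kappa: float = 0.5, Ku: float = 100.0) -> None:
        if not xi > psi > 0:
            raise ValueError("particle radius must exceed the coating width")
        self.xi = float(xi)
        self.psi = float(psi)
        self.Du0, self.Cu0, self.kappa, self.Ku = Du0, Cu0, kappa, Ku
        self.Du, self.Cu = size_coefficients(xi, Du0, Cu0)
        self.gamma_nu = available_area_fraction(normal_spectrum, xi)
        self.gamma_au = available_area_fraction(abnormal_spectrum, xi)
        self.Pnu = diffusive_permeability(normal_spectrum, xi, Du0)
        self.Pau = diffusive_permeability(abnormal_spectrum, xi, Du0)
        for name in ("Du", "Cu", "gamma_nu", "gamma_au", "Pnu", "Pau"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"derived coefficient {name} is not finite")

    @property
    def active_fraction(self) -> float:
        """Volume fraction of the particle occupied by the active substance."""
        return ((self.xi - self.psi) / self.xi) ** 3

    @classmethod
    def from_params(cls, xi: float, params,
                    normal_spectrum: PoreSpectrum,
                    abnormal_spectrum: PoreSpectrum) -> "NanoparticleSpec":
        return cls(xi, params.psi, normal_spectrum, abnormal_spectrum,
                   Du0=params.Du0, Cu0=params.Cu0,
                   kappa=params.kappa, Ku=params.Ku)
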