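"""Instantaneous treatment events and radiosensitivity diagnostics.

Irradiation is modeled as an instantaneous event: the linear-quadratic
surviving fraction is evaluated per node with an effective dose locally
amplified by the bound active substance, and the damaged cells are moved
from the proliferating/quiescent pools to the damaged pool.  Injection is
a bolus added to the blood compartment.

Two scalar diagnostics summarize the tumor's radiosensitivity without
changing the state: the volume-averaged fraction of tumor cells that the
scheduled dose would damage if delivered now, and the total amount of
bound active substance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TreatmentSchedule", "effective_dose", "damaged_fraction",
           "apply_irradiation", "apply_injection",
           "potential_damaged_fraction", "bound_active_substance"]


@dataclass
class TreatmentSchedule:
    """Injection/irradiation timing.  Times in hours from simulation start.

    ``U0`` is the injected blood concentration in model units; the same
    total particle volume is injected regardless of the particle radius
    (the concentration normalization is absorbed into the dose-enhancement
    factor Ku), so the default is 1.
    """

    t_inj: float | None = None
    U0: float = 1.0
    t_irr: float | None = None
    dose: float = 2.0

    def __post_init__(self) -> None:
        if self.t_inj is not None and self.t_inj < 0:
            raise ValueError("injection time must be >= 0")
        if self.t_irr is not None and self.t_irr < 0:
            raise ValueError("irradiation time must be >= 0")
        if self.dose < 0 or self.U0 < 0:
            raise ValueError("dose and injected amount must be >= 0")


def effective_dose(u_b, xi: float, psi: float, Ku: float, D: float):
    """Locally amplified dose D_eff = D (1 + Ku u_b ((xi - psi)/xi)^3).

    Bound particles raise the local dose in proportion to their active-core
    volume fraction; without particles the cells still receive the full
    physical dose D.
    """
    if xi <= psi:
        raise ValueError("particle radius must exceed the coating width")
    active = ((xi - psi) / xi) ** 3
    return D * (1.0 + Ku * np.asarray(u_b, dtype=float) * active)


def damaged_fraction(Deff, k_x: float, alpha: float, beta: float):
    """Linear-quadratic damage probability Gamma = 1 - exp(-k_x (a D + b D^2))."""
    Deff = np.asarray(Deff, dtype=float)
    if np.any(Deff < 0):
        raise ValueError("effective dose must be nonnegative")
    out = 1.0 - np.exp(-k_x * (alpha * Deff + beta * Deff**2))
    return out if out.ndim else float(out)


def _gammas(state, spec, params, dose, species: int = 0):
    u_b = state.u_b[species] if state.u_b.shape[0] else np.zeros_like(state.n_p)
    if spec is not None:
        Deff = effective_dose(u_b, spec.xi, spec.psi, spec.Ku, dose)
    else:
        Deff = np.full_like(state.n_p, dose)
    gp = damaged_fraction(Deff, params.kp, params.alpha, params.beta)
    gq = damaged_fraction(Deff, params.kq, params.alpha, params.beta)
    return gp, gq


def apply_irradiation(state, schedule, params, species: int = 0):
    """Instantaneous irradiation: move the damaged fractions of n_p and n_q to m.

    Cell volume is transferred, not destroyed, so saturation is preserved
    exactly; damaged cells die (turn into fluid) only later, at the
    continuous rate M.  With several nanoparticle species attached the
    event is ambiguous, so it is restricted to single-species states.
    """
    if len(state.specs) > 1:
        raise ValueError("irradiation requires at most one nanoparticle species")
    spec = state.specs[species] if state.specs else None
    gp, gq = _gammas(state, spec, params, schedule.dose, species)
    damaged = gp * state.n_p + gq * state.n_q
    state.n_p *= 1.0 - gp
    state.n_q *= 1.0 - gq
    state.m += damaged
    return state


def apply_injection(state, schedule):
    """Bolus injection: add U0 to the blood concentration of every species."""
    state.u_bl += schedule.U0
    return state


def potential_damaged_fraction(state, params, grid, dose: float | None = None):
    """Tumor-wide fraction of cells the scheduled dose would damage right now.

    Volume-weighted aggregate
    ``int (Gamma_p n_p + Gamma_q n_q) r^2 dr / int (n_p + n_q) r^2 dr``
    over the whole domain, evaluated per nanoparticle species.  Returns a
    scalar for single-species states, an array otherwise, and NaN when no
    tumor cells remain.
    """
    if dose is None:
        dose = params.D_dose
    w = grid.volume
    cells = ((state.n_p + state.n_q) * w).sum()
    if cells <= 0.0:
        return float("nan") if len(state.specs) <= 1 else \
            np.full(len(state.specs), np.nan)
    n_species = max(len(state.specs), 1)
    out = np.empty(n_species)
    for i in range(n_species):
        spec = state.specs[i] if state.specs else None
        gp, gq = _gammas(state, spec, params, dose, i)
        out[i] = ((gp * state.n_p + gq * state.n_q) * w).sum() / cells
    return float(out[0]) if n_species == 1 else out


def bound_active_substance(state, grid):
    """Total bound active-substance volume, int u_b * active_fraction * 4 pi r^2 dr."""
    if not state.specs:
        return 0.0
    af = np.array([s.active_fraction for s in state.specs])
    totals = 4.0 * np.pi * (state.u_b * grid.volume).sum(axis=1) * af
    return float(totals[0]) if len(state.specs) == 1 else totals
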