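"""Model parameter bundle.

All quantities are expressed in the model's internal units: time in hours,
length in units of r_hat = 1e-2 cm (except nanoparticle and pore radii,
which are in nanometres), irradiation dose in Gy.  Concentration-like
variables (VEGF, glucose, capillary surface density, cell fractions) are
dimensionless after normalization; the nanoparticle concentration scale is
absorbed into the dose-enhancement factor ``Ku``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelParams", "load_params"]


@dataclass
class ModelParams:
    # --- cells ---
    B: float = 0.01          # maximum proliferation rate, 1/h
    sigma_p: float = 15.0    # critical solid stress for proliferation
    eps: float = 500.0       # smoothing parameter of the step functions
    M: float = 0.01          # death rate of radiation-damaged cells, 1/h

    # --- solid stress law ---
    k: float = 500.0         # stress coefficient
    ss: float = 0.3          # cell fraction below which cells do not interact
    s0: float = 0.8          # stress-free (rest) cell fraction

    # --- interstitial fluid ---
    Ln: float = 0.1          # hydraulic conductivity of normal capillaries
    La: float = 0.22         # hydraulic conductivity of abnormal capillaries
    pc: float = 4.0          # capillary blood pressure
    Ll: float = 1300.0       # hydraulic conductivity of lymphatic capillaries
    pl: float = 0.0          # lymph pressure
    K: float = 0.1           # tissue (Darcy) hydraulic conductivity

    # --- VEGF ---
    Sv: float = 1.0          # secretion rate by quiescent cells
    omega: float = 1.0       # internalization rate by capillaries
    Mv: float = 0.01         # nonspecific degradation rate
    Dv: float = 21.0         # diffusion coefficient

    # --- capillaries ---
    R_ang: float = 0.008     # maximum angiogenesis rate
    cmax: float = 5.0        # maximum capillary surface density
    Mc: float = 0.03         # characteristic degradation rate
    kM: float = 2.0          # degradation weighting in the tumor core
    Vn: float = 0.1          # normalization rate
    Vd: float = 0.1          # denormalization rate
    v_star: float = 0.001    # Michaelis constant for VEGF action
    Dc: float = 0.03         # active-motion coefficient of abnormal capillaries
    X: float = 100.0         # maximum capillary-wall pore radius, nm

    # --- glucose ---
    g_star: float = 0.01     # Michaelis constant for consumption
    Png: float = 4.0         # glucose permeability of normal capillaries
    Pag: float = 10.0        # glucose permeability of abnormal capillaries
    nu_g: float = 1200.0     # consumption parameter of proliferating cells
    Qhg: float = 0.5         # consumption rate of normal tissue
    Dg: float = 100.0        # diffusion coefficient
    xi_g: float = 0.36       # hydrodynamic radius of glucose, nm

    # --- irradiation ---
    alpha: float = 0.1       # linear radiosensitivity, 1/Gy
    beta: float = 0.01       # quadratic radiosensitivity, 1/Gy^2
    kp: float = 1.0          # sensitivity coefficient, proliferating cells
    kq: float = 0.2          # sensitivity coefficient, quiescent cells
    D_dose: float = 2.0      # clinical dose per fraction, Gy
    Ku: float = 100.0        # dose enhancement factor of the active substance

    # --- nanoparticles ---
    kappa: float = 0.5       # binding coefficient to tumor cells, 1/h
    psi: float = 7.0         # polymer coating width, nm
    Du0: float = 65.0        # diffusion coefficient parameter (Du = Du0/xi)
    Cu0: float = 0.003       # blood clearance parameter (Cu = Cu0*xi)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rates = ("B", "M", "Mv", "Mc", "Vn", "Vd", "R_ang", "Sv", "omega",
                 "Qhg", "kappa", "Cu0")
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"rate parameter {name} must be >= 0")
        if not 0.0 < self.ss < self.s0 < 1.0:
            raise ValueError("cell fractions must satisfy 0 < ss < s0 < 1")
        if self.pl > self.pc:
            raise ValueError("lymph pressure cannot exceed capillary pressure")
        if not 0.0 < self.psi:
            raise ValueError("coating width psi must be positive")
        if self.xi_g >= self.X:
            raise ValueError("glucose radius must lie below the pore cutoff X")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}


def load_params(path: str | Path) -> ModelParams:
    """Load parameters from a YAML or JSON config file.

    The document must be a flat mapping whose keys mirror the attribute
    names of :class:`ModelParams`; unknown keys are rejected so that typos
    do not silently fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    return ModelParams(**data)
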