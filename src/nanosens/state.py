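"""In-memory containers: radial grid, model state, diagnostic trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Grid", "State", "Trajectory"]


@dataclass
class Grid:
    """Uniform radial grid on [0, L] with two floating material boundaries.

    Nodes sit at ``r_i = i*dr`` and act as finite-volume cells with faces
    at the midpoints; the innermost cell is the sphere of radius ``dr/2``.
    ``R_tumor`` (tumor/normal-tissue interface) and ``R_tissue`` (outer
    edge of the normal tissue) are continuous radii that move with the
    solid phase, independently of the node spacing.
    """

    dr: float
    n: int
    R_tumor: float
    R_tissue: float
    r: np.ndarray = field(init=False)
    face_r: np.ndarray = field(init=False)       # n+1 faces, first at 0
    face_area: np.ndarray = field(init=False)    # r_face^2 (per steradian)
    volume: np.ndarray = field(init=False)       # cell volumes (per steradian)

    def __post_init__(self) -> None:
        self.r = np.arange(self.n) * self.dr
        faces = np.concatenate(([0.0], (self.r[:-1] + self.r[1:]) / 2,
                                [self.r[-1] + self.dr / 2]))
        self.face_r = faces
        self.face_area = faces**2
        self.volume = np.diff(faces**3) / 3.0
        if not 0.0 <= self.R_tumor < self.R_tissue <= self.r[-1]:
            raise ValueError("need 0 <= R_tumor < R_tissue <= domain extent")

    @property
    def extent(self) -> float:
        return float(self.r[-1])

    def node_inside(self, radius: float) -> int:
        """Index of the outermost node with r <= radius."""
        return int(np.searchsorted(self.r, radius, side="right") - 1)

    def cell_containing(self, radius: float) -> int:
        """Index of the cell whose volume contains the given radius."""
        j = int(np.floor(radius / self.dr + 0.5))
        return min(max(j, 0), self.n - 1)

    def fill_radius(self, j: int, fill: float) -> float:
        """Radius at which cell j is filled to the given volume fraction."""
        f3_in = self.face_r[j] ** 3
        f3_out = self.face_r[j + 1] ** 3
        return float(np.cbrt(f3_in + np.clip(fill, 0.0, 1.0)
                             * (f3_out - f3_in)))

    def fill_fraction(self, radius: float, j: int | None = None) -> float:
        """Volume fraction of the containing cell that lies inside ``radius``."""
        if j is None:
            j = self.cell_containing(radius)
        f3_in = self.face_r[j] ** 3
        f3_out = self.face_r[j + 1] ** 3
        return float(np.clip((radius**3 - f3_in) / (f3_out - f3_in),
                             0.0, 1.0))


@dataclass
class State:
    """All model fields at one instant.

    Tissue fields are arrays over the grid nodes; the nanoparticle fields
    carry a leading species axis so that several particle sizes can be
    propagated through the same (particle-independent) tissue dynamics,
    e.g. during a radius sweep.  ``specs`` holds one
    :class:`~nanosens.pores.NanoparticleSpec` per species.
    """

    n_p: np.ndarray   # proliferating tumor cells
    n_q: np.ndarray   # quiescent tumor cells
    h: np.ndarray     # normal cells
    m: np.ndarray     # radiation-damaged tumor cells
    v: np.ndarray     # VEGF
    c_n: np.ndarray   # normal capillary surface density
    c_a: np.ndarray   # abnormal capillary surface density
    g: np.ndarray     # glucose
    u_f: np.ndarray   # free nanoparticles, shape (n_species, n)
    u_b: np.ndarray   # bound nanoparticles, shape (n_species, n)
    u_bl: np.ndarray  # nanoparticle blood concentration, shape (n_species,)
    t: float = 0.0
    specs: list = field(default_factory=list)
    far: dict = field(default_factory=dict)  # Dirichlet far-field values

    @classmethod
    def zeros(cls, n: int, n_species: int = 0) -> "State":
        z = lambda: np.zeros(n)
        return cls(n_p=z(), n_q=z(), h=z(), m=z(), v=z(), c_n=z(), c_a=z(),
                   g=z(), u_f=np.zeros((n_species, n)),
                   u_b=np.zeros((n_species, n)), u_bl=np.zeros(n_species))

    @property
    def s(self) -> np.ndarray:
        """Total cell fraction; the fluid fraction is f = 1 - s."""
        return self.n_p + self.n_q + self.h + self.m

    @property
    def f(self) -> np.ndarray:
        return 1.0 - self.s

    TISSUE_FIELDS = ("n_p", "n_q", "h", "m", "v", "c_n", "c_a", "g")

    def copy(self) -> "State":
        return State(**{f: getattr(self, f).copy() for f in self.TISSUE_FIELDS},
                     u_f=self.u_f.copy(), u_b=self.u_b.copy(),
                     u_bl=self.u_bl.copy(), t=self.t, specs=list(self.specs),
                     far=dict(self.far))

    def spec_arrays(self) -> dict[str, np.ndarray]:
        """Per-species coefficient vectors, in species order."""
        def vec(attr):
            return np.array([getattr(s, attr) for s in self.specs])
        return {k: vec(k) for k in
                ("xi", "Du", "Cu", "gamma_nu", "gamma_au", "Pnu", "Pau",
                 "kappa", "Ku", "active_fraction")}

    def check_finite(self, where: str = "") -> None:
        total = (self.n_p.sum() + self.n_q.sum() + self.h.sum()
                 + self.m.sum() + self.v.sum() + self.c_n.sum()
                 + self.c_a.sum() + self.g.sum() + self.u_f.sum()
                 + self.u_b.sum() + self.u_bl.sum())
        if not np.isfinite(total):
            for name in self.TISSUE_FIELDS + ("u_f", "u_b", "u_bl"):
                if not np.all(np.isfinite(getattr(self, name))):
                    raise FloatingPointError(
                        f"non-finite values in field '{name}'"
                        + (f" after stage {where}" if where else ""))


class Trajectory:
    """Time series of scalar diagnostics plus optional spatial snapshots."""

    def __init__(self, species_radii: np.ndarray | None = None) -> None:
        self.times: list[float] = []
        self.records: list[dict] = []
        self.species_radii = species_radii
        self.snapshots: dict[float, pd.DataFrame] = {}

    def append(self, t: float, record: dict) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("trajectory times must be strictly increasing")
        self.times.append(t)
        self.records.append(record)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.records)
        frame.insert(0, "t", self.times)
        return frame

    def series(self, key: str) -> np.ndarray:
        return np.asarray([rec[key] for rec in self.records])
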