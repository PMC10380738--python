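"""Time integration: operator splitting on a uniform radial grid.

Each step applies, in order: (1) the mechanics update (stress, pressure,
velocities), (2) explicit-Euler kinetics plus the exactly-integrated blood
pool, (3) Crank-Nicolson diffusion for VEGF, glucose, abnormal capillaries
and free nanoparticles, (4) conservative flux-corrected transport (FCT)
for all advected fields, and (5) the floating-boundary update that keeps
the tumor interface and the outer tissue edge sharp.

Two deliberate deviations from plain explicit Euler inside the kinetics
stage: the glucose balance is advanced with an exponential (exact for
frozen coefficients) update, because its consumption rate constant grows
like 1/g* as glucose is depleted and would otherwise force a far smaller
global step; and the blood clearance ODE is advanced by its closed form.
Both reduce to forward Euler in the small-step limit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg.lapack import dgtsv as _dgtsv
from scipy.optimize import brentq

from .kinetics import kinetic_rhs
from .mechanics import _relax_cell_fraction, face_velocities, solid_stress
from .state import Grid, State, Trajectory
from .treatment import (TreatmentSchedule, apply_injection, apply_irradiation,
                        bound_active_substance, potential_damaged_fraction)

__all__ = ["steady_state_cell_fraction", "normal_glucose_steady",
           "initialize", "cn_diffuse", "fct_advect",
           "update_floating_boundaries", "advance", "run_simulation",
           "save_checkpoint", "load_checkpoint"]

log = logging.getLogger(__name__)

CFL_MAX = 0.9          # advection substeps are taken beyond this Courant number
_NEG_TOL = 1e-6        # tolerated undershoot before the integrator aborts
_S_CAP = 0.95          # cell-fraction cap when redepositing clipped boundary mass

CHECKPOINT_VERSION = 1


# --------------------------------------------------------------------------
# steady states and initial conditions
# --------------------------------------------------------------------------

def steady_state_cell_fraction(params, tol: float = 1e-12,
                               max_iter: int = 100) -> float:
    """Cell fraction of normal tissue in fluid equilibrium.

    Solves the coupled fixed point {p = Ln pc / (Ln + Ll s), sigma(s) = -p}:
    capillary inflow balances lymphatic drainage pointwise, and the slight
    fluid excess stretches the cell network a hair below the rest fraction
    s0 (for the default parameters by a few parts in 1e6).
    """
    # bracket the root nearest s0: from the adhesion minimum up to s0
    probe = np.linspace(params.ss, params.s0, 256)
    s_lo = float(probe[np.argmin(solid_stress(probe, params))])
    s = params.s0
    for _ in range(max_iter):
        p = params.Ln * params.pc / (params.Ln + params.Ll * s)
        s_new = brentq(lambda q: solid_stress(q, params) + p,
                       s_lo, params.s0, xtol=1e-15)
        if abs(s_new - s) <= tol * s:
            return s_new
        s = s_new
    raise RuntimeError("steady-state cell fraction iteration did not converge")


def normal_glucose_steady(params, sst: float | None = None) -> float:
    """Steady glucose level of normal tissue (inflow through c_n = 1)."""
    if sst is None:
        sst = steady_state_cell_fraction(params)

    def balance(g):
        return params.Png * (1.0 - g) \
            - params.Qhg * sst * g / (g + params.g_star)

    return brentq(balance, 0.0, 1.0, xtol=1e-15)


def initialize(params, dr: float = 0.5, extent: float = 80.0,
               R0T: float = 2.0, R0N: float = 40.0,
               specs=(), steady_glucose: bool = False) -> tuple[State, Grid]:
    """Initial condition: a small tumor colony centered in normal tissue.

    Inside ``R0T`` (0.2 mm by default) proliferating tumor cells sit at
    the normal-tissue steady fraction; between ``R0T`` and ``R0N`` (4 mm)
    normal cells and normal capillaries (c_n = 1) do.  Glucose starts at
    its normalization value 1 everywhere; ``steady_glucose=True`` instead
    starts it at the normal-tissue steady level, which makes a tumor-free
    configuration an exact fixed point of the scheme.  Beyond ``R0N`` the
    domain is cell-free fluid.  All remaining fields start at zero.
    """
    n = int(round(extent / dr)) + 1
    grid = Grid(dr=dr, n=n, R_tumor=R0T, R_tissue=R0N)
    if R0T > 0.0 and grid.node_inside(R0T) < 3:
        raise ValueError("grid too coarse: fewer than 4 nodes inside the "
                         "initial tumor radius")
    sst = steady_state_cell_fraction(params)
    state = State.zeros(n, n_species=len(specs))
    state.specs = list(specs)

    # fill cells by the volume fraction each region occupies, so the
    # floating fronts start exactly at R0T and R0N with partially filled
    # interface cells
    f3 = grid.face_r**3
    vol3 = np.diff(f3)
    tumor_frac = np.clip((np.minimum(f3[1:], R0T**3) - f3[:-1]) / vol3,
                         0.0, 1.0)
    tissue_frac = np.clip((np.minimum(f3[1:], R0N**3) - f3[:-1]) / vol3,
                          0.0, 1.0)
    normal_frac = tissue_frac - tumor_frac
    state.n_p[:] = sst * tumor_frac
    state.h[:] = sst * normal_frac
    state.c_n[:] = normal_frac
    g0 = normal_glucose_steady(params, sst) if steady_glucose else 1.0
    state.g[:] = g0
    state.far = {"v": 0.0, "g": g0, "c_a": 0.0, "u_f": 0.0}
    return state, grid


# --------------------------------------------------------------------------
# Crank-Nicolson diffusion
# --------------------------------------------------------------------------

_cn_cache: dict = {}


def _cn_operators(D: float, dt: float, grid: Grid):
    """Banded LHS and tridiagonal RHS coefficients for one CN step."""
    key = (grid.n, grid.dr, D, dt)
    op = _cn_cache.get(key)
    if op is not None:
        return op
    n, dr = grid.n, grid.dr
    area, vol = grid.face_area, grid.volume
    # conservative spherical Laplacian: (A_r (u_+ - u) - A_l (u - u_-)) / (V dr)
    upper = area[1:n] / (vol[: n - 1] * dr)          # coupling to node i+1
    lower = area[1:n] / (vol[1:n] * dr)              # coupling to node i-1
    diag = np.zeros(n)
    diag[: n - 1] -= upper
    diag[1:n] -= lower
    w = 0.5 * dt * D
    # LHS tridiagonal (du: above, d: main, dl: below), Dirichlet last row
    du_ = -w * upper
    d_ = 1.0 - w * diag
    dl_ = -w * lower
    d_[n - 1] = 1.0
    dl_[n - 2] = 0.0
    op = (dl_, d_, du_, w * upper, 1.0 + w * diag, w * lower)
    if len(_cn_cache) > 256:
        _cn_cache.clear()
    _cn_cache[key] = op
    return op


def cn_diffuse(field: np.ndarray, D: float, dt: float, grid: Grid,
               right_value: float = 0.0) -> np.ndarray:
    """One Crank-Nicolson step of spherical diffusion.

    Zero flux at the origin (the innermost face has zero area) and a fixed
    far-field value at the outer boundary.  Accepts a single field or a
    batch with a leading axis.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    if D == 0.0 or dt == 0.0:
        return field.copy()
    dl_, d_, du_, up, dg, lo = _cn_operators(D, dt, grid)
    batched = field.ndim == 2
    q = field if batched else field[None, :]
    rhs = dg * q
    rhs[:, :-1] += up * q[:, 1:]
    rhs[:, 1:] += lo * q[:, :-1]
    rhs[:, -1] = right_value
    _, _, _, out, info = _dgtsv(dl_.copy(), d_.copy(), du_.copy(),
                                rhs.T, overwrite_dl=1, overwrite_d=1,
                                overwrite_du=1, overwrite_b=True)
    if info != 0:
        raise FloatingPointError(f"singular tridiagonal system (info={info})")
    out = out.T
    return out if batched else out[0]


# --------------------------------------------------------------------------
# flux-corrected transport
# --------------------------------------------------------------------------

def fct_advect(field: np.ndarray, velocity: np.ndarray, dt: float,
               grid: Grid) -> np.ndarray:
    """One conservative FCT step of radial advection.

    Donor-cell (upwind) transport plus a flux-limited antidiffusive
    correction toward the second-order flux, so the result has no new
    extrema while fronts stay much sharper than with plain upwind.  Total
    content ``sum(field * cell_volume)`` changes only through the outer
    boundary flux (zero-gradient outflow there); the innermost face has
    zero area, so nothing leaks through the origin.  Accepts a single
    field or a batch with a leading axis; the velocity is shared.
    """
    n, dr = grid.n, grid.dr
    batched = field.ndim == 2
    q = field if batched else field[None, :]
    area, vol = grid.face_area, grid.volume

    if velocity.shape[0] == n + 1:      # already face-centered
        vf = velocity
    else:
        vf = np.empty(n + 1)
        vf[0] = 0.0
        vf[1:n] = 0.5 * (velocity[:-1] + velocity[1:])
        vf[n] = velocity[-1]

    cfl = np.abs(vf).max() * dt / dr
    if cfl > 1.0:
        raise FloatingPointError(f"advection Courant number {cfl:.2f} > 1")

    av = area * vf
    pos = vf > 0.0
    # low-order (donor cell) fluxes
    q_up = np.where(pos[1:n], q[:, :-1], q[:, 1:])
    F_low = np.empty((q.shape[0], n + 1))
    F_low[:, 0] = 0.0
    F_low[:, 1:n] = av[1:n] * q_up
    F_low[:, n] = av[n] * q[:, -1]          # zero-gradient outer boundary

    q_td = q - dt * np.diff(F_low, axis=1) / vol

    # antidiffusive fluxes toward the Lax-Wendroff face value
    F_high = np.empty_like(F_low)
    F_high[:, 0] = 0.0
    F_high[:, n] = F_low[:, n]
    c_face = vf[1:n] * dt / dr
    F_high[:, 1:n] = av[1:n] * (0.5 * (q[:, :-1] + q[:, 1:])
                                - 0.5 * c_face * (q[:, 1:] - q[:, :-1]))
    A = F_high - F_low

    # Zalesak limiter against the local extrema of q and q_td
    q_ref_max = np.maximum(q, q_td)
    q_ref_min = np.minimum(q, q_td)
    pad_max = np.concatenate([q_ref_max[:, :1], q_ref_max, q_ref_max[:, -1:]],
                             axis=1)
    pad_min = np.concatenate([q_ref_min[:, :1], q_ref_min, q_ref_min[:, -1:]],
                             axis=1)
    q_max = np.maximum(np.maximum(pad_max[:, :-2], pad_max[:, 1:-1]),
                       pad_max[:, 2:])
    q_min = np.minimum(np.minimum(pad_min[:, :-2], pad_min[:, 1:-1]),
                       pad_min[:, 2:])

    Ap = np.maximum(A, 0.0)
    Am = np.minimum(A, 0.0)
    # the threshold keeps denormal flux sums from underflowing to 0/0
    tiny = 1e-280
    P_plus = np.maximum(Ap[:, :-1] - Am[:, 1:], tiny)
    P_minus = np.maximum(Ap[:, 1:] - Am[:, :-1], tiny)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore",
                     under="ignore"):
        R_plus = np.minimum(1.0, (q_max - q_td) * vol / (dt * P_plus))
        R_minus = np.minimum(1.0, (q_td - q_min) * vol / (dt * P_minus))

    C = np.ones_like(A)
    interior = slice(1, n)
    A_int = A[:, interior]
    C[:, interior] = np.where(
        A_int >= 0.0,
        np.minimum(R_plus[:, 1:], R_minus[:, :-1]),
        np.minimum(R_plus[:, :-1], R_minus[:, 1:]))
    C = np.clip(C, 0.0, 1.0)

    q_new = q_td - dt * np.diff(C * A, axis=1) / vol
    return q_new if batched else q_new[0]


# --------------------------------------------------------------------------
# floating material boundaries
# --------------------------------------------------------------------------

def _clip_into(fields: list[np.ndarray], j: int, grid: Grid) -> None:
    """Move any field content in cells beyond j conservatively into cell j."""
    for fld in fields:
        tail = fld[j + 1:]
        if tail.size and tail.any():
            fld[j] += float((tail * grid.volume[j + 1:]).sum()) \
                / grid.volume[j]
            tail[:] = 0.0


def _track_front(fields: list[np.ndarray], j: int, grid: Grid,
                 riders: list[np.ndarray] = ()) -> tuple[int, float]:
    """Volume-fill front tracking for a material occupying cells <= j.

    The combined density of ``fields`` defines the material.  Content the
    advection stage smeared beyond the interface cell j is clipped back
    into it (``riders`` — e.g. bound nanoparticles at the tumor front —
    are clipped along, conserving their totals).  The interface cell is
    interpreted as partially filled at the dense-material density of its
    inner neighbor: when it fills up, the front advances one cell and the
    overflow moves outward; when it empties, the front retreats.  Returns
    the new interface cell index and its fill fraction, from which the
    front radius follows by cell-volume conservation.
    """
    n = grid.n
    _clip_into(list(fields) + list(riders), j, grid)
    density = lambda i: sum(float(f[i]) for f in fields)
    while True:
        dense = density(j - 1) if j > 0 else density(j)
        here = density(j)
        if here <= 0.0:
            if j == 0:
                return j, 0.0
            j -= 1
            continue
        if dense <= 0.0:
            dense = here
        if here >= dense and j < n - 2 and density(j - 1) > 0.0:
            # cell full: advance the front, pushing the excess outward
            excess = (here - dense) / here
            for f in fields:
                f[j + 1] += f[j] * excess * grid.volume[j] / grid.volume[j + 1]
                f[j] *= 1.0 - excess
            j += 1
            continue
        return j, min(here / dense, 1.0)


def update_floating_boundaries(state: State, grid: Grid, dt: float,
                               Is: np.ndarray | None = None) -> Grid:
    """Re-sharpen both material fronts and move them by volume conservation.

    The tumor/normal interface is tracked by the tumor-cell content of its
    interface cell, the outer tissue edge by the normal-cell content of
    its own; in both cases the front radius is the radius enclosing the
    conserved material volume at dense packing, which is what keeps the
    fronts from numerically diffusing (the tumor from artificially
    invading the normal tissue, the tissue edge from shredding into the
    surrounding fluid).  Capillaries are confined to the tissue the same
    way.  ``Is`` is unused (kept for signature compatibility with
    kinematic variants); ``dt`` likewise only documents the call site.
    """
    tumor_fields = [state.n_p, state.n_q, state.m]
    tumor_volume = float(((state.n_p + state.n_q + state.m)
                          * grid.volume).sum())
    if tumor_volume > 1e-12:
        j_t = grid.cell_containing(grid.R_tumor)
        riders = [state.u_b[k] for k in range(state.u_b.shape[0])]
        j_t, fill = _track_front(tumor_fields, j_t, grid, riders=riders)
        grid.R_tumor = grid.fill_radius(j_t, fill)

    if float((state.h * grid.volume).sum()) > 1e-12:
        j_n = grid.cell_containing(grid.R_tissue)
        j_n, fill = _track_front([state.h], j_n, grid)
        grid.R_tissue = grid.fill_radius(j_n, fill)
        # capillaries exist only within tissue
        _clip_into([state.c_n, state.c_a], j_n, grid)

    if not grid.R_tumor < grid.R_tissue:
        raise FloatingPointError("tumor interface overran the tissue boundary")
    return grid


def _extend_domain(state: State, grid: Grid, factor: float = 1.3
                   ) -> tuple[State, Grid]:
    """Grow the computational domain, padding the new nodes with far-field values."""
    n_new = int(np.ceil(grid.n * factor))
    new_grid = Grid(dr=grid.dr, n=n_new, R_tumor=grid.R_tumor,
                    R_tissue=grid.R_tissue)
    pad = n_new - grid.n
    for name in State.TISSUE_FIELDS:
        fill = state.far.get(name, 0.0)
        setattr(state, name,
                np.concatenate([getattr(state, name), np.full(pad, fill)]))
    state.u_f = np.pad(state.u_f, ((0, 0), (0, pad)))
    state.u_b = np.pad(state.u_b, ((0, 0), (0, pad)))
    log.info("domain extended to %d nodes (%.1f model lengths)",
             n_new, new_grid.extent)
    return state, new_grid


# --------------------------------------------------------------------------
# one full step and the outer loop
# --------------------------------------------------------------------------

def _clip_negative(name: str, arr: np.ndarray) -> None:
    low = arr.min()
    if low < -_NEG_TOL:
        idx = np.unravel_index(int(arr.argmin()), arr.shape)
        raise FloatingPointError(
            f"field '{name}' reached {low:.3e} at node {idx}")
    if low < 0.0:
        np.clip(arr, 0.0, None, out=arr)


_EULER_FIELDS = ("n_p", "n_q", "m", "v", "c_n", "c_a")


def _mechanics_fields(state: State, grid: Grid, params, dt: float):
    """Edge-aware mechanics stage shared by the time step and diagnostics.

    The partially filled tissue-edge cell enters the constitutive law at
    its dense-material values (its raw average under-reads the packing)
    and the cell-free region beyond the edge is mechanically void: no
    stress, no transvascular sources.  The stiff lymphatic-exchange mode
    is relaxed implicitly over ``dt`` before the velocities are built on
    the cell faces.

    Returns ``(sigma, p, Is_face, If_face)``.
    """
    j_n = grid.cell_containing(grid.R_tissue)
    fill = max(grid.fill_fraction(grid.R_tissue, j_n), 1e-3)
    s_eff = state.s.copy()
    Lc = params.Ln * state.c_n + params.La * state.c_a
    Lh = params.Ll * state.h
    s_eff[j_n] = min(s_eff[j_n] / fill, _S_CAP)
    Lc[j_n] /= fill
    Lh[j_n] /= fill
    s_eff[j_n + 1:] = 0.0
    Lc[j_n + 1:] = 0.0
    Lh[j_n + 1:] = 0.0
    s_star = _relax_cell_fraction(s_eff, Lc, Lh, params, dt) \
        if dt > 0.0 else s_eff
    weight = np.ones(grid.n)
    weight[j_n] = fill
    weight[j_n + 1:] = 0.0
    scale = np.maximum(weight, 1e-3)
    Is, If, sigma, p = face_velocities(s_star, state.h / scale,
                                       state.c_n / scale, state.c_a / scale,
                                       grid, params, source_weight=weight)
    return sigma, p, Is, If


def advance(state: State, grid: Grid, params, dt: float) -> tuple[State, Grid]:
    """Advance the coupled system by one operator-split step of length dt."""
    if dt == 0.0:
        return state, grid
    # (1) mechanics on cell faces, with the stiff drainage mode implicit
    sigma, p, Is, If = _mechanics_fields(state, grid, params, dt)

    # (2) kinetics: forward Euler, with exact updates for glucose and blood
    rates = kinetic_rhs(state, params, p, sigma)
    for name in _EULER_FIELDS:
        arr = getattr(state, name)
        arr += dt * rates[name]
        _clip_negative(name, arr)
    a, lam = rates["g_inflow"], rates["g_decay"]
    k_tot = a + lam
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-k_tot * dt)
        g_inf = np.where(k_tot > 0.0, a / np.maximum(k_tot, 1e-300), state.g)
    state.g = g_inf + (state.g - g_inf) * decay
    if state.specs:
        state.u_f += dt * rates["u_f"]
        state.u_b += dt * rates["u_b"]
        _clip_negative("u_f", state.u_f)
        Cu = np.array([sp.Cu for sp in state.specs])
        state.u_bl *= np.exp(-Cu * dt)

    # (3) Crank-Nicolson diffusion
    state.v = cn_diffuse(state.v, params.Dv, dt, grid, state.far["v"])
    state.g = cn_diffuse(state.g, params.Dg, dt, grid, state.far["g"])
    state.c_a = cn_diffuse(state.c_a, params.Dc, dt, grid, state.far["c_a"])
    for k, sp in enumerate(state.specs):
        state.u_f[k] = cn_diffuse(state.u_f[k], sp.Du, dt, grid,
                                  state.far["u_f"])

    # (4) FCT advection; substep if the Courant number is too large
    vmax = max(np.abs(Is).max(), np.abs(If).max())
    n_sub = max(int(np.ceil(vmax * dt / grid.dr / CFL_MAX)), 1)
    if n_sub > 1:
        log.warning("t=%.3f: Courant %.2f, advecting in %d substeps",
                    state.t, vmax * dt / grid.dr, n_sub)
    solid_stack = np.concatenate(
        [np.stack([state.n_p, state.n_q, state.h, state.m,
                   state.c_n, state.c_a]), state.u_b])
    fluid_stack = state.u_f
    for _ in range(n_sub):
        solid_stack = fct_advect(solid_stack, Is, dt / n_sub, grid)
        if fluid_stack.shape[0]:
            fluid_stack = fct_advect(fluid_stack, If, dt / n_sub, grid)
    (state.n_p, state.n_q, state.h, state.m,
     state.c_n, state.c_a) = solid_stack[:6]
    state.u_b = solid_stack[6:]
    state.u_f = fluid_stack

    # (5) floating boundaries
    update_floating_boundaries(state, grid, dt, Is)
    if grid.R_tissue > grid.extent - 3.0 * grid.dr:
        state, grid = _extend_domain(state, grid)

    state.t += dt
    state.check_finite()
    return state, grid


def _diagnostics(state: State, grid: Grid, params) -> dict:
    from .treatment import damaged_fraction
    tumor_cells = state.n_p + state.n_q + state.m
    w = grid.volume
    live = ((state.n_p + state.n_q) * w).sum()
    if live > 0.0:
        gp = damaged_fraction(params.D_dose, params.kp, params.alpha,
                              params.beta)
        gq = damaged_fraction(params.D_dose, params.kq, params.alpha,
                              params.beta)
        pdf0 = float((gp * (state.n_p * w).sum()
                      + gq * (state.n_q * w).sum()) / live)
    else:
        pdf0 = float("nan")
    rec = {
        "pdf_baseline": pdf0,
        "R_tumor": grid.R_tumor,
        "R_tissue": grid.R_tissue,
        "tumor_cell_volume": 4.0 * np.pi * float(
            (tumor_cells * grid.volume).sum()),
        "pdf": potential_damaged_fraction(state, params, grid),
        "bound_active": bound_active_substance(state, grid),
        "u_bl": (float(state.u_bl[0]) if state.u_bl.size == 1
                 else state.u_bl.copy()),
        "p_max": float(_mechanics_fields(state, grid, params, 0.0)[1].max()),
    }
    return rec


def _snapshot(state: State, grid: Grid, params) -> pd.DataFrame:
    sigma, p, Is_f, If_f = _mechanics_fields(state, grid, params, 0.0)
    Is = 0.5 * (Is_f[:-1] + Is_f[1:])
    If = 0.5 * (If_f[:-1] + If_f[1:])
    cols = {"r": grid.r, "np": state.n_p, "nq": state.n_q, "h": state.h,
            "m": state.m, "f": state.f, "v": state.v, "cn": state.c_n,
            "ca": state.c_a, "g": state.g,
            "uf": (state.u_f[0] if state.u_f.shape[0] else
                   np.zeros(grid.n)),
            "ub": (state.u_b[0] if state.u_b.shape[0] else
                   np.zeros(grid.n)),
            "sigma": sigma, "p": p, "Is": Is, "If": If}
    return pd.DataFrame(cols)


def run_simulation(params, schedule: TreatmentSchedule | None, t_end: float,
                   state: State | None = None, grid: Grid | None = None,
                   dt: float = 5e-3, dr: float = 0.5,
                   output_every: float = 1.0,
                   snapshot_times: tuple = (),
                   progress: bool = False) -> Trajectory:
    """Run the model from ``state`` (or the standard initial condition) to t_end.

    Treatment events are snapped to the nearest time step.  Diagnostics
    are recorded every ``output_every`` hours (and at t_end); spatial
    snapshots are taken at the requested times.  Returns a
    :class:`Trajectory` whose ``final_state``/``final_grid`` attributes
    hold the end state for checkpointing or chained experiments.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if state is None or grid is None:
        state, grid = initialize(params, dr=dr)
    traj = Trajectory(species_radii=np.array(
        [sp.xi for sp in state.specs]) if state.specs else None)
    t0 = state.t
    traj.append(state.t, _diagnostics(state, grid, params))
    n_steps = int(round((t_end - t0) / dt))
    next_output = t0 + output_every
    snapshot_left = sorted(snapshot_times)
    injected = irradiated = False
    last_day = -1

    def fire_events():
        nonlocal injected, irradiated
        if schedule is None:
            return
        if (not injected and schedule.t_inj is not None
                and state.t >= schedule.t_inj - dt / 2):
            apply_injection(state, schedule)
            injected = True
        if (not irradiated and schedule.t_irr is not None
                and state.t >= schedule.t_irr - dt / 2):
            apply_irradiation(state, schedule, params)
            irradiated = True

    fire_events()
    for _ in range(n_steps):
        state, grid = advance(state, grid, params, dt)
        fire_events()
        if state.t >= next_output - dt / 2:
            traj.append(state.t, _diagnostics(state, grid, params))
            next_output += output_every
        while snapshot_left and state.t >= snapshot_left[0] - dt / 2:
            traj.snapshots[state.t] = _snapshot(state, grid, params)
            snapshot_left.pop(0)
        if progress:
            day = int(state.t // 24)
            if day > last_day:
                last_day = day
                log.info("day %d: R_tumor=%.2f, R_tissue=%.2f",
                         day, grid.R_tumor, grid.R_tissue)
    if traj.times[-1] < state.t:
        traj.append(state.t, _diagnostics(state, grid, params))
    traj.final_state = state
    traj.final_grid = grid
    return traj


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, state: State, grid: Grid) -> None:
    """Write the full state and grid to a single .npz file (format v1).

    Nanoparticle species are not stored: the sweep workflow checkpoints a
    particle-free grown tumor and re-attaches size-specific species on
    restore.
    """
    if state.specs:
        raise ValueError("checkpointing states with attached nanoparticle "
                         "species is not supported")
    arrays = {name: getattr(state, name) for name in State.TISSUE_FIELDS}
    np.savez(path, version=CHECKPOINT_VERSION, t=state.t,
             dr=grid.dr, n=grid.n, R_tumor=grid.R_tumor,
             R_tissue=grid.R_tissue,
             far_keys=np.array(list(state.far.keys())),
             far_vals=np.array(list(state.far.values())), **arrays)


def load_checkpoint(path, specs=()) -> tuple[State, Grid]:
    """Restore a checkpoint, optionally attaching nanoparticle species."""
    with np.load(path, allow_pickle=False) as data:
        if int(data["version"]) != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {data['version']}")
        n = int(data["n"])
        grid = Grid(dr=float(data["dr"]), n=n,
                    R_tumor=float(data["R_tumor"]),
                    R_tissue=float(data["R_tissue"]))
        state = State.zeros(n, n_species=len(specs))
        for name in State.TISSUE_FIELDS:
            getattr(state, name)[:] = data[name]
        state.t = float(data["t"])
        state.far = dict(zip(data["far_keys"].tolist(),
                             data["far_vals"].tolist()))
        state.specs = list(specs)
    return state, grid
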