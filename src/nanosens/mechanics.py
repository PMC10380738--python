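"""Poroelastic mechanics: solid stress, interstitial fluid pressure, velocities.

The tissue is a saturated biphasic medium: a porous solid phase of cells
(volume fraction ``s``) and interstitial fluid (``f = 1 - s``).  The solid
phase behaves as an elastic fluid with an isotropic stress ``sigma(s)``
that vanishes at the rest fraction ``s0``, is adhesive (negative) for
``ss < s < s0`` and repulsive above ``s0``.  Momentum balance of the slow
biphasic flow reduces to equal and opposite gradients of fluid pressure
and solid stress; fixing the integration constant by the far-field
equilibrium of normal tissue (where ``p + sigma = 0``) gives the pointwise
closure ``p = -sigma(s)``.

The solid velocity follows from summing all phase balances: net
transvascular fluid gain inside radius ``r`` must be exported by the
combined motion of solid and Darcy flow, which yields a cumulative shell
integral for ``Is`` with ``Is(0) = 0``; the fluid velocity then follows
from Darcy's law.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["solid_stress", "solid_stress_derivative", "fluid_pressure",
           "radial_gradient", "solve_velocities", "quasi_static_velocities",
           "face_velocities"]

_F_MIN = 1e-6  # fluid fraction below which the Darcy division is singular


def _stress_core(s, params):
    """sigma(s) without domain validation (hot path)."""
    return np.where(
        s > params.ss,
        params.k * (s - params.s0) * (s - params.ss) ** 2
        * np.power(np.maximum(1.0 - s, 0.0), 0.1),
        0.0,
    )


def solid_stress(s, params):
    """Isotropic solid stress sigma(s) = k (s-s0)(s-ss)^2 (1-s)^0.1 for s > ss.

    Zero below the contact fraction ``ss`` (cells too sparse to interact)
    and at full packing s = 1 by the (1-s)^0.1 factor.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("cell fraction must lie in [0, 1]")
    out = _stress_core(s, params)
    return out if out.ndim else float(out)


def solid_stress_derivative(s, params):
    """d sigma / d s, used by the steady-state linearization oracle."""
    s = np.asarray(s, dtype=float)
    k, s0, ss = params.k, params.s0, params.ss
    one_m = np.maximum(1.0 - s, 1e-300)
    core = ((s - ss) ** 2 + 2.0 * (s - s0) * (s - ss)) * one_m**0.1 \
        - 0.1 * (s - s0) * (s - ss) ** 2 * one_m**-0.9
    out = np.where(s > ss, k * core, 0.0)
    return out if out.ndim else float(out)


def fluid_pressure(s, params):
    """Interstitial fluid pressure, p = -sigma(s).

    The momentum balance only fixes grad p = -grad sigma; the constant is
    chosen so that p + sigma = 0 holds exactly in far-field normal tissue,
    which is the state imposed at the outer boundary for all time.
    """
    sigma = solid_stress(s, params)
    return -sigma


def radial_gradient(field: np.ndarray, dr: float) -> np.ndarray:
    """Second-order radial gradient: centered interior, one-sided ends."""
    return np.gradient(field, dr)


def solve_velocities(s, h, cn, ca, p, r, params):
    """Solid and fluid advective velocity fields on the radial grid.

    The transvascular source density is
    ``S = [Ln cn + La ca](pc - p) - Ll h (p - pl)``; integrating the
    combined-phase volume balance from the center outwards gives

        Is(r) = K dp/dr + (1/r^2) * int_0^r S z^2 dz,

    with ``Is(0) = 0`` by spherical symmetry, and
    ``If = Is - (K/f) dp/dr`` from Darcy's law.  The outer boundary is
    free (no constraint is imposed there).

    Returns ``(Is, If, S)``; the source density is returned for
    conservation diagnostics.
    """
    s = np.asarray(s, dtype=float)
    f = 1.0 - s
    if np.any(f < _F_MIN):
        i = int(np.argmin(f))
        raise FloatingPointError(
            f"fluid fraction {f[i]:.3e} at node {i} (r={r[i]:.2f}) makes the "
            "Darcy division singular")
    dr = r[1] - r[0]
    dpdr = radial_gradient(p, dr)
    source = (params.Ln * cn + params.La * ca) * (params.pc - p) \
        - params.Ll * h * (p - params.pl)
    shell = cumulative_trapezoid(source * r * r, r, initial=0.0)
    Is = params.K * dpdr
    Is[1:] += shell[1:] / (r[1:] * r[1:])
    Is[0] = 0.0
    If = Is - (params.K / f) * dpdr
    If[0] = 0.0
    return Is, If, source


def _relax_cell_fraction(s, Lc, Lh, params, dt):
    """Backward-Euler relaxation of the local fluid-exchange mode.

    The pointwise feedback loop s -> sigma -> p -> transvascular source ->
    volume change is extremely fast wherever lymphatics are present
    (relaxation rate ~ Ll * h * sigma'(s0) ~ 1e5 per hour for the default
    parameters): physically, excess fluid escapes into the lymphatic
    system almost instantly and normal tissue sits in quasi-static
    equilibrium.  Advancing that mode explicitly would require absurdly
    small steps, so the velocity source is evaluated at the implicitly
    relaxed fraction ``s*`` solving

        s* = s * exp(-dt * S(s*)),
        S(x) = Lc (pc - p(x)) - Lh (p(x) - pl),  p(x) = -sigma(x),

    which is the backward-Euler step of the local volume balance
    ds/dt = -s S(s).  In slowly exchanging regions (the tumor interior)
    s* differs from s by O(dt) and the scheme reduces to the explicit one;
    in stiff regions it lands on the equilibrium.  Solved by safeguarded
    Newton iteration per node (the residual is strictly increasing in x).
    """
    s = np.asarray(s, dtype=float)
    x = np.minimum(np.maximum(s, 0.0), 0.999)
    idx = None          # after the first sweep, iterate unconverged nodes only
    xs, ss_, Lcs, Lhs = x, s, Lc, Lh
    for _ in range(60):
        p = -_stress_core(xs, params)
        S = Lcs * (params.pc - p) - Lhs * (p - params.pl)
        expf = np.exp(np.minimum(np.maximum(-dt * S, -60.0), 60.0))
        f_res = xs - ss_ * expf
        dS = (Lcs + Lhs) * solid_stress_derivative(xs, params)
        f_prime = 1.0 + ss_ * expf * dt * dS
        step = f_res / np.maximum(f_prime, 1e-12)
        xs = np.minimum(np.maximum(xs - step, 0.0), 0.999)
        live = np.abs(step) > 1e-14
        if idx is None:
            x = xs
            if not live.any():
                return x
            idx = np.nonzero(live)[0]
            xs, ss_, Lcs, Lhs = x[idx], s[idx], Lc[idx], Lh[idx]
        else:
            x[idx] = xs
            if not live.any():
                return x
            keep = np.nonzero(live)[0]
            idx = idx[keep]
            xs, ss_, Lcs, Lhs = xs[keep], ss_[keep], Lcs[keep], Lhs[keep]
    return x


def face_velocities(s_star, h, cn, ca, grid, params, source_weight=None):
    """Staggered (cell-face) velocity fields for the transport stage.

    The Darcy flux is evaluated from adjacent-node pressure differences
    and the transvascular source is accumulated cell by cell, so the
    discrete volume balance ``(A_out Is_out - A_in Is_in)/V = S`` holds
    exactly per cell and grid-scale pressure oscillations are properly
    damped instead of slipping through a centered gradient.

    ``source_weight`` (per cell, default 1) scales each cell's source
    contribution; the solver uses it to weight the partially filled
    tissue-edge cell by its material fill fraction and to exclude the
    cell-free region beyond the tissue boundary.

    Returns ``(Is_face, If_face, sigma, p)`` with the face arrays of
    length n+1; the innermost face (zero area, at the origin) carries zero
    velocity and the outermost face extrapolates freely.
    """
    s_star = np.asarray(s_star, dtype=float)
    f = 1.0 - s_star
    if np.any(f < _F_MIN):
        i = int(np.argmin(f))
        raise FloatingPointError(
            f"fluid fraction {f[i]:.3e} at node {i} makes the Darcy "
            "division singular")
    sigma = solid_stress(s_star, params)
    p = -sigma
    n, dr = grid.n, grid.dr
    source = (params.Ln * cn + params.La * ca) * (params.pc - p) \
        - params.Ll * h * (p - params.pl)
    weight = grid.volume if source_weight is None \
        else grid.volume * source_weight
    shell_face = np.concatenate(([0.0], np.cumsum(source * weight)))

    dpdr_face = np.zeros(n + 1)
    dpdr_face[1:n] = np.diff(p) / dr

    Is_face = params.K * dpdr_face
    Is_face[1:] += shell_face[1:] / grid.face_area[1:]
    Is_face[0] = 0.0

    f_face = np.empty(n + 1)
    f_face[1:n] = 0.5 * (f[:-1] + f[1:])
    f_face[0] = f[0]
    f_face[n] = f[-1]
    If_face = Is_face - (params.K / f_face) * dpdr_face
    If_face[0] = 0.0
    return Is_face, If_face, sigma, p


def quasi_static_velocities(s, h, cn, ca, r, params, dt):
    """Velocity fields with the stiff fluid-exchange mode treated implicitly.

    Returns ``(sigma, p, Is, If, s_star)`` where sigma and p are evaluated
    at the relaxed cell fraction ``s*`` (see :func:`_relax_cell_fraction`);
    the subsequent advection step, whose velocity divergence equals the
    relaxed source, then moves ``s`` onto ``s*``.  With dt = 0 this is
    exactly :func:`solve_velocities`.
    """
    s = np.asarray(s, dtype=float)
    Lc = params.Ln * cn + params.La * ca
    Lh = params.Ll * h
    if dt > 0.0:
        s_star = _relax_cell_fraction(s, Lc, Lh, params, dt)
    else:
        s_star = s
    sigma = solid_stress(s_star, params)
    p = -sigma
    Is, If, _ = solve_velocities(s_star, h, cn, ca, p, r, params)
    return sigma, p, Is, If, s_star
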