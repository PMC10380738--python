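"""Local (non-transport) kinetics of the eleven tissue fields and the blood pool.

Every term here is a pointwise reaction rate; diffusion and advection are
handled by the solver's transport stages.  Normal cells ``h`` have no
kinetics at all (they only ride the solid flow), and the fluid fraction is
never integrated directly: saturation ``s + f = 1`` makes its equation
redundant, so the net fluid balance only enters through the velocity
field of the mechanics module.
"""

from __future__ import annotations

import numpy as np

__all__ = ["smooth_step_prolif", "smooth_step_transition", "kinetic_rhs",
           "blood_concentration", "binding_halftime_check"]


def smooth_step_prolif(sigma, params):
    """Proliferation gate Theta_p = (1 + tanh(eps (sigma_p - sigma)))/2.

    Near 1 well below the critical stress, near 0 well above it; the
    smoothing parameter ``eps`` = 500 makes the transition effectively a
    step while keeping the right-hand side differentiable.
    """
    return 0.5 * (1.0 + np.tanh(params.eps * (params.sigma_p - sigma)))


def smooth_step_transition(g, params):
    """Quiescence gate Theta_tr = (1 + tanh(eps (g - g*)))/2 (1 when glucose is ample)."""
    return 0.5 * (1.0 + np.tanh(params.eps * (g - params.g_star)))


def kinetic_rhs(state, params, p, sigma):
    """Pointwise time derivatives of all kinetically active fields.

    Parameters
    ----------
    state : State
        Current fields (tissue arrays plus per-species nanoparticle arrays).
    p, sigma : ndarray
        Interstitial fluid pressure and solid stress, precomputed by the
        mechanics stage.

    Returns
    -------
    dict
        Arrays keyed by field name.  ``"f"`` is the fluid balance implied
        by saturation (reported for diagnostics, never integrated).  The
        keys ``"g_inflow"`` and ``"g_decay"`` expose the glucose balance
        split into its source coefficient and its linear-in-g sink rate,
        which the solver uses for a positivity-robust update; ``"g"`` is
        their combination.
    """
    pr = params
    n_p, n_q, h, m = state.n_p, state.n_q, state.h, state.m
    v, c_n, c_a, g = state.v, state.c_n, state.c_a, state.g

    theta_p = smooth_step_prolif(sigma, pr)
    theta_tr = smooth_step_transition(g, pr)
    michaelis_g = g / (g + pr.g_star)

    prolif = pr.B * n_p * theta_p * michaelis_g
    to_quiescent = pr.B * (1.0 - theta_tr) * n_p
    to_prolif = pr.B * theta_tr * n_q

    c_tot = c_n + c_a
    vegf_on = v / (v + pr.v_star)
    vegf_off = pr.v_star / (v + pr.v_star)

    rates = {
        "n_p": prolif - to_quiescent + to_prolif,
        "n_q": to_quiescent - to_prolif,
        "h": np.zeros_like(h),
        "m": -pr.M * m,
        "v": pr.Sv * n_q - pr.omega * c_tot * v - pr.Mv * v,
        "c_n": -pr.Mc * (n_q + m) * c_n + pr.Vn * vegf_off * c_a
               - pr.Vd * vegf_on * c_n,
        "c_a": -pr.Mc * (n_p + pr.kM * (n_q + m)) * c_a
               + pr.R_ang * vegf_on * c_tot * (1.0 - c_tot / pr.cmax)
               - pr.Vn * vegf_off * c_a + pr.Vd * vegf_on * c_n,
    }

    g_inflow = pr.Png * c_n + pr.Pag * c_a
    g_decay = (pr.nu_g * pr.B * n_p * theta_p
               + pr.Qhg * (n_q + h + n_p * (1.0 - theta_p))) / (g + pr.g_star)
    rates["g_inflow"] = g_inflow
    rates["g_decay"] = g_decay
    rates["g"] = g_inflow * (1.0 - g) - g_decay * g

    # implied fluid balance (saturation closure, diagnostics only)
    inflow = (pr.Ln * c_n + pr.La * c_a) * (pr.pc - p)
    outflow = pr.Ll * h * (p - pr.pl)
    rates["f"] = inflow - outflow + pr.M * m - prolif

    if len(state.specs) > 0:
        sp = state.spec_arrays()
        col = lambda a: a[:, None]
        u_f, u_b, u_bl = state.u_f, state.u_b, state.u_bl
        # direction switch: hydrostatic inflow carries the blood
        # concentration, outflow (p > pc) carries the tissue concentration
        carried = col(u_bl) * np.heaviside(pr.pc - p, 0.5) \
            + u_f * np.heaviside(p - pr.pc, 0.5)
        advective = (pr.Ln * col(sp["gamma_nu"]) * c_n
                     + pr.La * col(sp["gamma_au"]) * c_a) \
            * (pr.pc - p) * carried
        diffusive = (col(sp["Pnu"]) * c_n + col(sp["Pau"]) * c_a) \
            * (col(u_bl) - u_f)
        binding = col(sp["kappa"]) * (n_p + n_q) * u_f
        lymphatic = pr.Ll * h * (p - pr.pl) * u_f
        rates["u_f"] = advective + diffusive - binding - lymphatic
        rates["u_b"] = binding
    else:
        rates["u_f"] = np.zeros_like(state.u_f)
        rates["u_b"] = np.zeros_like(state.u_b)
    return rates


def blood_concentration(t, t_inj, U0, Cu):
    """Blood concentration after a bolus at ``t_inj``: U0 exp(-Cu (t - t_inj)).

    Zero before the injection; the delta-function injection and first-order
    clearance admit this closed form, which the solver also uses stepwise
    (exact exponential decay between events).
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= t_inj, U0 * np.exp(-Cu * np.maximum(t - t_inj, 0.0)), 0.0)
    return out if out.ndim else float(out)


def binding_halftime_check(params, cell_fraction: float = 0.8) -> float:
    """Half-time (h) for free particles to bind at the given tumor cell density.

    Documentation-level sanity check on the binding coefficient: with the
    default kappa = 0.5 and cells at their rest fraction the half-time is
    ln 2 / (0.5 * 0.8) ~ 1.7 h, i.e. roughly half of the particles bind
    within the first couple of hours.
    """
    rate = params.kappa * cell_fraction
    return float(np.log(2.0) / rate) if rate > 0 else float("inf")
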