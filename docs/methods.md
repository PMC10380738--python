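# Methods

This note documents the model equations as implemented, the numerical
scheme, the deliberate design choices made where the design was open, and
the limitations a user should know before trusting a number.

## Units and normalization

Time is measured in hours, length in units of r̂ = 10⁻² cm (so the grid
spacing Δr = 0.5 corresponds to 50 µm), dose in Gy. Nanoparticle and
capillary-pore radii are in nanometres throughout the pore-transport
module; the particle diffusion parameter `Du0` already folds the unit
conversion, so `Du = Du0/ξ` is in model units. Cell, fluid, glucose,
VEGF and capillary variables are dimensionless after normalization; the
nanoparticle concentration scale is absorbed into the dose-enhancement
factor `Ku`, which is why the injected blood concentration is fixed at
`U0 = 1` for every particle size (equal injected total particle volume).

## Model structure

### Tissue phases and mechanics

The tissue is saturated and incompressible: cells (`s = n_p + n_q + h + m`)
plus interstitial fluid (`f`) fill space, `s + f = 1`. The implementation
never integrates `f`; it is defined as `1 − s`, which makes the
saturation identity exact by construction (the fluid equation is the
redundant sum of the others).

The solid stress law

    σ(s) = k (s − s0)(s − ss)² (1 − s)^0.1,   s > ss   (else 0)

is zero at the contact fraction `ss = 0.3`, adhesive between `ss` and the
rest fraction `s0 = 0.8`, repulsive above, and zero again at full
packing. Momentum balance of the slow flow gives ∇p = −∇σ; the
integration constant is fixed so that `p + σ = 0` holds exactly in
far-field normal tissue, i.e. `p = −σ(s)` pointwise. The maximum
attainable interstitial fluid pressure is therefore −min σ ≈ 8.4, reached
when fluid accumulation pulls the cell network to s ≈ 0.63; the simulated
day-51 tumor core sits at p ≈ 3.7 with capillary pressure `pc = 4`.

Summing all phase balances eliminates the kinetic terms and yields the
solid velocity as a boundary integral,

    Is(r) = K ∂p/∂r + (1/r²) ∫₀ʳ S(z) z² dz,
    S = [Ln c_n + La c_a](pc − p) − Ll h (p − pl),

with Is(0) = 0 by symmetry, and Darcy's law gives the fluid velocity
If = Is − (K/f) ∂p/∂r. A free (no-constraint) condition applies at the
outer boundary.

### Kinetics

Proliferating cells divide at rate B, gated by a smooth step in stress
(Θp, half-height at σp = 15) and a Michaelis factor g/(g + g*); glucose
shortage drives the reversible proliferating↔quiescent transition (Θtr,
half-height at g* = 0.01). Quiescent cells secrete VEGF; VEGF converts
normal capillaries to abnormal ones (denormalization) and drives logistic
angiogenesis; capillaries degrade in contact with quiescent/damaged cells
(and abnormal ones additionally with proliferating cells). Glucose enters
through both capillary types in proportion to (1 − g) and is consumed
fastest by proliferating cells. Normal cells `h` have no kinetics at all:
they only ride the solid flow.

Free nanoparticles enter advectively — coefficient
[Ln γ_n(ξ) c_n + La γ_a(ξ) c_a](pc − p), carrying the blood concentration
when p < pc and the tissue concentration when p > pc — and diffusively,
coefficient [P_n(ξ) c_n + P_a(ξ) c_a](u_bl − u_f). They bind irreversibly
to live tumor cells at rate κ(n_p + n_q) and are lost to the lymphatics
with the drained fluid. Bound particles move only with the cells. The
blood concentration decays as exp(−Cu t) after the bolus.

### Pore-limited transvascular transport

Each capillary type carries a pore-radius spectrum on [0, X = 100] nm:

    PSn(x) = x^3.7 exp(−x^0.9)      (normal)
    PSa(x) = x^11  exp(−x^0.85)     (abnormal, reference)
    PSb(x) = x^13  exp(−x^0.8)      (abnormal, more permeable)
    PSc(x) = 1                      (abnormal, uniform extreme)

A particle of radius ξ in a pore of radius x is subject to steric
exclusion A = (x−ξ)²/x² (zero for x ≤ ξ) and the Renkin hindrance
R(λ) = 1 − 2.1λ + 2.09λ³ − 0.95λ⁵, λ = ξ/x, which decreases from 1 to
0.04 on [0, 1]. The per-pore permeability is P = A · (Du0/ξ) · R. The
absolute pore count N_y of each spectrum is anchored so that the
convolved permeability at the glucose hydrodynamic radius (0.36 nm)
reproduces the measured glucose permeability (4 for normal, 10 for
abnormal capillaries); every abnormal spectrum shape is anchored to the
same target, so swapping the shape changes only the nanoparticle
coefficients, never the tissue dynamics. The hydraulic conductivity of
abnormal capillaries is derived by scaling the normal value by the ratio
of pore-occupied surface-area fractions, giving La = 0.219 ≈ 0.22.
Integrals use adaptive quadrature on [ξ, X] (the integrand vanishes
identically below ξ) with absolute tolerance 10⁻⁹; a 10⁵-point trapezoid
brute force serves as the oracle in the tests.

### Treatment

Irradiation is an instantaneous event: per node, the linear-quadratic
damaged fractions Γx = 1 − exp(−k_x(α D_eff + β D_eff²)), x ∈ {p, q},
move cells into the damaged pool, which subsequently dies at rate M
(turning into fluid, which the elevated tumor pressure expels — hence the
transient shrinkage after irradiation). The effective dose is

    D_eff = D (1 + Ku · u_b · ((ξ − ψ)/ξ)³).

The additive baseline term is a deliberate reading: radiation without
particles must still damage cells (a plain irradiation experiment kills
about half of proliferating cells at 2 Gy), and the enhancement is
described as a linear *increase* of the dose. This is the single most
consequential interpretive choice in the treatment module.

Two diagnostics summarize radiosensitization without changing the state:
the volume-weighted potential damaged fraction
∫(Γp n_p + Γq n_q) r² dr / ∫(n_p + n_q) r² dr at the scheduled dose, and
the total bound active substance ∫ u_b ((ξ−ψ)/ξ)³ 4πr² dr.

## Numerical scheme

Operator splitting per step of Δt = 5·10⁻³ h (default): mechanics →
kinetics → diffusion → advection → floating-front update, with a
NaN/negativity scan after the step.

**Mechanics.** Velocities live on cell faces: the Darcy flux uses
adjacent-node pressure differences and the source integral is accumulated
cell by cell, making the discrete balance div([Is − K∇p] r²) = S r² exact
per finite volume and suppressing grid-scale pressure checkerboards that
node-centered gradients cannot see.

The pointwise feedback s → σ → p → S is extremely stiff wherever
lymphatics are present: its rate is about Ll·h·σ′(s0) ≈ 9·10⁴ h⁻¹ at the
defaults, the physical statement being that normal tissue drains excess
fluid essentially instantly and always sits in quasi-static equilibrium.
The velocity source is therefore evaluated at the backward-Euler-relaxed
cell fraction s* solving s* = s·exp(−Δt·S(s*)) per node (safeguarded
Newton; the residual is strictly monotone). Where exchange is slow — the
avascular tumor interior — s* differs from s by O(Δt) and the scheme is
effectively explicit; where it is stiff, the source lands on the
equilibrium. The remaining explicit coupling (the Darcy/stress diffusion
K·s·σ′ ≲ 16 in model units) bounds the stable step at roughly
Δt < Δr²/(2·K·s·σ′) ≈ 8·10⁻³ h at Δr = 0.5, which motivates the default.

**Kinetics.** Explicit Euler, with two exceptions that reduce to Euler as
Δt → 0: the glucose balance is advanced by its exact
exponential-relaxation step for frozen coefficients (its sink rate
constant grows like ν_g·B·n_p/g* ≈ 10³ h⁻¹ as glucose depletes, which
plain Euler cannot take at a usable Δt), and the blood clearance ODE uses
its closed form. Fields are clipped at tiny negative undershoots; an
undershoot beyond 10⁻⁶ aborts the run with the node index.

**Diffusion.** Crank–Nicolson for VEGF, glucose, abnormal capillaries
(their active motion is modeled as diffusion with coefficient Dc — the
printed transport term is diffusion-shaped, although sprouting up the
VEGF gradient would suggest chemotactic drift; flagged as a sensitivity
topic) and free nanoparticles (per-species Du). Conservative spherical
finite-volume Laplacian, zero flux at the origin, Dirichlet at the outer
boundary at the initial far-field values (glucose 1, others 0).

**Advection.** Conservative flux-corrected transport: donor-cell upwind
low-order fluxes plus Zalesak-limited antidiffusive corrections toward
the Lax–Wendroff flux. Solid-velocity fields (cells, capillaries, bound
particles) and fluid-velocity fields (free particles) are advected as
batches sharing one velocity. Total content is conserved to near machine
precision with zero boundary flux, no new extrema are created beyond
geometric dilution, and fronts stay markedly sharper than plain upwind.
If the face Courant number exceeds 0.9, the advection stage substeps.

**Floating fronts.** Two continuous radii mark the tumor/normal interface
and the outer tissue edge. Each front's interface cell is interpreted as
partially filled at the dense-material density of its inner neighbor;
content the advection smeared beyond it is clipped back conservatively
(bound nanoparticles ride along at the tumor front), the front advances
or retreats when the interface cell fills or empties, and the front
radius is recomputed from the conserved material volume. Without this,
two failure modes appear within simulated days: the tumor slowly
"invades" the normal tissue numerically, and the tissue edge shreds into
a dilute haze whose cell fraction falls below the contact fraction ss —
a regime where σ = 0 makes capillary inflow unopposed and the domain
inflates without bound. For the same reason the partially filled edge
cell enters the constitutive law at its dense value and the cell-free
region beyond the edge carries no transvascular sources. Capillaries are
confined to the tissue by the same clipping.

The domain (default 8 mm, 161 nodes) auto-extends when the tissue edge
approaches its end.

## Initial and boundary conditions

A tumor colony of radius 0.2 mm (proliferating cells at the normal-tissue
steady fraction sst) sits at the center of 4 mm of normal tissue
(h = sst, c_n = 1); glucose is 1 everywhere; everything else starts at
zero; beyond the tissue is cell-free fluid. sst solves the coupled fixed
point {p = Ln·pc/(Ln + Ll·s), σ(s) = −p} and differs from s0 by
−3.6·10⁻⁶ (the linearized estimate −p/σ′(s0) with σ′(s0) ≈ 106.4 agrees
to three digits). `initialize(steady_glucose=True)` instead starts
glucose at its normal-tissue steady level ≈ 0.901, making a tumor-free
configuration an exact fixed point of the discrete scheme — used to
verify that nothing drifts over ten simulated days.

## Experiments and problem sizes

The standard pipeline grows the tumor for 51 days (Δr = 0.5, Δt = 5·10⁻³;
about 3 minutes on one core), then attaches one nanoparticle species per
candidate radius to the day-51 state, injects unit blood concentration,
and follows 8 post-injection days, recording each species' potential
damaged fraction and bound active substance hourly. Free and bound
particles feed back on nothing before irradiation is actually delivered,
so co-evolving all radii through one shared tissue run is exactly
equivalent to restarting a checkpoint once per radius, at a fraction of
the cost (a 43-radius sweep takes ~90 s). The optimum is the argmax of
the peak potential damaged fraction, ties broken toward the smaller
radius. "No angiogenesis" sets the angiogenesis and denormalization rates
to zero (normalization left at its default, so any abnormal capillaries
would decay) and regrows the tumor under those conditions.

## Known limitations

- The vertical scale of the nanoparticle curves is in arbitrary units
  (the concentration normalization is folded into Ku), so only shapes,
  ratios and argmax locations are meaningful. The damage response
  saturates at the vascularized rim near the optimum under the default
  injected amount, and since the peak-vs-radius curves are flat to within
  a fraction of a percent over ±1–2 nm, the damage-based argmax sits 1–2
  nm below the delivery-based one under the more permeable spectra and is
  sensitive to the (arbitrary) delivery scale. It is, however, stable
  under halving of both the grid spacing and the time step.
- Spherical symmetry, noninvasive growth, a single nutrient, no cell
  death from nutrient deprivation, no binding-site saturation, no
  electrostatic pore interactions.
- The quasi-static drainage relaxation replaces sub-grid screening-layer
  dynamics (screening length ~1 µm at the defaults) with instantaneous
  local equilibrium; transients faster than the time step in normal
  tissue are not resolved, by design.
- Explicit kinetics bound the usable time step; the defaults were chosen
  from the stability analysis above, not from convergence studies at
  every parameter combination.
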