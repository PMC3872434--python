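# Methods

`hemolab` studies how respiration changes the hemodynamics of a total
cavopulmonary connection (TCPC, the Fontan-type junction that routes both
venae cavae directly into the pulmonary arteries).  The experiment compares
two boundary-condition regimes on the same junction: **Condition I**
(cardiac pulsatility only, zero-pressure outlets) and **Condition II**
(cardiac *and* respiratory pulsatility at the inlets, measured-style
pressure traces at the outlets), and evaluates control-volume energy loss
(EL), the LPA/RPA flow-distribution ratio (FR), wall shear stress (WSS)
and Reynolds/Courant diagnostics.

## Synthetic boundary waveforms

Clinical velocity and pressure traces are emulated by a parametric
generator.  A trace is a beat-periodic cardiac Fourier series riding on a
respiratory envelope,

    v(t) = [m0 + Σ_k a_k sin(2π k t / T_h + φ_k)] · [1 + m sin(2π t / T_b + ψ)],

with heart period `T_h = 0.6 s` and breath period `T_b = 4 T_h = 2.4 s` by
default: one breath spans exactly four heart beats, the structural
assumption the whole decomposition relies on.  (The 0.6 s beat is a
package default consistent with a six-cycle run of 36,000 steps at
Δt = 10⁻⁴ s; clinical heart and breath rates vary and are configurable.)
The multiplicative envelope reproduces the beat-to-beat amplitude
variation across a breath seen in venous ultrasound; an additive mode is
available.  Modulation depth `m < 1` keeps the envelope positive, and a
validator rejects venous specs whose cardiac amplitudes could reverse the
flow unless reversal is explicitly allowed.  Gaussian measurement noise is
seeded and off by default.

Default levels (SI units) are anchored to the laminar operating regime of
a small Fontan patient in a ~9 mm junction: peak port Reynolds number
near 800 under cardiac pulsatility alone and below 1000 once respiration
is included, i.e. peak inlet speeds of roughly 0.34 and 0.40 m/s.  That
fixes the scale: IVC mean 0.24 m/s with three cardiac harmonics and a
20% respiratory modulation, innominate veins 0.12 m/s each (their
flux-weighted merger feeds the SVC inlet at 0.24 m/s), outlet pressures
1.6 kPa (≈ 12 mmHg) with a 40 Pa cardiac ripple and a gentle, slightly
phase-asymmetric respiratory swing (m = 0.04).  Measured port Reynolds
numbers in the desk run are ≈ 740 (cardiac only) and ≈ 840 (with
respiration) — the laminar regime the model assumes.

What the generator does *not* emulate: measured-trace irregularities
(variable beat length, ectopy), ultrasound/catheter transfer functions,
and intrathoracic-pressure coupling to the venous return.  Tests passing
on these synthetic traces therefore validate the machinery (separation,
solver, metrics), not the clinical values themselves.

## Spectral separation

Because the record always covers whole breaths, every generated tone sits
exactly on a DFT bin.  Separation is plain bin bookkeeping: the DC bin is
the mean; bins at multiples of the heart fundamental are cardiac; the
remaining multiples of the breath fundamental are respiratory; everything
else is residual.  Components are returned by inverse transform of
disjoint, exhaustive bin sets, so reconstruction and Parseval bookkeeping
hold to round-off.  No window function is applied; records are truncated
to whole breaths instead, which avoids leakage by construction.

Two genuinely open choices are exposed as options rather than guessed:

* **Sidebands** `k f_heart ± j f_breath` (products of multiplicative
  modulation) default to the *respiratory* component because they vanish
  when respiration is absent; `sidebands="cardiac"` reassigns those closer
  to a cardiac harmonic than to the midpoint of the spacing.
* **The Condition I beat** defaults to *folding* (averaging the four beats
  of mean + cardiac + residual), which also averages residual noise down;
  pure harmonic resynthesis is available and identical on clean signals.
  For on-bin tones the four evenly spaced beats sample the respiratory
  envelope at zero mean, so folding removes respiration exactly.

Frequency estimation takes the dominant non-DC peak as the cardiac
candidate and the largest peak strictly below it as the respiratory
fundamental, then enforces the 4:1 ratio exactly; a flat spectrum raises
an error, and a record must span at least two breaths.

## Idealized junction geometry

The patient-specific 3-D vessel is not available; the central fidelity
reduction of this package is a **2-D planar surrogate**: a parameterized
cross with the IVC entering from below, the SVC from above (laterally
offset by one diameter by default), and the LPA/RPA arms leaving left and
right.  All channel widths default to 9 mm — the order of the diameter
implied by a Reynolds number of ~800 at ~0.34 m/s for blood — and a
nominal out-of-plane depth (9 mm) converts planar face fluxes to
volumetric flow.  Every metric (EL, FR, WSS, Re, Cr) is well defined in
2-D; absolute wattages are *not* comparable to 3-D patient values, but the
Condition I/II contrast, conservation properties and convergence behaviour
are.

Arms must be at least three widths long so port flows are fully developed.
The mask is rasterized on a uniform marker-and-cell (MAC) grid
(cell-centered pressure, face-normal velocities) with at least 10 cells
across every channel; rectangle edges snap to grid lines, so grid-aligned
dimensions rasterize exactly and refinement by an integer factor conserves
the fluid area exactly.  Near-wall WSS resolution comes from this
cells-across floor plus refinement studies rather than body-fitted prism
layers.  The characteristic length for Reynolds numbers is the hydraulic
diameter `2 w d / (w + d)` of the rectangular port section.

## Flow solver

Incompressible Navier–Stokes with constant density 1060 kg/m³ and
viscosity 4.0 mPa·s (Newtonian blood, body forces omitted), rigid no-slip
walls.  The discretization is a fractional-step projection method:

* **Advection** — flux form, second-order upwind-biased face
  reconstruction (1.5 u_C − 0.5 u_UU) with a first-order fallback adjacent
  to boundaries.
* **Diffusion** — standard 5-point Laplacian; no-slip enters tangential
  stencils through reflected ghosts (−u), zero-gradient ghosts (+u) across
  outlet spans.
* **Time advance** — explicit variable-step Adams–Bashforth 2 (Euler on
  the first step).
* **Projection** — a pressure Poisson equation with Neumann walls/inlets
  and face-Dirichlet outlet pressure, assembled once per grid and solved
  by a sparse direct factorization every step, making each velocity field
  discretely divergence-free to round-off (~10⁻¹¹ 1/s in practice,
  far below the 10⁻⁵ residual criterion carried by the configuration).

Inlet profiles are parabolic by default (normalized so the *discrete* mean
equals the waveform value exactly, making port influx exact); a flat
profile is available — the profile choice has minor effect on downstream
distribution.  Outlets extrapolate the predictor velocity at zero normal
gradient and receive the prescribed pressure through the Poisson problem;
equal pressure traces at both outlets act as a pure gauge, a property used
by the regime-equivalence test.

**Time step.**  The advective Courant bound `Cr = u Δt / h` and the
explicit-diffusion bound `Δt ≤ h²ρ/(4μ)` both apply.  Empirically the
junction flow is stable for observed Cr up to ≈ 0.29 and unstable by 0.37
(the outlet region goes first), so the default ceiling is `cr_max = 0.3`
applied to a conservative speed estimate (3× the peak inlet speed, since
merging streams and parabolic profiles accelerate the interior), and a
runtime guard halves Δt whenever the observed Cr exceeds `1.2 cr_max`.
Δt is snapped to divide the cycle period so kept windows align with cycle
boundaries.  `select_timestep` also exposes the literal mean-speed Courant
inversion for diagnostics.

Runs integrate a configured number of cycles and discard warm-up cycles
from all metrics (defaults: 3 heart cycles with 1 discarded for Condition
I, 2 breaths with 1 discarded for Condition II).  Cycle-to-cycle
periodicity of the port fluxes is reported in the diagnostics; the
impulsive start decays with a time constant of roughly one second at the
default scale, so single-cycle warm-ups retain a small transient — the
desk-scale defaults trade this against runtime, and the convergence log
makes the residual drift visible.

## Metrics

Port fluxes integrate face-normal velocities over tagged boundary faces
(through-flow positive); port pressure is the area mean extrapolated to
the face plane from the two interior cells (second order).

* **FR** = Q_LPA / Q_inlet × 100%, the share of total venous return sent
  to the left lung.  FR_LPA + FR_RPA = 100 exactly whenever mass balances,
  which the projection guarantees.
* **EL(t)** = Σ_in (P + ½ρ⟨U²⟩)Q − Σ_out (P + ½ρ⟨U²⟩)Q.  The kinetic term
  uses the area-averaged *squared* speed; the alternative (squared
  area-averaged speed) is computed as a diagnostic and the time-averaged
  gap reported.  The unsteady velocity-potential term of the classical
  control-volume expression is ill-defined for viscous rotational flow (no
  global potential exists); the default omits it, and an optional port
  inertance approximation ρ L d⟨U⟩/dt Q (L = arm length) is provided.
  Instantaneous, cumulative (J) and time-averaged (W) forms are reported.
  EL is gauge invariant under uniform pressure shifts, which is what makes
  the "minimum diastolic pressure at the LPA = 0" normalization harmless;
  `normalize_pressure` implements that shift and the property is tested.
* **WSS** = μ ∂u_t/∂n at every solid-adjacent face, one-sided second-order
  difference from the tangential velocities at h/2 and 3h/2 off the wall
  (exact for a linear profile; ~3% low bias on a parabolic profile at 20
  cells across, shrinking under refinement).  WSS is reported as
  instantaneous signed fields at selected instants, not time-averaged —
  averaging a sign-alternating stress destroys its meaning.
* **Re** = ρUD/μ per port with D the hydraulic diameter; a laminar check
  flags instants above a threshold (default 1000) without switching
  models.

## The two-regime comparison

Condition I's inlet boundary conditions are *derived from* Condition II's
traces by spectral separation and beat folding — the two regimes are
internally consistent by construction, and the pipeline test asserts the
round-trip identity exactly.  The comparison report selects four instants
from the normalized inlet waveforms within one kept breath — IVC
peak/bottom crossed with innominate peak/bottom — and tabulates
instantaneous EL, FR and peak WSS at each, plus time-averaged EL and FR,
the EL ratio in both directions, and the signed and absolute FR
difference.

## Verification and problem sizes

* **Plane Poiseuille** (9 mm channel, 0.1 m/s, 20 cells across):
  centerline velocity, pressure gradient, WSS and EL = ΔP·Q against the
  closed forms; errors ~0.5%, 0.8%, 2.7% and 0.9% respectively.
* **Oscillatory channel** at Womersley number α = 0.4 (2 mm channel):
  the profile stays within ~1.2% L2 of the instantaneous parabola,
  confirming the unsteady path in the quasi-steady limit.
* **Grid convergence of EL** on the steady junction uses 14, 20 and 28
  cells across.  A coarser 10-cell level is still outside the asymptotic
  range (its increment does not yet shrink); from 14 cells on the
  successive changes decrease monotonically (2.6% → 1.4%, and 1.2% on a
  further 40-cell level) as the junction-corner stress singularities are
  resolved.
* **Desk-scale comparison**: 9 mm junction at h = 0.45 mm (20 cells
  across, ≈ 5600 fluid cells), Condition I three beats (two kept),
  Condition II two breaths (one kept).  This completes in a few minutes
  on one CPU; the sizes were chosen so the full suite stays interactive
  while every channel still carries ≥ 20 cells.

## Known limitations

* 2-D planar surrogate: absolute EL/WSS magnitudes are not patient values;
  only relative regime contrasts and verified invariants transfer.
* Rigid walls; no fluid–structure interaction, no vessel compliance, and
  no lumped-parameter (Windkessel) outlet coupling — outlet pressure is
  prescribed directly.  Without downstream lung resistance the
  *instantaneous* LPA/RPA split swings considerably more over a beat than
  in vivo; time-averaged FR is the robust quantity.
* Laminar Newtonian rheology; no transition modelling even if a flagged
  instant exceeds the Reynolds threshold.
* Explicit time stepping limits the affordable Reynolds/resolution range;
  the junction-corner singularities slow EL convergence to roughly first
  order in h.
* Single-breath periodicity is assumed exact (fixed 4:1 beat:breath
  ratio); variable heart rate breaks the bin structure and is out of
  scope.
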