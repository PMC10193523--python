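# Methods

This note documents the models, numerical choices and limitations behind
`cmumd`: a self-contained toy molecular-dynamics engine whose purpose is to
implement, exercise and validate constant chemical potential molecular
dynamics (CμMD) — concentration-dependent external forces that hold the
composition of selected sub-volumes of a simulation box constant — in all
four published geometry variants (planar symmetric, asymmetric inlet/outlet,
cannibalistic dual-target, spherical).

All quantities are in reduced Lennard-Jones units: ε = σ = m = k_B = 1.
Concentrations are number densities (1/σ³).

## The control scheme

The solution volume around a phase boundary is partitioned into a transition
region (TR) adjacent to the boundary, a control region (CR) whose
composition is held at a target c₀, a force region (FR) where the restraint
acts, and the remaining molecule reservoir. The instantaneous CR
concentration of the controlled species is a smooth function of particle
coordinates,

    c_inst = (1 / V_CR) Σ_j θ(z_j),

and each controlled particle feels an external force along the control axis

    F(z) = k (c₀ − c_inst) G(z) d̂,

where d̂ is the unit direction from the FR toward the CR. A deficit in the
CR pumps material in from the reservoir across the FR; an excess pumps it
out. In the spherical variant z is replaced by the radial distance from the
control center and d̂ by −r̂.

**Switching function θ.** A product of two logistic (Fermi) edges at the CR
bounds, θ(z) = s((z−z_lo)/w) · s(−(z−z_hi)/w) with s(u) = 1/(1+e^(−u)).
The edge width w defaults to 1/20 of the CR width. The integral of θ over
the axis equals the CR width exactly, so the smooth estimator is unbiased
for a homogeneous fluid; the per-configuration difference from a hard count
is counting noise of the O(ρ·A·w) particles in the edge layers.

**Localizer G.** The derivative of a Fermi function of width w_F: a sech²
bell, G(z) = sech²((z−z_F)/(2 w_F)) / (4 w_F), symmetric about the FR
center z_F, with unit integral and peak height 1/(4 w_F). With G normalized
to 1/length, k carries units of energy·volume/number so that k·Δc·G is a
force. The bell is exponentially localized but fatter-tailed than a
Gaussian: the fraction of its weight beyond 5 w_F is ≈1.3×10⁻², beyond
16 w_F it is below 10⁻⁶. FR widths should therefore be chosen so that
~±3 w_F fits between the CR and the reservoir volume.

**Units of k.** The dimensional contract is that k (c₀ − c_inst) G is a
force; with G in 1/σ and concentrations in 1/σ³ this puts k in ε·σ³ per
particle. The scenario defaults (k = 300–600) make the restoring force on
one FR particle ≈ k · (0.05·c₀) · G_peak ≈ 0.7–1.4 ε/σ for a 5% deviation
at c₀ = 0.15, comparable to but not dominating typical LJ pair forces; the
controller's steady-state deficit under a constant drain scales as 1/k.

**Instantaneous vs averaged feedback.** The instantaneous c_inst enters the
force. An optional exponential moving average (`CmuController.ema_window`,
default off) is available to damp feedback noise in small or dilute CRs,
where the relative fluctuation of c_inst is 1/√(c₀·V_CR) per sample and can
dominate the control error.

## Adaptive geometry

Anchored regions keep fixed offsets from the phase boundary. The interface
is located on the solvent concentration profile as the 50% crossing of the
bulk solvent level, linearly interpolated between bins, and smoothed with an
exponential moving average (default span 100 steps) to suppress
single-histogram noise. For a slab, both faces are returned (the crossings
bounding the solvent-density dip). Re-anchoring happens at the diagnostic
cadence (default every 50 steps) rather than every step; this is cheap and
indistinguishable from per-step anchoring at the face velocities realized
here (≲10⁻⁴ σ/step).

The sink/source eligibility layer tracks the crystal face independently,
using the frozen-particle z-histogram: a bin counts as crystal once its
frozen density reaches half the densest (core) bin. This "completed layer"
criterion matters: freshly frozen particles form an under-dense halo, and a
face defined by extreme or quantile positions would chase that halo outward
until the sink layer invades the CR (a feedback artifact we observed with
both min/max and quantile face definitions).

## The host engine

Binary Lennard-Jones fluid, all pair parameters equal (ε = σ = 1, species
labels only matter to the controller and the sink); truncated at r_c = 2.5.
The default truncation is *shifted-force* (both the potential and the force
go continuously to zero at r_c), chosen so that microcanonical energy is
conserved to the level the integrator permits; plain truncated-and-shifted
LJ is available via `LJParams(shift_force=False)`. Forces are computed in
numba kernels: a linked-cell list by default, and a naive O(N²) double loop
kept as the correctness reference (the two agree to 10⁻¹³ on random
configurations; the cell path requires ≥3 cells per periodic dimension).

Integration is BAOAB Langevin with dt = 0.005, friction γ = 1, which
reduces exactly to velocity Verlet at γ = 0. Secular NVE drift at dt =
0.005 is below 10⁻⁴ ε per particle over 10⁴ steps; the kinetic temperature
equilibrates to the thermostat target within ~2% (the residual is the
standard O(dt²) discretization bias). Frozen (crystal) and wall (membrane)
particles exert LJ forces but never move.

**Crystallization proxy.** Growth and dissolution are modeled as stochastic
freezing/release, not as a physical phase transition: solute inside a
capture layer next to a crystal face freezes in place with a per-step
probability, and frozen particles in the outermost crystal layer can be
released with thermal velocities. This makes the demand placed on the
controller a tunable, assertable rate. It deliberately does not reproduce
nucleation barriers, latent heat, or crystalline order; the grown layer has
fluid-like density until further freezes compact it.

## Scenarios (the study conditions)

All scenarios run a supercritical fluid at T = 1.5 and total density 0.45.
Below the critical temperature of force-shifted LJ this density lies in the
liquid–vapor coexistence region and the fluid slowly demixes, superimposing
density drifts on the concentration signals under study; the supercritical
state is single-phase by construction and diffusive enough (D ≈ 0.2 σ²/τ)
that transport responses are measurable in runs of 1.2×10⁴ steps (60 τ).
System sizes are ~900–1300 particles; a 12 000-step run takes ~30–60 s on
one CPU. These problem sizes are the package's chosen desk-scale study
conditions.

- **growth** — central frozen slab (4σ thick, box 7×7×44) with mirrored
  anchored CR/FR pairs sharing c₀ = 0.15 and a two-face sink (rate 10⁻³
  per eligible solute per step, sized so the sink consumes ~25–30% of the
  solute inventory over the 12 000-step window: enough that the
  uncontrolled depletion artifact is unambiguous against CR counting
  noise, while the controlled run's reservoir still covers the demand).
  The generator sizes the solute reservoir against the expected sink
  consumption over the measurement window and raises a sizing error with
  suggested counts when infeasible. Depletion is quoted against the
  initial fill concentration (= c₀ everywhere), not against a noisy early
  window.
- **membrane** — a frozen wall (3σ) with two cylindrical pores separates an
  inlet CR and an outlet CR with targets c_mean ± Δc/2 (single species, no
  solvent); recirculation from outlet to inlet happens through the periodic
  z boundary, so no particle insertion is ever needed.
- **cannibalistic** — a 5σ slab with a supersaturated CR (c₀ˢ = 0.25) at
  its low-z face and an undersaturated CR (c₀ᵁ = 0.15) at its high-z face,
  each anchored to its own tracked interface; the low face freezes and the
  high face releases. Two balance conditions shape the defaults: (i) the
  freeze and release fluxes are matched (~1.5×10⁻³ events/step each) so
  neither side's solute inventory drains over the run — the scheme's own
  steady-state requirement; (ii) each CR holds c₀·V_CR ≈ 50–80 particles so
  that time-averaged counting noise stays well below the 5% control band
  being verified. Each side's fluid is initialized at its own target.
- **spherical** — concentric GR/TR/CR/FR shells about the box center in a
  cubic box, with the reservoir in the corners; the outer shell must stay
  inside the half-box so minimum-image radii are unambiguous.

## Numerical and degenerate-input choices

- Region membership is never hard: all forces and concentration estimates
  are smooth in coordinates; there is no per-particle region assignment to
  tie-break.
- Interface detection on a profile with no threshold crossing raises an
  error rather than guessing; during a run such a diagnostic step keeps the
  previous regions.
- The cannibalistic sink raises a stop signal when the slab becomes thinner
  than the capture layer (faces crossed); the run loop ends cleanly and
  flags the result.
- Profiles use true bin volumes (slab or spherical shell); integration is
  trapezoidal on bin centers with no smoothing. The screening factor masks
  (NaN) any grid point where the denominator integral is still zero instead
  of extrapolating.
- Flux counting is minimum-image-based and checks the plane's periodic
  images; a warning is raised when inter-frame displacements exceed L_z/4
  (crossing aliasing).
- Supersaturation reporting rounds to two significant figures; the driving
  force Δμ/k_BT = ln S is labeled *ideal* — no activity coefficients.
- The screening factor uses plain number concentrations (no charge
  weighting); only monovalent-like profiles are in scope.

## What passing tests do and do not show

The test suite verifies the control machinery: restraint identity at
target, estimator/oracle agreement, localizer normalization, depletion in
an uncontrolled closed system and its cure under control, growth-rate
ordering in c₀, gradient-driven membrane flux, dual-target steadiness with
simultaneous growth and dissolution, and spherical shell correctness. It
does not show that the toy reproduces any real solution's thermodynamics:
there are no activity coefficients, no real force fields, no crystalline
order parameter, and the sink rates are imposed rather than emergent.
Quantitative growth rates, solubilities or permeabilities of real systems
are out of scope by design.

## Known limitations

- Single control axis (z) or radius; no multi-axis grids.
- Thermostatting is global; the FR is not thermostatted separately, so very
  large k would locally heat the fluid faster than γ = 1 can dissipate.
- External control forces do not conserve momentum (by construction); the
  momentum injected per step equals the summed external force × dt.
- Concentration control in very dilute CRs is feedback-noise-limited; use
  larger CR volumes, higher targets, or the c_inst moving average.
- The extended-XYZ writer stores species and positions only; velocities
  live in the binary checkpoint.
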