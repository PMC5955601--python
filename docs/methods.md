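# Methods

## Model

The package treats a neuron as a tree of cylindrical compartments with a
passive leak, optional voltage-gated single-gate channels, and a spatially
uniform extracellular field. With intracellular potential v_i, extracellular
potential v_e = −E₀(**s**·ê) (gauge-fixed to zero at the soma centroid) and
membrane potential v = v_i − v_e, each compartment obeys

    c_m A dv/dt = −I_mem(v) + Σ_j g_ij (v_i,j − v_i,i),

where g_ij are axial couplings and I_mem collects leak and channel currents.
Because tCS-scale fields (≲ 2 V/m) polarize the membrane by fractions of a
millivolt, channels operate in a near-linear regime and the production solver
works with the quasi-active (QA) linearization: each gated current
g_w w(V)(V − E_w), with activation w∞(V) and time constant τ_w(V), is
expanded to first order around rest V_R, giving the per-area admittance

    Y(ω) = iω c_m + g_L γ_R + Σ_ch g_L μ_ch / (1 + iω τ_w,ch),
    γ_R = 1 + g_w w∞(V_R)/g_L,   μ = (g_w/g_L)(V_R − E_w) w∞′(V_R).

The sign of μ classifies the current: restorative (μ > 0; opposes slow
fluctuations; e.g. the h-current, for which w∞′ < 0 and V_R < E_w) or
regenerative (μ < 0). μ* = μ g_L/g_w is the density-independent type
parameter. Freezing a channel (clamping w at rest) is exactly the μ = 0 case
and turns it into a leak increment g_w w∞(V_R).

For one temporal frequency the sensitivity profile comes from the exact
sparse linear solve (G_axial + diag Y) v̂_i = diag Y v̂_e; amplitude and
phase are |v̂_i − v̂_e| and arg(v̂_i − v̂_e). DC is solved as a real system at
ω = 0 exactly, never as a small frequency, to avoid conditioning artifacts.

Sign convention: with v_e = −E₀(**s**·ê), a positive field along +ê
depolarizes the end with the largest axis coordinate (the apical end when ê
is the somato-dendritic axis). Phases are reported relative to the field
sinusoid, wrapped to (−π, π].

## Analytic cable solutions

In normalized units (lengths in λ, sensitivities in V per V/λ) the cable
response at frequency f is controlled by the complex space constant
λ_eq = λ/√(1 + iωτ); its real part λ_gen(f) is the effective decay length
and shrinks with frequency. A straight sealed cable in a uniform field
polarizes as v(X) = λ̂_eq sinh((X − L/2)/λ̂_eq)/cosh(L/(2λ̂_eq)) —
antisymmetric, maximal at the ends, with the end value λ tanh(L/2) at DC.

A bent cable (main branch length H along the field, bent branch length D at
angle Θ) experiences the projected extracellular profile: slope 1 on the
main branch and −cos Θ on the bent branch, **continuous at the bend** (a
discontinuous profile would imply an unphysical delta-field at an interior
point). Θ is measured so that Θ = π is a straight continuation and Θ = 0 a
complete fold-back. The solution is computed exactly by hyperbolic matching:
v_i = v_e + A cosh(x/λ_eq) + B sinh(x/λ_eq) per piece, with sealed ends and
C¹ continuity at the bend (a 4×4 complex solve per frequency). An
independent single-mode route is provided by the sealed-end Green's-function
solution of −V_i″ + V_i = sin(Ω_x X + φ_s): particular response
sin(Ω_x X + φ_s)/(Ω_x² + 1) plus hyperbolic terms fixed by the sealed ends;
at Ω_x = 0 a spatially constant extracellular potential polarizes nothing.
Both routes are validated against finite differences and against the
compartmental solver to ≤ 1e−3 relative.

Resonance detection on a sweep: grid argmax refined by quadratic
interpolation in log-frequency; a location counts as resonant only if the
refined peak lies above the lowest swept frequency and the amplitude
(peak minus the 0.5 Hz baseline) exceeds 1% of the peak. The 1% floor is a
detection threshold choice; it cleanly separates the monotone (Θ ≥ π/2) and
resonant (acute Θ) bent-cable regimes on our fixtures.

## Discretization and numerics

- Compartment length ≤ min(10 μm, 0.01 λ_DC). Each SWC edge becomes equal
  sub-cylinders with the child radius; couplings are center-to-center series
  half-resistances (second-order finite volume). Against closed forms this
  gives ≤ 0.04% error up to 1 kHz on the standard cable fixture, converging
  at second order.
- A type-1 root is a single equivalent cylinder with length = diameter =
  2·max soma radius. Synthetic cable/star fixtures are built without a soma
  so that the exact antisymmetry and reduction identities hold; "soma" on
  those resolves to the junction compartment.
- "End sensitivity" quoted against closed forms reconstructs the boundary
  value from the last compartment center via the sealed-end condition
  ∂v/∂x = E; profile comparisons evaluate closed forms at compartment
  coordinates.
- Units: mV, ms, μm, μS (so μS·mV = nA, nF/μS = ms), cm² areas, Ω·cm axial
  resistivity, V/m fields; 1 V/m across 1000 μm is 1 mV. All conversions are
  centralized in `fieldpol.units` and tested.
- Time domain: Crank–Nicolson (implicit midpoint) on the linear system with
  the gate states as extra variables, dt = 0.025 ms, factorized once —
  unconditionally stable and second order, which matters for the onset
  overshoot of restorative models. The nonlinear oracle uses the staggered
  scheme (exact exponential gate update, implicit membrane step) and is
  reserved for validation on small fixtures.
- The measurement protocol mirrors standard practice: 700 ms settling
  without the field (for the linear deviation system this is exact, as rest
  is the fixed point; the nonlinear integrator settles explicitly), field on
  for ≥ 2 cycles and ≥ 400 ms, sensitivity read from the last polarization
  extremum (AC) or the steady tail (DC). Phasor and protocol readouts agree
  to ≲ 0.01% on the cable fixtures.
- w∞′(V) uses the channel's analytic form when available (Boltzmann gates
  supply one), else a central difference with 0.01 mV step — μ precision
  places the resonance.

## Default parameters

| parameter | default | why |
| --- | --- | --- |
| c_m | 1 μF/cm² | standard specific capacitance |
| g_L | 50 μS/cm² | uniform leak density of the QA analyses |
| R_a | 100 Ω·cm | axial resistivity |
| cable λ, τ | 500 μm, 40 ms | cable-figure conditions; realized exactly via r = 0.25 μm |
| QA τ_w, w∞(V_R) | 50 ms, 0.5 | generic restorative-channel defaults |
| distribution ratio | 60 | somato-apical gradient of measured I_h densities |
| frequency grid | {0} ∪ 30 log-spaced in [0.5, 1000] Hz | resolves the 5–50 Hz resonance band at ~10 points/decade |
| field amplitude | 1 V/m | tCS scale; results are amplitude-independent (linear) |

Cable fixtures are specified electrotonically (λ, τ); the radius is a free
scale and the membrane densities are solved from λ = √(r/(2 R_a g_m)) and
τ = c_m/g_m, so normalized results are exact while densities stay at the
50 μS/cm² scale.

## Synthetic morphologies

The generator reproduces the geometric features the field response depends
on, not the statistics of real reconstructions: a straight cable (the
antisymmetry/decay baseline), a bent cable with controlled (H, D, Θ) (the
projection-induced "passive resonance"), a soma-star model (a main "apical"
cable with N angled "basal" branches plus one antiparallel branch — the
branch-count asymmetry and shunt logic), and a seeded surrogate pyramidal
cell: soma, 800 μm apical trunk with a tuft, a basal star, and oblique
branches at an acute angle whose tips project beyond their branch points on
the field axis. Randomness is limited to azimuths and ±10% branch lengths
behind a single integer seed; identical seeds give byte-identical SWC.

What passing tests on these fixtures show — and what they do not: they
verify the solver, the QA theory and the morphology-driven mechanisms
(branch-count asymmetry, acute-angle resonance, h-like resonance placement,
shunt and high-conductance effects). They do not calibrate absolute
sensitivities of any real reconstructed cell, which depend on the full
morphology and measured channel densities.

## Design choices where the design was open

- Spatial discretization is convergence-driven (the reference analyses do
  not state theirs); the default bound keeps closed-form error well under
  0.5%.
- The bent-branch extracellular profile is taken continuous at the bend (see
  above); Θ = π reduces exactly to the straight cable, which fixes the angle
  convention.
- The somato-dendritic axis uses segment volumes π r² l for the center of
  mass, excludes the soma itself, and excludes the axon by default (the
  axis targets the somato-dendritic extent); a toggle includes it.
- Spine correction scales the effective membrane area (hence per-area
  conductances and capacitance equivalently) of dendritic regions only; the
  soma is excluded by default.
- Multiple channels are linearized or frozen independently and their
  admittances sum.
- The "most distal apical point" for linear conductance distributions is the
  apical compartment of maximal path distance, ties broken by lowest index.
- Gated channels encountered by the frequency-domain solver are linearized
  around the model's resting potential automatically; the time stepper does
  the same unless asked not to, in which case it refuses and points to the
  nonlinear integrator.

## Known limitations

- Single-gate channels only (no m^a·h^b kinetics, no calcium pools); the QA
  theory implemented is first order in one gate per channel.
- Uniform fields only, plus the piecewise-linear bent-cable profile; no
  point-source or endogenous field geometries, no LFP forward model, no
  ephaptic coupling, and no suprathreshold dynamics.
- Branched (star) morphologies go through the compartmental solver only;
  the analytic module covers straight and bent cables.
- High-conductance comparisons: the absolute sensitivity reduction is strict
  below ~100 Hz; near 300–400 Hz the flattened curves approach the
  low-conductance curve within ~0.1% and can cross it, a property of the
  linear model itself.
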