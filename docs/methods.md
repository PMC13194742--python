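# Methods

## Scope and model overview

`hydrostim` implements the quasi-static biophysics of hydrogel-mediated
capacitively-coupled deep-brain stimulation at desk scale: interfacial
(Maxwell–Wagner) polarization at a conductive-hydrogel/brain boundary, a
one-dimensional series-impedance model of power transfer through the
layered head with SAR evaluation, burst-waveform synthesis, a
sphere-inclusion localization model, and the standard hydrogel/electrode
characterization formulas. Full 3-D field solving and thermal transport
are out of scope; the sphere model plus a test-time finite-difference
Laplace oracle stand in for finite-element field maps.

## Dielectric description

A medium is (σ, ε_r), constant or tabulated on a frequency grid.
Admittivity is Y = σ + jωε₀ε_r with ε₀ = 8.85 × 10⁻¹² F m⁻¹ throughout;
this slightly rounded value of the vacuum permittivity is used
consistently so that all derived coefficients match the reference
derivation they reproduce (the difference from the CODATA value is
< 0.05 %).

The relaxation time is computed with absolute permittivity, τ = ε₀ε_r/σ.
This convention yields seconds and makes the identity exact: two media
with equal τ produce exactly zero interfacial surface charge (because
Y_h/Y_b then collapses to σ_h/σ_b), which the tests assert to machine
precision.

Tabulated media interpolate linearly in log₁₀(frequency) — tissue
dispersions are smooth on a log axis — exactly at grid nodes, and refuse
extrapolation. The bundled table carries the hydrogel (30 S/m, 1.35) and
the 5 MHz brain point (0.27 S/m, 670) as primary values; the brain values
at other grid points and the scalp/skull dispersions are package defaults
in the style of standard tissue-property databases, intended to make the
sweep well-posed over 100 kHz–10 MHz. They are overridable from a CSV
(columns `tissue,frequency_hz,conductivity_s_per_m,relative_permittivity`)
and should be replaced for quantitative work at frequencies other than
5 MHz. The insulation film defaults to σ = 0, ε_r = 3 (thin polymer).

## Interfacial polarization

From current continuity, E_h/E_b = Y_b/Y_h; substituting into the
displacement-discontinuity expression gives

ρ_s / E_h = ε₀ (ε_b Y_h/Y_b − ε_h),

a complex quantity. The default mapping to a real coefficient is the
complex magnitude, which gives 0.0542 nC cm⁻² per V m⁻¹ for the reference
media at 5 MHz; the real part (in-phase component, ≈ 0.045) is exposed as
an alternative convention. The magnitude is the default because the
surface-charge estimates it produces are the ones the activation-threshold
comparison is calibrated against.

The field inside the hydrogel is estimated as E = ΔU/r from a potential
drop measured between the inclusion centre and edge — a uniform-field
assumption over the inclusion radius, with no correction for probe
polarization. Activation is declared when ρ_s ≥ 15 nC cm⁻² (the
configurable threshold).

## Sphere-inclusion model and its oracle

Localization is summarized by the Clausius–Mossotti factor on complex
effective permittivities ε* = ε₀ε_r − jσ/ω:
K = (ε₁* − ε₂*)/(ε₁* + 2ε₂*), interior field factor 3ε₂*/(ε₁* + 2ε₂*),
DC limit K = (σ₁ − σ₂)/(σ₁ + 2σ₂). The reported maximum polar surface
charge per unit applied field is 3ε₀|ε_r,₂K|.

The analytic factors are cross-checked in the test suite against an
independent brute-force solver (`tests/_laplace_oracle.py`): a
cell-centered 7-point finite-difference discretization of ∇·(k∇φ) = 0 with
harmonic-mean face coefficients, Dirichlet φ = −E₀z on a box of half-width
3 sphere radii, solved with diagonally preconditioned BiCGStab. The
staircase sphere boundary gives an O(h) error, removed by Richardson
extrapolation over two grids (40³ and 56³), after which the interior field
factor agrees with the closed form to ~1 % across contrasts (the test
asserts 5 %). The oracle is test-only and never feeds the implementation.

**Monotonicity caveat.** The surface-charge coefficient increases strictly
with hydrogel conductivity over σ_h ∈ [0.27, 100] S/m at 5 MHz. |K| also
rises over this range but is *not* globally monotone: right at
conductivity parity (σ_h ≈ 0.27–0.45 S/m) the permittivity contrast
dominates the contrast factor and |K| dips by < 2 % before the
conductivity-driven rise takes over. The trend scenario samples the range
on a 50-point linear grid, on which the rise is strictly monotone; a fine
or logarithmic grid near parity resolves the dip.

## Layered circuit model and SAR

Each layer of thickness d over shared area A contributes a series
impedance. The default "as-printed" element is
Z = d/(σA) + 1/[(σ + jωε₀ε_r)(A/d)] — a resistive term plus a full
lossy-dielectric slab term. Because the slab term already contains
conduction, this form double counts it; it is retained as the default for
reproducibility, and a physically conventional single parallel-RC slab
Z = d/[(σ + jωε₀ε_r)A] is available via `mode="parallel-rc"`. The
denominator grouping (σ + jωε₀ε_r)·(A/d) is the only dimensionally
consistent parse of the as-printed form. Layers with σ below 10⁻⁹ S/m
(the insulation film) are treated as purely capacitive in as-printed mode.

From the drive RMS voltage: I = V_rms/|Z_total|, J = I/A, per-layer
E = J/|Y| (magnitude convention, producing a real field amplitude), and
SAR = σE²/ρ with ρ the brain mass density, default 1046 kg m⁻³ (standard
literature value, configurable). The coupling area defaults to the
reference value 0.78 × 10⁻⁵ m² as printed alongside a "10 mm diameter"
transmitter; note a 10 mm disc is geometrically 7.85 × 10⁻⁵ m² — the
geometric value is available as `GEOMETRIC_DISC_AREA`. Similarly the
0.0445 cm² projected inclusion area used for current-density conversion is
about twice the geometric projection of a 1.7 mm sphere; both printed
values are used verbatim where the reference workflow uses them.

Whether the RMS voltage entering the sweep should be the duty-cycled burst
value (0.156 V for the ±2.5 V, 60 μs/130 Hz drive) or the continuous
carrier value (1.77 V) is genuinely ambiguous, so both conventions are
computed everywhere SAR is reported; the 2 W kg⁻¹ verdict holds under both
(max ≈ 3.9 × 10⁻³ and 0.50 W kg⁻¹ respectively over 100 kHz–5 MHz with the
default table).

## Waveform

Bursts are rectangular-gated sine pulses with zero rise time and carrier
phase restarting at 0 at each pulse onset; duty = width × rate ∈ (0, 1],
V_rms = (A/√2)√duty. Traces are deterministic (no RNG). A warning is
emitted when a pulse holds fewer than 10 carrier cycles, where the gated-
RMS description degrades.

## Characterization metrics

* Young's modulus E = 2√(G′² + G″²)(1 + ν), ν = 0.5 by default
  (incompressible), so E = 3|G*|.
* Four-point conductivity σ = LI/(WHU) for a rectangular bar.
* CSC: trapezoidal integral of the CV current over the traversed
  potential, ÷ 2vA. Default rectification integrates |i| (standard
  practice; both sweep branches add). The signed "as-printed" variant is
  retained for fidelity and cancels to ≈ 0 on symmetric loops.
* CIC = (|Q_a| + |Q_c|)/A, phases segmented by the sign of a
  median-filtered (window 3) copy of the current — robust to isolated
  noisy samples; monophasic traces are rejected.
* Gel point: first upward crossover of G′ over G″, linearly interpolated
  between samples; `None` when already gelled or never gelling.
* J = I/A in mA cm⁻²; calcium activation when max ΔF/F₀ ≥ 0.5.

Integration is trapezoidal throughout; closed-form recovery tolerances are
10⁻³ relative at ≥ 1000 samples per cycle (the CV vertex sample contributes
an O(1/samples) edge error).

## Synthetic generators

Each generator takes a seed, builds one `numpy.random.default_rng` stream
per call, and adds Gaussian noise (the simplest defensible noise model) to
an exact closed form: triangular-sweep RC voltammograms (exact
per-segment ramp response; R = 0 gives the ideal ±Cv rectangle), square
biphasic pulses, logistic G′ gelation against constant G″
(t* = t_mid − ln(G′_p/G″ − 1)/rate), wire-pair potential readings
ΔU = E·r + noise, and per-cell calcium transients with a fixed responder
fraction. Defaults mirror the reference measurement conditions: CV swept
−0.5…0.5 V at 50 mV/s; ±0.5 V-class biphasic pulses of 60 μs per phase;
gelation completing within the first minutes with a plateau modulus of
order 10² Pa (G′_p = 160 Pa, G″ = 20 Pa, rate 0.1 s⁻¹, t_mid = 60 s);
responder fraction 0.45 with peak ΔF/F₀ = 2.0.

Note the logistic parameterization: with t_mid fixed, a faster gel rate
moves a crossover that lies *below* the inflection (G″ < G′_p/2) later,
not earlier, because a sharper sigmoid stays near zero longer. The
"faster gelation crosses earlier" intuition holds when the crossover sits
at or above the inflection, and the tests exercise both regimes.

What the generators deliberately do not emulate: electrode drift,
capacitive charging asymmetry, faradaic side reactions, 1/f and line
noise, photobleaching, or cell-to-cell amplitude heterogeneity. Passing
round-trips therefore demonstrate correctness of the formulas and their
numerical implementation on idealized traces, not robustness to real
instrument artefacts.

## Scenarios and determinism

`hydrostim.pipeline.run_scenario` exposes four named, schema-validated
scenarios (`polarization-reference`, `sar-sweep-reference`,
`conductivity-trend`, `metrics-demo`); reports are pure functions of their
configuration (no timestamps), so re-runs are byte-identical. The numbered
scripts under `analysis/` are thin narrative drivers over these scenarios
and write their tables under `results/`.

Problem sizes used by the shipped analyses: 60-point frequency sweeps,
50-point conductivity grids, 2000-sample CV cycles, 100-cell calcium
panels — sizes at which every closed-form recovery is well inside its
stated tolerance while the whole analysis suite runs in seconds.

## Known limitations

* One-dimensional series circuit: no fringing, no lateral spreading, no
  electrode contact impedance.
* Quasi-static single-carrier analysis; burst harmonics are not
  superposed.
* Uniform-field ΔU/r estimate inside the inclusion; sphere model assumes
  an isolated sphere in an unbounded host.
* Default scalp/skull dielectric entries are plausible placeholders, not
  measured values; replace them for quantitative SAR at other
  frequencies.
* No thermal model: SAR is compared against the exposure limit, but
  temperature rise is not computed.
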