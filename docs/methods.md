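# Methods

This note documents the models implemented in `nmdose`, the assumptions
behind them, the numerical choices made where the underlying framework
is silent, and what the synthetic fixtures do and do not establish.

## Dose model and unit chain

Organ absorbed dose follows the standard internal-dosimetry
decomposition into biokinetics and physics: the time-integrated activity
coefficient (TIAC, hours) counts nuclear transformations in a source
region per administered MBq, and the S-value (Gy per transformation)
carries all radiation transport through specific absorbed fractions
(SAFs, kg⁻¹). Every unit conversion is centralized in `nmdose.dose`:

- 1 MeV = 1.602176634e-13 J (exact, via the elementary charge);
- 1 MBq·h = 1e6 Bq × 3600 s = 3.6e9 nuclear transformations;
- D [mGy/MBq] = TIAC [h] × 3.6e9 × S [Gy/nt] × 1e3, i.e. a net
  multiplier of 3.6e12 from TIAC × S to mGy/MBq.

S-values sum E·Y·Φ over discrete photon, electron and alpha lines and
replace the sum with a trapezoidal integral over the tabulated beta
spectrum. The beta integral is evaluated on the spectrum's own grid
(spectra are denser than SAF grids), with the electron SAF interpolated
to each spectrum node. Alpha recoil energy is ignored.

## SAF handling

- Energy interpolation is log–log linear with end clamping. At a grid
  node the stored value is returned exactly; below/above the grid the
  end value is used, avoiding unphysical extrapolation. Grid segments
  with a zero endpoint fall back to linear interpolation in log-energy
  (zero has no logarithm; the fallback keeps node identity and
  finiteness).
- The composite source "Other" is the mass-weighted mean SAF over the
  phantom's eligible soft-tissue sources not claimed by the biokinetic
  model. Eligibility is explicit phantom configuration: organ contents
  and air do not exchange with circulating blood and are excluded.
- The blood rule: biokinetic models that do not carry the circulating
  blood as an explicit source would silently drop the blood-bearing
  sub-regions (large vessels, heart content). These are folded into
  Other with weight equal to their share of the regional blood volume;
  when Blood is an explicit source the composition is left untouched so
  no transformation is counted twice.
- The 100-day infant is always derived, never stored:
  S_100d = 0.6528·(S_1yr − S_0d) + S_0d, applied elementwise to whole
  S-matrices. The derivation is linear and order-preserving, so derived
  values always lie between the newborn and 1-year values.
- The region vocabulary maps common synonyms (e.g. "urinary bladder
  wall", "red (active) bone marrow") onto one canonical spelling;
  fixture phantoms may use free-form names, and strict validation is
  opt-in. The reference target list carries 48 entries of which the eye
  lens has no tissue weight in any scheme; it is reported as an extra
  row, never as a Remainder member.

## Effective dose

Tissue weighting uses the ICRP 103 set (gonads 0.08; marrow, colon,
lung, stomach, breast, Remainder 0.12; bladder, oesophagus, liver,
thyroid 0.04; bone surface, brain, salivary glands, skin 0.01) and the
ICRP 60 set (gonads 0.20, thyroid 0.05, Remainder 0.05, …); both tables
are shipped as config data verified against SHA-256 checksums at load.
Radiation weights are 1 for photons and electrons (beta included) and 20
for alphas, applied to the per-radiation-type dose breakdown carried
through the whole pipeline.

Remainder tissues are the unweighted arithmetic mean of 13 organs in the
103 scheme, the 13th being sex specific (prostate / uterus-cervix). For
sex-specific organs each sex contributes the equivalent dose of its own
organ to the sex average (testes/ovaries for "Gonads"); the
detriment-adjusted variant is the same recombination without the /2 sex
average, per sex. By construction
E = (E_male + E_female)/2 whenever organ membership mirrors across
sexes, and recomputing E from the stored per-target doses reproduces it
exactly.

An optional per-target mass override rescales self-irradiation S terms
by M_ref/M_new for patient-specific target masses, followed by a second
dose pass.

## Decay chains

Serial chains are solved with the closed-form Bateman solution including
branch fractions. When any two decay constants come within 1e-9 relative
the distinct-eigenvalue form suffers catastrophic cancellation, so the
chain is routed to the matrix exponential of the chain generator — the
exact confluent solution, computed stably — rather than a hand-coded
per-multiplicity polynomial form. Stable members are represented with an
infinite half-life and zero activity.

## Retention fitting and TIACs

The organ curve fitter represents A(t)/A0 as 1–3 retention exponentials,
optionally damped by one or two uptake factors of the form
(1 − e^(−μt)), which forces A(0) = 0 for uptake systems. All nine
system × component combinations are available in the library; the CLI
menu exposes the five named combinations (direct×{1,2,3}, 1-uptake×1,
2-uptake×1).

The objective is unweighted SSE on normalized activities (a relative
weighting flag divides residuals by the data). Initialization is
multistart: rates log-spaced between 1/(10·t_max) and 10/t_min,
amplitudes from non-negative linear least squares at each rate guess
(variable projection); the best-SSE solution wins. Because every model
expands into a plain sum of exponentials, the TIAC has a closed form for
any integration period including T_D = ∞; the physical decay constant is
added to every rate when the curve was decay-corrected, a semantic
carried as an explicit flag so no silent assumption is made. A zero
total rate with infinite T_D raises a divergence error.

The compartment solver evaluates exp((M − λ_phys·I)·t) for first-order
transfer matrices with conserving columns; it is exact for any linear
system and conserves total activity when λ_phys = 0 and no excretion
path exists.

## Dynamic bladder

Between voids the content volume grows with the urine flow (plus an
additive hydration flow over a user window) and the content activity
obeys dA/dt = inflow(t) − λA, integrated with a high-order explicit
Runge–Kutta scheme (rtol 1e-10) and dense output. At each void — by
default at multiples of the voiding interval, first void at one
interval — the volume drops to the residual and activity is removed in
proportion to the removed volume (well-mixed urine). The wall dose
integrates A(t)·S(V(t)) per inter-void segment with adaptive quadrature;
the content→wall S-value is interpolated log–log in volume and clamped
outside its grid. With a volume-independent S the model reduces exactly
to the static product (content TIAC) × S. The content TIAC feeds the
static SAF pathway for all non-wall targets. Content→wall S(V) curves
are configuration data at miniature scale; real curves are
user-suppliable in the same dialect.

## Age and weight interpolation

Organ doses are interpolated piecewise-linearly between the fixed
phantom nodes (ages 0, 1, 5, 10, 15, 20 y; the derived 100-day infant,
0.274 y, is insertable as an optional node) or between reference total
body weights, 3.5–73 kg male and 3.5–64 kg female. Interpolation is
linear on the dose scale by default with a log-scale flag (paediatric
doses span decades); no extrapolation is permitted. The effective dose
is recomputed from the interpolated organ doses of both sexes rather
than interpolated itself, keeping it internally consistent.

## Sphere dosimetry

Sphere S-values use Φ = AF(E, V)/mass with bilinear log–log
interpolation in energy and volume, exact on grid nodes and clamped at
the edges, for volumes 0.01–3000 cm³ and user-defined tissue materials.
The photon/electron/alpha/beta split is retained. Progeny are assumed
produced and retained in place, with the parent's retention folded into
a mono-exponential of the same TIAC (effective clearance 1/TIAC per
hour). Over an infinite integration period every retained progeny atom
eventually decays, so the Bateman in-growth integral collapses to
TIAC_child = (product of branch fractions) × TIAC_parent for radioactive
members; stable members contribute nothing. This is verified in the
tests against numerical integration of the in-growth ODE.

## Fixtures: what they emulate and what they do not

The fixture generator produces seeded, bit-reproducible miniatures with
analytic ground truth: phantoms whose SAFs conserve energy exactly
(Dirichlet energy shares divided by target masses, constant in energy by
default so closure holds at any emission energy), toy nuclides with
known Δ totals, sphere AF tables monotone in volume, decreasing
content→wall S(V) curves, and lognormal-noised time–activity curves with
stored truth. Weighted-phantom pairs share masses across sexes with only
the sex-specific organ names swapped, which keeps sex-averaging
identities exact at toy scale.

These fixtures establish correctness of the arithmetic, interpolation,
integration and recombination steps. They do not establish realism:
real SAF tables are not energy-constant, real male/female phantoms do
not share masses, and real biokinetic data have structured (not
lognormal i.i.d.) errors. Passing tests therefore validate the
computational framework, not any specific dose coefficient.

## Problem sizes and numerical tolerances used in the tests

- Bateman vs ODE oracle: 100 random 2–4 member chains, agreement 1e-8
  relative wherever a member's activity is within six decades of its
  peak (below that the reference integrator itself has no relative
  accuracy).
- TIAC closed form vs adaptive quadrature: 1e-8 relative.
- Retention-fit recovery: 200 seeded replicates of a 2-exponential
  (amplitudes 0.5/0.3, rates 0.5/0.05 h⁻¹ — a typical fast-washout plus
  slow-retention organ), 10 log-spaced samples to 48 h, 5 %
  multiplicative lognormal noise; the median recovered rate constant
  over replicates must stay within 10 % of truth for both components.
  Every fit in this experiment reaches an SSE at or below that of the
  true parameters, i.e. the multistart optimizer finds the global
  optimum and the residual spread is purely statistical.
- Whole-body closure of S-matrices on conserving fixtures: 1e-6
  relative; the fixture construction itself is exact to 1e-12.
- Bladder ODE rtol 1e-10; static-limit equivalence 1e-8 relative.

## Known limitations

- SAF generation from voxel phantoms, dose-point kernels and
  charged-particle transport are out of scope; SAF and AF tables are
  inputs.
- Specific published biokinetic models are treated as external inputs;
  none are bundled.
- Progeny during phantom (non-sphere) dosimetry are not automatically
  added to parent S-values; decay-chain handling is the caller's
  responsibility through per-nuclide TIACs or the sphere module.
- The fetal/uterus dose pathway from bladder content is not modelled.
- Uncertainty propagation and risk (detriment) coefficients per sievert
  are not computed.
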