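# Methods

## Scope and model assumptions

The package quantifies a turn-off fluorescence sensing workflow: a
fluorophore (the "probe", here a quinoline-appended acridine bearing an
aromatic amine) whose emission is quenched by an electron-poor
nitroaromatic analyte (picric acid), plus the photophysical and
green-chemistry characterization that accompanies such a report. Three
physical models underlie the analytics:

**Stern–Volmer quenching.** I₀/I = 1 + K_SV·[Q]. Both collisional
(dynamic) quenching and ground-state complex formation (static quenching,
association constant K_a) produce this linear law at low quencher
concentration, so the fitted slope is reported as K_SV without asserting a
mechanism. The default fit leaves the intercept free and warns when it
deviates from 1 by more than 0.05 — the practical symptom of leaving the
linear regime (upward curvature from combined static + dynamic quenching,
or inner-filter effects, neither of which is modelled). A boolean mask
restricts the fit to a chosen concentration window; `fix_intercept=True`
fits (I₀/I − 1) = K_SV·[Q] through the origin. Ordinary least squares is
used in both cases; heteroscedasticity of I₀/I at strong quenching is not
weighted for, matching common practice for these plots.

**Detection limit.** LOD = 3σ_blank/|slope|, with σ_blank the ddof=1
sample standard deviation of ≥3 blank replicates and the slope from an OLS
line through the low-concentration calibration. The regressed response is
raw intensity by default; `response="delta_intensity"` regresses I₀ − I
instead (the two give identical LODs up to the slope's sign). The identity
LOD·|slope| = 3σ_blank holds to machine precision by construction. Note
the estimator is mildly biased low in small blank panels (the Gaussian
sample-SD bias, E[σ̂] = c₄σ ≈ 0.973σ at n = 10); no correction is applied
because the 3σ/slope convention does not apply one.

**Continuous variation (Job's method).** Host and guest are mixed at fixed
total concentration C_total while the host mole fraction x varies; for a
single HmGn complex the signal (proportional to complex concentration)
peaks at x = m/(m+n) regardless of K_a. The discrete maximum is refined by
a parabola through its three neighbours; the ratio is the small-integer
rounding of (1 − x_max)/x_max, reported only for components ≤ 4 (beyond
that the curve becomes too flat for the method to discriminate). A maximum
at the edge of the sampled range is flagged inconclusive rather than
rounded. The symmetry score 1 − mean|s(x) − s(1−x)|/max|s| is 1 for an
ideal 1:1 curve. Optional baseline correction removes the straight line
through the endpoint signals.

## Binding equilibrium solvers

The 1:1 equilibrium is solved in closed form,
[HG] = 2H₀G₀ / (s + √(s² − 4H₀G₀)) with s = H₀ + G₀ + 1/K_a — the
subtraction-free form of the quadratic root, stable at large K_a where the
textbook form cancels catastrophically. General m:n complexes solve
K_a(H₀ − mc)^m (G₀ − nc)^n = c by Brent's method on
[0, min(H₀/m, G₀/n)], to relative tolerance ~9e-16. One caution on
saturation behaviour: for equal totals H₀ = G₀ = c the free-species
residue decays only as √(c/K_a), so "complete" binding needs
K_a·c ≳ 10¹² for 10⁻⁶ relative saturation — relevant when constructing
saturation test cases.

## Photophysics

Peaks are local maxima with prominence ≥ 5% of the global signal maximum
(scipy's prominence definition), refined by a 3-point parabolic fit; on a
regular grid this recovers an isolated Gaussian center to well under a
tenth of the grid spacing. Stokes shifts are computed as
Δν = 10⁷(1/λ_abs − 1/λ_em) cm⁻¹ (λ in nm). The table builder pairs the
**shortest-wavelength** absorption maximum (the high-energy π–π* band)
with the emission maximum by default — the pairing that reproduces the
published per-solvent Stokes-shift tables for this fluorophore — with
`band="longest"` available for the n–π* band. Molar absorptivity uses
Beer–Lambert ε = A/(c·l) at the chosen band's peak height. One published
entry (DCM) is not reproducible from its own printed wavelengths
(268/434 nm give 1.4272 × 10⁴ cm⁻¹ vs 1.4279 × 10⁴ printed, an upstream
rounding artifact); the tests pin the value computed from the wavelengths.

## Green metrics

Standard definitions throughout: AE from the balanced equation only
(invariant to masses and yield), PMI/E-factor on a configurable role basis
that by default counts reactants and catalyst but **not** solvent — a
deliberate choice because the reference syntheses run in a recyclable deep
eutectic solvent, and a closed-loop solvent should not dominate mass
intensity. RME = 100·(product mass)/(reactant mass), CE mole-weighted on
carbon, yield from the limiting reactant (smallest moles/equivalents).
E = PMI − 1 holds identically; RME = 100/PMI holds exactly when PMI is
computed on the reactant-only basis. Published RME/PMI values for these
compounds (~77%, ~1.29) cannot be reconstructed from the printed reagent
masses and yields under any standard basis, so the package reports the
standard definitions and flags rather than imitates. Atomic masses are the
IUPAC 2021 conventional weights compiled into the package (3–4 decimals),
which reproduces the recomputable published atom economies within ±0.2
percentage points. Element balance is audited per reaction; when
byproducts are unlisted, a residual of exactly k·H₂O is recognized as
condensation water (the Friedländer condensations here release 2 or 4
waters).

## Synthetic data: what it emulates, and what it does not

The simulators generate the study's input classes with known ground truth:
Gaussian band spectra (band σ defaults 10 nm absorption / 18 nm emission,
typical solution bandwidths), solvatochromic series as per-solvent band
offsets, titrations under either a pure dynamic law or a pure static limit
(bound probe fully dark, per the H-bonded complex/PET picture), Job series
from the equilibrium solvers, and LOD calibrations whose default top
standard sits at 50σ/|slope| (a comfortably quantifiable signal) with 10
blank replicates — a realistic blank panel where the source protocol is
silent. Noise is additive i.i.d. Gaussian on intensities; there is no shot
noise, baseline drift, inner-filter attenuation, scatter, or vibronic band
structure. Passing recovery tests therefore demonstrates estimator
correctness under an idealized instrument model, not robustness to real
instrument pathology. All randomness flows through explicit
`numpy.random.default_rng(seed)` instances; no global state.

Default study conditions mirror the reference system's magnitudes:
K_SV ~ 6.5 × 10⁶ M⁻¹, LOD ~ 1.8 × 10⁻⁹ M, K_a = 10⁶ M⁻¹ and
C_total = 2 × 10⁻⁵ M for continuous variation, probe 10⁻⁵ M, I₀ = 1000 a.u.

## Numerical choices and degenerate inputs

- Peak ties and non-concave 3-point neighbourhoods fall back to the grid
  point; vertices are clipped to the bracketing interval.
- Flat or monotone spectra yield an empty peak set, not an error; an
  all-zero spectrum cannot be normalized.
- Stern–Volmer requires ≥3 distinct concentrations and strictly positive
  intensities; constant intensity legitimately fits K_SV = 0.
- σ_blank = 0 yields LOD = 0; a zero calibration slope is a fit error.
- Formula parsing strips the typography found in papers (underscores,
  unicode subscripts, whitespace) before applying the grammar
  `element := [A-Z][a-z]?`, optional count ≥ 1, parenthesized groups with
  multipliers; Hill order (C, H, alphabetical) is the canonical
  serialization.
- Test problem sizes are kept at desk scale (10–41 point series,
  100-replicate Monte-Carlo panels, 1000-case solver cross-checks), which
  the full suite completes in a few seconds.

## Known limitations

- No Benesi–Hildebrand or global multiwavelength binding fits; K_a enters
  only through the simulators.
- No discrimination of static vs dynamic quenching (would need lifetime
  data); no inner-filter correction.
- Average (not monoisotopic) masses only: HRMS agreement checks are
  nominal-mass sanity checks and drift ~0.5 u per chlorine.
- Monte-Carlo recovery bounds are statements about means over seeded
  replicate panels; single noisy realizations scatter more widely (the
  LOD's single-fit spread is ~25% relative at the default panel sizes).
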