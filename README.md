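# quenchkit

Analytics for "turn-off" fluorescence chemosensing of nitroaromatics —
built around the workflow used to characterize a quinoline-appended
acridine fluorophore as a selective sensor for picric acid (PA,
2,4,6-trinitrophenol) — plus the green-chemistry bookkeeping that goes
with reporting its synthesis.

It is aimed at bench chemists and analytical spectroscopists who have
titration, continuous-variation and spectral CSV data (or want simulated
data with known ground truth) and need the standard derived quantities
with uncertainties and diagnostics instead of spreadsheet arithmetic.

## What it computes

**Sensing analytics** (model/results objects, statsmodels-style):

- **Stern–Volmer quenching constant.** `SternVolmer(...).fit()` regresses
  I₀/I on quencher concentration, I₀/I = 1 + K_SV·[Q], with a free or
  fixed unit intercept, standard error, R², and a warning when the
  intercept drifts from 1 (a sign the series left the linear regime).
- **Detection limit.** `LODCalibration(...).fit()` combines a linear
  low-concentration calibration with blank replicates:
  LOD = 3σ_blank/|slope| (σ_blank is the n−1 sample SD).
- **Job's-plot stoichiometry.** `JobPlot(...).fit()` locates the maximum
  of a continuous-variation curve by parabolic interpolation; the mole
  fraction at the maximum gives the host:guest ratio (x_max = 0.5 → 1:1).
- Quenching efficiency, a selectivity/interference panel over competing
  nitroaromatics (2NP, 3NP, 4NP, 3NA, ANP, ...), and a reversibility
  index for regeneration with a base such as triethylamine.

**Photophysics** (`quenchkit.spectra`): band maxima by prominence-filtered
peak picking with 3-point parabolic refinement, molar absorptivity
ε = A/(c·l), Stokes shifts Δν = 10⁷(1/λ_abs − 1/λ_em) cm⁻¹, and
solvatochromic (bathochromic) shift ranges across solvent series.

**Green metrics** (`quenchkit.greenmetrics`): atom economy, process mass
intensity, E-factor (= PMI − 1), reaction mass efficiency, carbon
efficiency and percent yield from a YAML reaction specification, with an
element-balance audit that infers condensation water automatically.

**Simulators** (`quenchkit.simulate`): seeded generators for every input —
Gaussian band spectra, solvatochromic series, dynamic or static-complex
quenching titrations, Job series driven by an exact 1:1 (closed-form) or
m:n (bracketed root) binding-equilibrium solver, and LOD calibrations.

## Worked example

```python
import numpy as np
from quenchkit.simulate import QuenchSimSpec, simulate_titration
from quenchkit.sensing import stern_volmer_fit

grid = np.linspace(0, 1e-6, 10)          # quencher, M
spec = QuenchSimSpec(mechanism="dynamic_SV", seed=1,
                     ksv=6.52e6, i0=1000.0, noise_sd=10.0)
print(stern_volmer_fit(simulate_titration(spec, grid)).summary())
```

```
Stern-Volmer quenching fit: I0/I = intercept + Ksv*[Q]
  Ksv        6.34282e+06 M^-1  (se 1.16e+05)
  intercept  1.03734
  R^2        0.997344   n = 10
```

The planted constant of 6.52 × 10⁶ M⁻¹ is recovered within 3% from a
10-point titration carrying 1% intensity noise; the intercept stays within
its warning band of 1 and R² ≈ 0.997 confirms the linear (low-[Q]) regime.

The same round trip from the shell, for stoichiometry:

```sh
quenchkit simulate job --seed 1 --ka 1e6 --outdir sim/
quenchkit sense job sim/job.csv
```

```
Job's-plot (continuous variation) analysis
  x_max (host mole fraction)  0.5000
  host:guest ratio            1:1
  curve symmetry about 0.5    1.0000
```

A noiseless 1:1 equilibrium series (Ka = 10⁶ M⁻¹, C_total = 2 × 10⁻⁵ M)
peaks at mole fraction 0.5, i.e. a 1:1 probe–analyte complex — consistent
with hydrogen-bond-driven static quenching between the probe's amine and
the phenolic OH of picric acid.

Green metrics from a packaged reaction file
(`quenchkit greenmetrics src/quenchkit/data/reactions/4a.yaml`):

```
Compound    Yield%      AE     PMI      CE     RME  E-factor
4a            37.6    87.8   3.621    37.6    33.0     2.621
```

AE = 87.8% is intrinsic to the balanced condensation (2 aminoketone +
bis-dione → biacridine + 4 H₂O); the mass-based metrics reflect the masses
recorded in the file.

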