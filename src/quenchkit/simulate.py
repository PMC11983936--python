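"""Synthetic instrument data with known ground truth.

Everything the analysis modules consume can be generated here: Gaussian
band spectra, solvatochromic absorption/emission series, quenching
titrations (collisional Stern-Volmer or ground-state 1:1 complexation),
continuous-variation (Job) series driven by an exact binding-equilibrium
solver, and low-concentration calibrations with blank replicates for
detection-limit work.  Every generator takes an explicit seed and is
bit-reproducible; noise is additive i.i.d. Gaussian on the intensities.

The 1:1 host-guest equilibrium

    H + G <-> HG,   Ka = [HG] / ([H][G])

has the closed-form solution

    [HG] = ( (H0 + G0 + 1/Ka) - sqrt((H0 + G0 + 1/Ka)^2 - 4 H0 G0) ) / 2

evaluated here in the subtraction-free form 2ab/(s + sqrt(s^2 - 4ab)) to
avoid catastrophic cancellation at large Ka.  General m:n complexes are
solved by bracketed root finding on the mass balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .sensing import JobSeries, TitrationSeries
from .spectra import Spectrum

__all__ = [
    "BandSpec",
    "BindingSimSpec",
    "QuenchSimSpec",
    "SimulationError",
    "solve_equilibrium_1_1",
    "solve_equilibrium_m_n",
    "simulate_spectrum",
    "simulate_solvatochromic_series",
    "simulate_titration",
    "simulate_job_series",
    "simulate_lod_calibration",
]


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# binding equilibria


def solve_equilibrium_1_1(h0: float, g0: float, ka: float) -> float:
    """Exact [HG] for a 1:1 complex; 0 <= [HG] <= min(H0, G0)."""
    if h0 < 0 or g0 < 0:
        raise SimulationError("total concentrations must be non-negative")
    if ka <= 0:
        raise SimulationError("Ka must be positive")
    if h0 == 0 or g0 == 0:
        return 0.0
    s = h0 + g0 + 1.0 / ka
    disc = s * s - 4.0 * h0 * g0
    disc = max(disc, 0.0)  # guard tiny negative from rounding
    c = 2.0 * h0 * g0 / (s + math.sqrt(disc))
    return min(c, h0, g0)


def solve_equilibrium_m_n(
    h0: float, g0: float, ka: float, m: int = 1, n: int = 1
) -> float:
    """[HmGn] from the mass balance Ka*(H0 - m c)^m (G0 - n c)^n = c,
    solved by Brent's method on [0, min(H0/m, G0/n)]."""
    if not (1 <= m <= 4 and 1 <= n <= 4):
        raise SimulationError("stoichiometric coefficients must be in 1..4")
    if h0 < 0 or g0 < 0:
        raise SimulationError("total concentrations must be non-negative")
    if ka <= 0:
        raise SimulationError("Ka must be positive")
    if h0 == 0 or g0 == 0:
        return 0.0
    c_max = min(h0 / m, g0 / n)

    def f(c: float) -> float:
        return ka * (h0 - m * c) ** m * (g0 - n * c) ** n - c

    lo, hi = 0.0, c_max
    if f(lo) < 0:
        return 0.0  # only possible at c = 0 within rounding
    if f(hi) > 0:
        raise SimulationError(
            f"no sign change on bracket [0, {c_max:g}]: f(lo)={f(lo):g}, f(hi)={f(hi):g}"
        )
    return float(brentq(f, lo, hi, xtol=c_max * 1e-15 + 1e-300, rtol=8.9e-16))


# --------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian band: center (nm), width sigma (nm), amplitude (a.u.)."""

    center_nm: float
    width_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise SimulationError("band width must be positive")
        if self.amplitude < 0:
            raise SimulationError("band amplitude must be non-negative")


def simulate_spectrum(
    bands,
    grid: tuple[float, float, float],
    *,
    kind: str = "absorption",
    noise_sd: float = 0.0,
    seed: int = 0,
    solvent: str = "",
    concentration_M: float | None = None,
    path_length_cm: float = 1.0,
    excitation_nm: float | None = None,
) -> Spectrum:
    """Sum of Gaussian bands on a regular grid plus seeded Gaussian noise."""
    lo, hi, step = grid
    if step <= 0 or hi <= lo:
        raise SimulationError("grid must be (min, max, step) with step > 0, max > min")
    wl = np.arange(lo, hi + step / 2, step)
    signal = np.zeros_like(wl)
    for band in bands:
        signal += band.amplitude * np.exp(
            -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=wl.size)
    return Spectrum(
        wavelengths=wl,
        signal=signal,
        kind=kind,
        solvent=solvent,
        concentration_M=concentration_M,
        path_length_cm=path_length_cm,
        excitation_nm=excitation_nm,
    )


def simulate_solvatochromic_series(
    base_abs_nm,
    base_em_nm: float,
    shifts: dict,
    *,
    abs_amplitudes: dict | None = None,
    abs_width_nm: float = 10.0,
    em_width_nm: float = 18.0,
    concentration_M: float = 1e-5,
    path_length_cm: float = 1.0,
    excitation_nm: float | None = None,
    abs_grid: tuple[float, float, float] = (220.0, 420.0, 0.2),
    em_grid: tuple[float, float, float] = (380.0, 560.0, 0.2),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[Spectrum, Spectrum]]:
    """Absorption/emission spectrum pairs across solvents.

    ``shifts`` maps a solvent name to ``(abs_shift, em_shift)`` where
    ``abs_shift`` is a scalar applied to every base absorption center or a
    per-band sequence.  ``abs_amplitudes`` optionally gives per-band
    absorbance amplitudes per solvent (e.g. to encode a target molar
    absorptivity via A = eps*c*l); the default is unit amplitude per band.
    """
    base_abs_nm = list(base_abs_nm)
    out = []
    for k, (solvent, (abs_shift, em_shift)) in enumerate(shifts.items()):
        offsets = (
            [float(abs_shift)] * len(base_abs_nm)
            if np.isscalar(abs_shift)
            else [float(v) for v in abs_shift]
        )
        if len(offsets) != len(base_abs_nm):
            raise SimulationError(
                f"solvent {solvent!r}: {len(offsets)} absorption shifts for "
                f"{len(base_abs_nm)} bands"
            )
        amps = (
            [1.0] * len(base_abs_nm)
            if abs_amplitudes is None
            else list(abs_amplitudes[solvent])
        )
        abs_bands = [
            BandSpec(center_nm=c + d, width_nm=abs_width_nm, amplitude=a)
            for c, d, a in zip(base_abs_nm, offsets, amps)
        ]
        em_bands = [
            BandSpec(center_nm=base_em_nm + float(em_shift), width_nm=em_width_nm)
        ]
        absorption = simulate_spectrum(
            abs_bands,
            abs_grid,
            kind="absorption",
            noise_sd=noise_sd,
            seed=seed + 2 * k,
            solvent=solvent,
            concentration_M=concentration_M,
            path_length_cm=path_length_cm,
        )
        emission = simulate_spectrum(
            em_bands,
            em_grid,
            kind="emission",
            noise_sd=noise_sd,
            seed=seed + 2 * k + 1,
            solvent=solvent,
            excitation_nm=excitation_nm,
        )
        out.append((absorption, emission))
    return out


# --------------------------------------------------------------------------
# quenching titrations


@dataclass
class QuenchSimSpec:
    """Quenching model for a simulated titration.

    ``mechanism="dynamic_SV"`` uses I = I0 / (1 + Ksv*[Q]); ``"static_complex"``
    forms a fully dark 1:1 probe-analyte complex, I = I0*(1 - [HG]/H0), with
    [HG] from the exact equilibrium solver and H0 the probe concentration.
    """

    mechanism: str
    seed: int
    ksv: float | None = None
    ka: float | None = None
    i0: float = 1000.0
    probe_conc_M: float = 1e-5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism == "dynamic_SV":
            if self.ksv is None or self.ka is not None:
                raise SimulationError("dynamic_SV takes ksv only")
        elif self.mechanism == "static_complex":
            if self.ka is None or self.ksv is not None:
                raise SimulationError("static_complex takes ka only")
        else:
            raise SimulationError(f"unknown mechanism {self.mechanism!r}")
        if self.i0 <= 0:
            raise SimulationError("I0 must be positive")


def simulate_titration(spec: QuenchSimSpec, conc_grid) -> TitrationSeries:
    """Noise-seeded quenching titration on the given concentration grid."""
    q = np.asarray(conc_grid, dtype=float)
    if np.any(q < 0) or np.any(np.diff(q) < 0):
        raise SimulationError("concentration grid must be non-negative, increasing")
    if spec.mechanism == "dynamic_SV":
        intensity = spec.i0 / (1.0 + spec.ksv * q)
    else:
        bound = np.array(
            [solve_equilibrium_1_1(spec.probe_conc_M, g, spec.ka) for g in q]
        )
        intensity = spec.i0 * (1.0 - bound / spec.probe_conc_M)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=q.size)
    return TitrationSeries(
        conc_M=q,
        intensity=intensity,
        i0=spec.i0,
        probe_conc_M=spec.probe_conc_M,
    )


# --------------------------------------------------------------------------
# Job series


@dataclass
class BindingSimSpec:
    """Ground truth for a continuous-variation experiment."""

    ka: float
    seed: int
    stoichiometry: tuple[int, int] = (1, 1)
    c_total_M: float = 2e-5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        m, n = self.stoichiometry
        if not (1 <= m <= 4 and 1 <= n <= 4):
            raise SimulationError("stoichiometry components must be in 1..4")
        if self.ka <= 0 or self.c_total_M <= 0:
            raise SimulationError("Ka and C_total must be positive")


def simulate_job_series(spec: BindingSimSpec, n_points: int = 11) -> JobSeries:
    """Continuous-variation series: host mole fraction x on an even grid in
    (0, 1) (exact 0 and 1 excluded), H0 = x*C_total, G0 = (1-x)*C_total,
    signal proportional to the complex concentration."""
    if n_points < 5:
        raise SimulationError("need >= 5 points")
    m, n = spec.stoichiometry
    x = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    signal = np.array(
        [
            solve_equilibrium_m_n(xi * spec.c_total_M, (1 - xi) * spec.c_total_M, spec.ka, m, n)
            for xi in x
        ]
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=x.size)
    return JobSeries(mole_fraction=x, signal=signal, c_total_M=spec.c_total_M)


# --------------------------------------------------------------------------
# LOD calibrations


def simulate_lod_calibration(
    slope: float,
    sigma_blank: float,
    *,
    n_points: int = 8,
    n_blanks: int = 10,
    seed: int = 0,
    intercept: float = 100.0,
    conc_max_M: float | None = None,
) -> tuple[TitrationSeries, np.ndarray]:
    """Linear low-concentration calibration plus blank replicates.

    The calibration spans [0, conc_max]; the default span puts the top
    standard at 50*sigma_blank/|slope| (a comfortably quantifiable signal),
    falling back to 1e-8 M when sigma_blank is 0.  Blanks are drawn from
    the same Gaussian noise model at zero concentration.
    """
    if n_blanks < 3:
        raise SimulationError("need >= 3 blank replicates")
    if n_points < 3:
        raise SimulationError("need >= 3 calibration points")
    if slope == 0:
        raise SimulationError("slope must be nonzero")
    if sigma_blank < 0:
        raise SimulationError("sigma_blank must be non-negative")
    if conc_max_M is None:
        conc_max_M = 50.0 * sigma_blank / abs(slope) if sigma_blank > 0 else 1e-8
    conc = np.linspace(0.0, conc_max_M, n_points)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_blank, size=n_points) if sigma_blank > 0 else 0.0
    intensity = intercept + slope * conc + noise
    blank_noise = (
        rng.normal(0.0, sigma_blank, size=n_blanks) if sigma_blank > 0 else np.zeros(n_blanks)
    )
    blanks = intercept + blank_noise
    series = TitrationSeries(conc_M=conc, intensity=intensity, i0=float(intercept))
    return series, blanks
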