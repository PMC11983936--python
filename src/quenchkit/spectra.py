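"""Absorption/emission spectra and photophysical quantities.

A :class:`Spectrum` is a wavelength-gridded trace (nm, a.u.) with solvent,
concentration and path-length metadata.  From pairs of absorption and
emission spectra recorded in a series of solvents, this module extracts the
quantities a photophysical characterization table reports: band maxima
(lambda_max), the Beer-Lambert molar absorptivity epsilon = A/(c*l), the
Stokes shift Delta_nu = 1e7 * (1/lambda_abs - 1/lambda_em) in cm^-1, and
solvatochromic (bathochromic) shift ranges across solvents.

Peak positions are refined by fitting a parabola through the three samples
around each discrete maximum; for a symmetric band on a regular grid this
recovers the true center to far better than the grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

__all__ = [
    "Spectrum",
    "Peak",
    "SpectrumError",
    "find_peaks",
    "stokes_shift",
    "molar_absorptivity",
    "absorbance",
    "photophysics_table",
    "bathochromic_range",
    "normalize",
]


class SpectrumError(ValueError):
    """Invalid spectrum data or a degenerate photophysical computation."""


@dataclass
class Spectrum:
    """A single absorption or emission trace on a strictly increasing grid."""

    wavelengths: np.ndarray
    signal: np.ndarray
    kind: str  # "absorption" | "emission"
    solvent: str = ""
    concentration_M: float | None = None
    path_length_cm: float = 1.0
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.kind not in ("absorption", "emission"):
            raise SpectrumError(f"kind must be absorption/emission, got {self.kind!r}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 3:
            raise SpectrumError("need a 1-d wavelength grid with >= 3 points")
        if self.signal.shape != self.wavelengths.shape:
            raise SpectrumError("wavelengths and signal must have the same length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.any(self.wavelengths < 0):
            raise SpectrumError("negative wavelengths")
        if not np.all(np.isfinite(self.signal)):
            raise SpectrumError("non-finite signal values")
        if self.concentration_M is not None and self.concentration_M <= 0:
            raise SpectrumError("concentration must be positive")
        if self.path_length_cm <= 0:
            raise SpectrumError("path length must be positive")


@dataclass(frozen=True)
class Peak:
    center_nm: float
    height: float
    prominence: float


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (interior i)."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i]), float(y[i])
    a, b, c = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a >= 0:  # not concave; keep the grid point
        return float(x[i]), float(y[i])
    xv = -b / (2 * a)
    lo, hi = x[i - 1], x[i + 1]
    xv = float(np.clip(xv, lo, hi))
    return xv, float(a * xv * xv + b * xv + c)


def find_peaks(s: Spectrum, min_prominence: float = 0.05) -> list[Peak]:
    """Local maxima with prominence >= ``min_prominence`` * max(signal),
    refined by 3-point parabolic interpolation, sorted by wavelength.

    A flat or monotone trace yields an empty list.
    """
    peak_scale = float(np.max(s.signal))
    if peak_scale <= 0 or np.ptp(s.signal) == 0:
        return []
    idx, props = _scipy_find_peaks(s.signal, prominence=min_prominence * peak_scale)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        center, height = _parabolic_refine(s.wavelengths, s.signal, int(i))
        peaks.append(Peak(center_nm=center, height=height, prominence=float(prom)))
    return sorted(peaks, key=lambda p: p.center_nm)


def stokes_shift(lambda_abs_nm: float, lambda_em_nm: float) -> float:
    """Stokes shift in cm^-1: 1e7 * (1/lambda_abs - 1/lambda_em).

    Positive when emission is red of absorption; antisymmetric in its
    arguments.
    """
    if lambda_abs_nm <= 0 or lambda_em_nm <= 0:
        raise SpectrumError("wavelengths must be positive")
    return 1e7 * (1.0 / lambda_abs_nm - 1.0 / lambda_em_nm)


def molar_absorptivity(absorbance_au: float, conc_M: float, path_cm: float) -> float:
    """Beer-Lambert epsilon = A / (c * l) in L mol^-1 cm^-1."""
    if conc_M <= 0 or path_cm <= 0:
        raise SpectrumError("concentration and path length must be positive")
    if absorbance_au < 0:
        raise SpectrumError("negative absorbance")
    return absorbance_au / (conc_M * path_cm)


def absorbance(epsilon: float, conc_M: float, path_cm: float) -> float:
    """Inverse of :func:`molar_absorptivity`: A = epsilon * c * l."""
    return epsilon * conc_M * path_cm


def normalize(s: Spectrum) -> Spectrum:
    """Scale the signal so its maximum is 1; idempotent and peak-preserving."""
    peak = float(np.max(s.signal))
    if peak <= 0:
        raise SpectrumError("cannot normalize a spectrum with max signal <= 0")
    return replace(s, signal=s.signal / peak)


@dataclass
class PhotophysRow:
    """One solvent's entry in a photophysical characterization table."""

    solvent: str
    lambda_abs_nm: list[float] = field(default_factory=list)
    lambda_em_nm: float | None = None
    epsilon: float | None = None
    stokes_shift_cm1: float | None = None
    flags: list[str] = field(default_factory=list)


def photophysics_table(
    series: Iterable[tuple[Spectrum, Spectrum]],
    band: str = "shortest",
    min_prominence: float = 0.05,
) -> pd.DataFrame:
    """Per-solvent lambda_abs list, lambda_em, epsilon and Stokes shift.

    ``band`` selects which absorption maximum is paired with the emission
    maximum for the Stokes shift and epsilon: ``"shortest"`` (the
    high-energy pi-pi* band, the pairing that reproduces typical printed
    Stokes-shift tables) or ``"longest"`` (the low-energy n-pi* band).
    """
    if band not in ("shortest", "longest"):
        raise SpectrumError("band must be 'shortest' or 'longest'")
    rows: list[PhotophysRow] = []
    for absorption, emission in series:
        if absorption.kind != "absorption" or emission.kind != "emission":
            raise SpectrumError("each pair must be (absorption, emission)")
        row = PhotophysRow(solvent=absorption.solvent)
        if absorption.solvent != emission.solvent:
            row.flags.append(
                f"solvent mismatch: {absorption.solvent!r} vs {emission.solvent!r}"
            )
        abs_peaks = find_peaks(absorption, min_prominence)
        em_peaks = find_peaks(emission, min_prominence)
        row.lambda_abs_nm = [p.center_nm for p in abs_peaks]
        if not abs_peaks:
            row.flags.append("no absorption maxima found")
        if em_peaks:
            # highest emission peak; ties broken toward longer wavelength
            best = max(em_peaks, key=lambda p: (p.height, p.center_nm))
            row.lambda_em_nm = best.center_nm
        else:
            row.flags.append("no emission maximum found")
        if abs_peaks and row.lambda_em_nm is not None:
            chosen = abs_peaks[0] if band == "shortest" else abs_peaks[-1]
            row.stokes_shift_cm1 = stokes_shift(chosen.center_nm, row.lambda_em_nm)
            if row.stokes_shift_cm1 < 0:
                row.flags.append("emission blue of absorption: negative Stokes shift")
            if absorption.concentration_M is not None:
                row.epsilon = molar_absorptivity(
                    chosen.height, absorption.concentration_M, absorption.path_length_cm
                )
        rows.append(row)
    return pd.DataFrame(
        {
            "solvent": [r.solvent for r in rows],
            "lambda_abs_nm": [r.lambda_abs_nm for r in rows],
            "lambda_em_nm": [r.lambda_em_nm for r in rows],
            "epsilon": [r.epsilon for r in rows],
            "stokes_shift_cm1": [r.stokes_shift_cm1 for r in rows],
            "flags": [r.flags for r in rows],
        }
    )


def bathochromic_range(
    table: pd.DataFrame | Sequence[PhotophysRow], which: str = "emission"
) -> float:
    """Solvatochromic range in nm: max - min of the selected wavelength.

    ``which`` is ``"emission"`` or ``"absorption_longest"`` (the red-most
    absorption band per solvent).
    """
    if not isinstance(table, pd.DataFrame):
        table = photophys_rows_to_frame(table)
    if len(table) < 2:
        raise SpectrumError("need at least two solvents for a shift range")
    if which == "emission":
        values = table["lambda_em_nm"].astype(float).to_numpy()
    elif which == "absorption_longest":
        values = np.array(
            [max(lams) if lams else np.nan for lams in table["lambda_abs_nm"]]
        )
    else:
        raise SpectrumError("which must be 'emission' or 'absorption_longest'")
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise SpectrumError("fewer than two usable wavelengths")
    return float(values.max() - values.min())


def photophys_rows_to_frame(rows: Sequence[PhotophysRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "solvent": [r.solvent for r in rows],
            "lambda_abs_nm": [r.lambda_abs_nm for r in rows],
            "lambda_em_nm": [r.lambda_em_nm for r in rows],
            "epsilon": [r.epsilon for r in rows],
            "stokes_shift_cm1": [r.stokes_shift_cm1 for r in rows],
            "flags": [r.flags for r in rows],
        }
    )
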