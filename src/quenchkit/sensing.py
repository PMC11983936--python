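"""Turn-off fluorescence sensing analytics.

The fitting core follows the model/results idiom: a model object is built
from data, ``.fit()`` returns a results object carrying the estimates,
their uncertainties and diagnostics, and ``.summary()`` prints a small
table.  Three models are provided:

``SternVolmer``
    Quenching titration fit of I0/I against quencher concentration [Q],
    I0/I = 1 + Ksv*[Q].  Static (ground-state complex) and dynamic
    (collisional) quenching both give this linear form at low [Q], so the
    slope Ksv is reported without asserting a mechanism.

``LODCalibration``
    Low-concentration linear calibration plus blank replicates; the
    detection limit is LOD = 3*sigma_blank / |slope|.

``JobPlot``
    Continuous-variation (Job) analysis: the mole fraction at the signal
    maximum reveals the host:guest binding stoichiometry (0.5 -> 1:1).

Scalar helpers (quenching efficiency, selectivity panel, reversibility
index) round out the sensing workflow.  Functional wrappers
(:func:`stern_volmer_fit`, :func:`detection_limit`, :func:`job_analyze`)
expose the same fits as plain calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "JobSeries",
    "SternVolmer",
    "SternVolmerResults",
    "LODCalibration",
    "LODResults",
    "JobPlot",
    "JobResults",
    "SelectivityPanel",
    "ReversibilityResult",
    "DomainError",
    "FitError",
    "stern_volmer_fit",
    "detection_limit",
    "job_analyze",
    "quenching_efficiency",
    "selectivity_panel",
    "reversibility_index",
    "dilution_corrected_conc",
]


class DomainError(ValueError):
    """Input data violate a physical precondition (e.g. I <= 0)."""


class FitError(RuntimeError):
    """A fit cannot be carried out (too few points, zero slope, ...)."""


# --------------------------------------------------------------------------
# data containers


@dataclass
class TitrationSeries:
    """Quencher concentration vs emission intensity at a fixed wavelength."""

    conc_M: np.ndarray
    intensity: np.ndarray
    i0: float | None = None
    probe_conc_M: float | None = None
    emission_nm: float | None = None
    excitation_nm: float | None = None
    analyte: str = ""

    def __post_init__(self) -> None:
        self.conc_M = np.asarray(self.conc_M, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.conc_M.shape != self.intensity.shape or self.conc_M.ndim != 1:
            raise DomainError("conc and intensity must be equal-length 1-d arrays")
        if np.any(self.conc_M < 0):
            raise DomainError("negative quencher concentrations")
        if np.any(np.diff(self.conc_M) < 0):
            raise DomainError("concentrations must be non-decreasing")
        if self.i0 is None:
            if self.conc_M[0] == 0:
                self.i0 = float(self.intensity[0])
            else:
                raise DomainError(
                    "i0 not given and the series has no zero-concentration point"
                )
        if self.i0 <= 0:
            raise DomainError("I0 must be positive")


@dataclass
class JobSeries:
    """Continuous-variation series: host mole fraction vs signal at fixed
    total concentration."""

    mole_fraction: np.ndarray
    signal: np.ndarray
    c_total_M: float | None = None

    def __post_init__(self) -> None:
        self.mole_fraction = np.asarray(self.mole_fraction, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mole_fraction.shape != self.signal.shape or self.mole_fraction.ndim != 1:
            raise DomainError("mole_fraction and signal must be equal-length 1-d arrays")
        if np.any((self.mole_fraction < 0) | (self.mole_fraction > 1)):
            raise DomainError("mole fractions must lie in [0, 1]")
        if self.mole_fraction.size < 5:
            raise DomainError("need >= 5 mole fractions")
        order = np.argsort(self.mole_fraction)
        self.mole_fraction = self.mole_fraction[order]
        self.signal = self.signal[order]


# --------------------------------------------------------------------------
# Stern-Volmer


class SternVolmer:
    """Stern-Volmer quenching model I0/I = intercept + Ksv*[Q].

    Parameters
    ----------
    conc_M, intensity : arrays of quencher concentration and intensity
    i0 : intensity without quencher (taken from a zero-conc point if absent)
    fix_intercept : force the theoretical intercept of 1, fitting
        (I0/I - 1) = Ksv*[Q] through the origin
    mask : boolean array selecting the points to fit (e.g. the low-[Q]
        linear regime)
    """

    def __init__(
        self,
        conc_M,
        intensity,
        i0: float | None = None,
        *,
        fix_intercept: bool = False,
        mask=None,
    ) -> None:
        self.series = TitrationSeries(conc_M, intensity, i0=i0)
        self.fix_intercept = fix_intercept
        n = self.series.conc_M.size
        self.mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
        if self.mask.shape != (n,):
            raise DomainError("mask length must match the series")
        q = self.series.conc_M[self.mask]
        i = self.series.intensity[self.mask]
        if np.unique(q).size < 3:
            raise FitError("need >= 3 distinct concentrations to fit")
        if np.any(i <= 0):
            raise DomainError("all intensities must be positive")
        self._q, self._y = q, self.series.i0 / i

    @classmethod
    def from_series(cls, t: TitrationSeries, **kwargs) -> "SternVolmer":
        return cls(t.conc_M, t.intensity, i0=t.i0, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df, conc_col: str = "conc_M", intensity_col: str = "intensity", **kwargs
    ) -> "SternVolmer":
        return cls(df[conc_col].to_numpy(), df[intensity_col].to_numpy(), **kwargs)

    def fit(self) -> "SternVolmerResults":
        q, y = self._q, self._y
        warnings: list[str] = []
        if self.fix_intercept:
            sxx = float(np.dot(q, q))
            ksv = float(np.dot(q, y - 1.0)) / sxx
            intercept = 1.0
            resid = (y - 1.0) - ksv * q
            dof = max(q.size - 1, 1)
            ksv_se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
            ss_tot = float(np.dot(y - 1.0, y - 1.0))
        else:
            lr = stats.linregress(q, y)
            ksv, intercept = float(lr.slope), float(lr.intercept)
            ksv_se = float(lr.stderr)
            resid = y - (intercept + ksv * q)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            if abs(intercept - 1.0) > 0.05:
                warnings.append(
                    f"intercept {intercept:.4g} deviates from 1 by > 0.05; "
                    "consider restricting to the low-concentration linear regime"
                )
        ss_res = float(np.dot(resid, resid))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        return SternVolmerResults(
            ksv=ksv,
            intercept=intercept,
            ksv_se=ksv_se,
            rsquared=rsq,
            n_points_used=int(q.size),
            linear_range_mask=self.mask.copy(),
            intercept_fixed=self.fix_intercept,
            warnings=warnings,
            model=self,
        )


@dataclass
class SternVolmerResults:
    ksv: float
    intercept: float
    ksv_se: float
    rsquared: float
    n_points_used: int
    linear_range_mask: np.ndarray
    intercept_fixed: bool
    warnings: list[str] = field(default_factory=list)
    model: SternVolmer | None = None

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching fit: I0/I = intercept + Ksv*[Q]",
            f"  Ksv        {self.ksv:.6g} M^-1  (se {self.ksv_se:.3g})",
            f"  intercept  {self.intercept:.6g}"
            + ("  (fixed)" if self.intercept_fixed else ""),
            f"  R^2        {self.rsquared:.6f}   n = {self.n_points_used}",
        ]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "Ksv_Minv": self.ksv,
            "Ksv_se": self.ksv_se,
            "intercept": self.intercept,
            "intercept_fixed": self.intercept_fixed,
            "r_squared": self.rsquared,
            "n_points_used": self.n_points_used,
            "warnings": list(self.warnings),
        }

    def plot(self, ax=None):
        """Stern-Volmer plot (I0/I vs [Q]) with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        q, y = self.model._q, self.model._y
        ax.plot(q, y, "o", label="data")
        grid = np.linspace(0, q.max(), 50)
        ax.plot(grid, self.intercept + self.ksv * grid, "-", label="fit")
        ax.set_xlabel("[Q] (M)")
        ax.set_ylabel("I0 / I")
        ax.legend()
        return ax


def stern_volmer_fit(
    t: TitrationSeries, fix_intercept: bool = False, range_mask=None
) -> SternVolmerResults:
    return SternVolmer.from_series(t, fix_intercept=fix_intercept, mask=range_mask).fit()


# --------------------------------------------------------------------------
# detection limit


class LODCalibration:
    """Linear calibration + blank replicates -> 3*sigma/slope detection limit.

    ``response`` selects the regressed variable: ``"intensity"`` (raw I vs
    concentration) or ``"delta_intensity"`` (I0 - I vs concentration).
    """

    def __init__(
        self,
        conc_M,
        intensity,
        blanks,
        *,
        i0: float | None = None,
        response: str = "intensity",
    ) -> None:
        self.series = TitrationSeries(conc_M, intensity, i0=i0)
        self.blanks = np.asarray(blanks, dtype=float)
        if self.blanks.ndim != 1 or self.blanks.size < 3:
            raise DomainError("need >= 3 blank replicates")
        if self.series.conc_M.size < 3:
            raise FitError("need >= 3 calibration points")
        if response not in ("intensity", "delta_intensity"):
            raise DomainError("response must be 'intensity' or 'delta_intensity'")
        self.response = response

    @classmethod
    def from_series(cls, t: TitrationSeries, blanks, **kwargs) -> "LODCalibration":
        return cls(t.conc_M, t.intensity, blanks, i0=t.i0, **kwargs)

    def fit(self) -> "LODResults":
        y = (
            self.series.intensity
            if self.response == "intensity"
            else self.series.i0 - self.series.intensity
        )
        lr = stats.linregress(self.series.conc_M, y)
        slope = float(lr.slope)
        if slope == 0:
            raise FitError("zero calibration slope: LOD undefined")
        sigma = float(np.std(self.blanks, ddof=1))
        return LODResults(
            slope=slope,
            intercept=float(lr.intercept),
            sigma_blank=sigma,
            lod_M=3.0 * sigma / abs(slope),
            rsquared=float(lr.rvalue) ** 2,
            n_blanks=int(self.blanks.size),
            response=self.response,
        )


@dataclass
class LODResults:
    slope: float
    intercept: float
    sigma_blank: float
    lod_M: float
    rsquared: float
    n_blanks: int
    response: str

    def summary(self) -> str:
        return "\n".join(
            [
                "Detection-limit calibration: LOD = 3*sigma_blank / |slope|",
                f"  slope        {self.slope:.6g} a.u./M  ({self.response})",
                f"  sigma_blank  {self.sigma_blank:.6g} a.u.  (n = {self.n_blanks}, ddof=1)",
                f"  LOD          {self.lod_M:.6g} M",
                f"  R^2          {self.rsquared:.6f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "sigma_blank": self.sigma_blank,
            "lod_M": self.lod_M,
            "r_squared": self.rsquared,
            "n_blanks": self.n_blanks,
            "response": self.response,
        }


def detection_limit(
    calibration: TitrationSeries, blanks, response: str = "intensity"
) -> LODResults:
    return LODCalibration.from_series(calibration, blanks, response=response).fit()


# --------------------------------------------------------------------------
# Job's plot


class JobPlot:
    """Continuous-variation stoichiometry analysis.

    The discrete signal maximum is refined by a parabola through its three
    neighbours; the host:guest ratio is the small-integer rounding of
    (1 - x_max)/x_max, reported only for components <= 4 (the method is
    unreliable beyond that).
    """

    MAX_RATIO = 4

    def __init__(self, mole_fraction, signal, *, baseline_correction: bool = False):
        self.series = JobSeries(mole_fraction, signal)
        self.baseline_correction = baseline_correction

    @classmethod
    def from_series(cls, j: JobSeries, **kwargs) -> "JobPlot":
        return cls(j.mole_fraction, j.signal, **kwargs)

    def fit(self) -> "JobResults":
        x = self.series.mole_fraction
        y = self.series.signal.astype(float).copy()
        if self.baseline_correction:
            # remove the straight line through the endpoints
            y = y - (y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0]))
        i = int(np.argmax(y))
        inconclusive = i == 0 or i == x.size - 1
        if inconclusive:
            x_max, y_max = float(x[i]), float(y[i])
        else:
            a, b, c = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
            if a < 0:
                x_max = float(np.clip(-b / (2 * a), x[i - 1], x[i + 1]))
                y_max = float(a * x_max**2 + b * x_max + c)
            else:
                x_max, y_max = float(x[i]), float(y[i])
        ratio = None
        if not inconclusive and 0 < x_max < 1:
            r = (1.0 - x_max) / x_max
            if r >= 1.0:
                n = round(r)
                ratio = (1, n) if 1 <= n <= self.MAX_RATIO else None
            else:
                m = round(1.0 / r)
                ratio = (m, 1) if 1 <= m <= self.MAX_RATIO else None
        if ratio is None:
            inconclusive = True
        # symmetry about x = 0.5 via interpolation onto mirrored abscissae
        mirrored = np.interp(1.0 - x, x, y)
        scale = float(np.max(np.abs(y)))
        symmetry = 1.0 - float(np.mean(np.abs(y - mirrored))) / scale if scale > 0 else 1.0
        return JobResults(
            x_max=x_max,
            signal_max=y_max,
            ratio=ratio,
            symmetry=symmetry,
            inconclusive=inconclusive,
        )


@dataclass
class JobResults:
    x_max: float
    signal_max: float
    ratio: tuple[int, int] | None
    symmetry: float
    inconclusive: bool

    @property
    def ratio_label(self) -> str:
        return "inconclusive" if self.ratio is None else f"{self.ratio[0]}:{self.ratio[1]}"

    def summary(self) -> str:
        return "\n".join(
            [
                "Job's-plot (continuous variation) analysis",
                f"  x_max (host mole fraction)  {self.x_max:.4f}",
                f"  host:guest ratio            {self.ratio_label}",
                f"  curve symmetry about 0.5    {self.symmetry:.4f}",
            ]
            + (["  warning: maximum at the edge of the sampled range"] if self.inconclusive else [])
        )

    def to_dict(self) -> dict:
        return {
            "x_max": self.x_max,
            "ratio": self.ratio_label,
            "symmetry": self.symmetry,
            "inconclusive": self.inconclusive,
        }


def job_analyze(j: JobSeries, baseline_correction: bool = False) -> JobResults:
    return JobPlot.from_series(j, baseline_correction=baseline_correction).fit()


# --------------------------------------------------------------------------
# scalar sensing helpers


def quenching_efficiency(i0: float, i: float) -> float:
    """Percent quenching 100*(1 - I/I0); negative values mean enhancement."""
    if i0 <= 0:
        raise DomainError("I0 must be positive")
    if i < 0:
        raise DomainError("I must be non-negative")
    return 100.0 * (1.0 - i / i0)


@dataclass
class SelectivityPanel:
    """Relative responses (1 - I/I0) per analyte, with the strongest flagged."""

    responses: dict[str, float]
    flagged: str | None
    selective: bool
    interference: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "responses": dict(self.responses),
            "flagged": self.flagged,
            "selective": self.selective,
            "interference": dict(self.interference),
        }


def selectivity_panel(
    probe_i0: float,
    intensities: Mapping[str, float],
    interference: Mapping[str, tuple[float, float]] | None = None,
) -> SelectivityPanel:
    """Relative quenching response of each analyte against the free probe.

    ``interference`` maps a competitor name to the pair of intensities
    (probe+competitor, probe+competitor+target); the retained target
    response in the competitor's presence is reported per competitor.
    The analyte with the maximal positive response is flagged; it is called
    selective when its response is at least 0.5 and at least 3x the runner-up.
    """
    if probe_i0 <= 0:
        raise DomainError("I0 must be positive")
    if not intensities:
        raise DomainError("empty analyte panel")
    responses = {name: 1.0 - i / probe_i0 for name, i in intensities.items()}
    ordered = sorted(responses.items(), key=lambda kv: kv[1], reverse=True)
    flagged = ordered[0][0] if ordered[0][1] > 0 else None
    runner_up = ordered[1][1] if len(ordered) > 1 else 0.0
    selective = (
        flagged is not None
        and ordered[0][1] >= 0.5
        and (runner_up <= 0 or ordered[0][1] >= 3 * runner_up)
    )
    interf = {}
    if interference:
        for name, (i_comp, i_comp_target) in interference.items():
            if i_comp <= 0:
                raise DomainError(f"non-positive intensity for competitor {name!r}")
            interf[name] = 1.0 - i_comp_target / i_comp
    return SelectivityPanel(
        responses=responses, flagged=flagged, selective=selective, interference=interf
    )


@dataclass
class ReversibilityResult:
    fraction: float  # clipped to [0, 1]
    raw: float

    def summary(self) -> str:
        return f"Reversibility: {100 * self.fraction:.1f}% of the quenched intensity recovered"


def reversibility_index(
    i_probe: float, i_quenched: float, i_recovered: float
) -> ReversibilityResult:
    """Fraction of the quenched intensity regained after the release agent.

    (I_recovered - I_quenched) / (I_probe - I_quenched), reported clipped to
    [0, 1] with the raw value retained.
    """
    if i_probe <= 0:
        raise DomainError("probe intensity must be positive")
    if i_quenched > i_probe:
        raise DomainError("quenched intensity exceeds the probe intensity")
    if i_probe == i_quenched:
        raise DomainError("no quenching occurred; reversibility undefined")
    raw = (i_recovered - i_quenched) / (i_probe - i_quenched)
    return ReversibilityResult(fraction=float(np.clip(raw, 0.0, 1.0)), raw=float(raw))


def dilution_corrected_conc(
    v_added_uL, c_stock_M: float, v_initial_mL: float
) -> np.ndarray:
    """Cuvette concentration for microliter spikes into an initial volume:
    [Q] = V_added * C_stock / (V_initial + V_added)."""
    v_added_uL = np.asarray(v_added_uL, dtype=float)
    if c_stock_M <= 0 or v_initial_mL <= 0:
        raise DomainError("stock concentration and initial volume must be positive")
    v_added_mL = v_added_uL / 1000.0
    return v_added_mL * c_stock_M / (v_initial_mL + v_added_mL)
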