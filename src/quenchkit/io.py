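"""CSV / YAML round-tripping for spectra, titrations, Job series and
reaction specifications.

Spectrum CSV: header ``wavelength_nm,signal`` with metadata as leading
``# key: value`` comment lines.  Titration CSV: ``conc_M,intensity`` (plus
``# i0: ...`` etc.).  Job CSV: ``mole_fraction,signal``.  Blanks: a
one-column ``intensity`` CSV.  Reaction specs are YAML with ``reactants``,
``auxiliaries``, ``product`` and optional ``byproducts`` blocks.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .greenmetrics import ReactionSpec, Species, SpecificationError
from .sensing import JobSeries, TitrationSeries
from .spectra import Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_job_csv",
    "write_job_csv",
    "read_blanks_csv",
    "write_blanks_csv",
    "read_reaction_yaml",
]


def _read_comment_metadata(path: Path) -> tuple[dict, str]:
    meta: dict[str, str] = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _maybe_float(meta: dict, key: str) -> float | None:
    value = meta.get(key)
    return None if value in (None, "", "None") else float(value)


def write_spectrum_csv(s: Spectrum, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {s.kind}\n")
        fh.write(f"# solvent: {s.solvent}\n")
        if s.concentration_M is not None:
            fh.write(f"# concentration_M: {s.concentration_M!r}\n")
        fh.write(f"# path_length_cm: {s.path_length_cm!r}\n")
        if s.excitation_nm is not None:
            fh.write(f"# excitation_nm: {s.excitation_nm!r}\n")
        pd.DataFrame(
            {"wavelength_nm": s.wavelengths, "signal": s.signal}
        ).to_csv(fh, index=False)


def read_spectrum_csv(path) -> Spectrum:
    meta, body = _read_comment_metadata(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    return Spectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        signal=df["signal"].to_numpy(),
        kind=meta.get("kind", "absorption"),
        solvent=meta.get("solvent", ""),
        concentration_M=_maybe_float(meta, "concentration_M"),
        path_length_cm=_maybe_float(meta, "path_length_cm") or 1.0,
        excitation_nm=_maybe_float(meta, "excitation_nm"),
    )


def write_titration_csv(t: TitrationSeries, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(f"# i0: {t.i0!r}\n")
        if t.probe_conc_M is not None:
            fh.write(f"# probe_conc_M: {t.probe_conc_M!r}\n")
        if t.analyte:
            fh.write(f"# analyte: {t.analyte}\n")
        pd.DataFrame({"conc_M": t.conc_M, "intensity": t.intensity}).to_csv(
            fh, index=False
        )


def read_titration_csv(path) -> TitrationSeries:
    meta, body = _read_comment_metadata(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    return TitrationSeries(
        conc_M=df["conc_M"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        i0=_maybe_float(meta, "i0"),
        probe_conc_M=_maybe_float(meta, "probe_conc_M"),
        analyte=meta.get("analyte", ""),
    )


def write_job_csv(j: JobSeries, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        if j.c_total_M is not None:
            fh.write(f"# c_total_M: {j.c_total_M!r}\n")
        pd.DataFrame(
            {"mole_fraction": j.mole_fraction, "signal": j.signal}
        ).to_csv(fh, index=False)


def read_job_csv(path) -> JobSeries:
    meta, body = _read_comment_metadata(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    return JobSeries(
        mole_fraction=df["mole_fraction"].to_numpy(),
        signal=df["signal"].to_numpy(),
        c_total_M=_maybe_float(meta, "c_total_M"),
    )


def write_blanks_csv(blanks, path) -> None:
    pd.DataFrame({"intensity": np.asarray(blanks, dtype=float)}).to_csv(
        Path(path), index=False
    )


def read_blanks_csv(path) -> np.ndarray:
    return pd.read_csv(Path(path), comment="#")["intensity"].to_numpy()


def _species_from_mapping(entry: dict, default_role: str) -> Species:
    if not isinstance(entry, dict) or "name" not in entry:
        raise SpecificationError(f"species entry must be a mapping with a name: {entry!r}")
    return Species(
        name=entry["name"],
        formula=entry.get("formula"),
        equivalents=float(entry.get("equivalents", 1.0)),
        mass_g=None if entry.get("mass_g") is None else float(entry["mass_g"]),
        role=entry.get("role", default_role),
    )


def read_reaction_yaml(path) -> ReactionSpec:
    """Load a reaction specification from YAML.

    Schema::

        name: 3a
        reactants:
          - {name: ..., formula: C13H11NO, equivalents: 1, mass_g: 0.5}
        auxiliaries:
          - {name: HCl, role: catalyst, mass_g: 0.59}
        product:
          formula: C25H25NO
          mass_g: 0.48        # optional
        byproducts: [H2O, H2O]  # optional; omitted -> water inferred
    """
    with open(Path(path), "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SpecificationError(f"{path}: reaction file must be a YAML mapping")
    try:
        reactants = [
            _species_from_mapping(e, "reactant") for e in raw.get("reactants", [])
        ]
        auxiliaries = [
            _species_from_mapping(e, "solvent") for e in raw.get("auxiliaries", [])
        ]
        product = raw["product"]
        byproducts = raw.get("byproducts")
        return ReactionSpec(
            reactants=reactants,
            auxiliaries=auxiliaries,
            product_formula=product["formula"],
            product_mass_g=(
                None if product.get("mass_g") is None else float(product["mass_g"])
            ),
            byproduct_formulas=byproducts,
            name=str(raw.get("name", Path(path).stem)),
        )
    except (KeyError, TypeError) as exc:
        raise SpecificationError(f"{path}: malformed reaction spec ({exc})") from exc
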