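"""Readers and writers for plain tabular spectrum files and titration manifests.

Spectrum files are two-column delimited text (wavelength, intensity), comma-
or tab-delimited (auto-detected), with optional ``#`` comment lines whose
``key=value`` tokens may carry ``lambda_ex_nm`` and ``temperature_K``.  EEM
files are matrix-form: the first row holds the emission grid, the first column
the excitation grid.  A titration manifest is a YAML document listing, per
point, either a spectrum file or a pre-extracted intensity, together with the
ligand concentration and the absorbances needed for inner-filter correction.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np
import yaml

from .datatypes import (
    DEFAULT_TAU0_S,
    EEM,
    AbsorbanceSpectrum,
    EmissionSpectrum,
    TitrationPoint,
    TitrationSeries,
)
from .errors import ParseError, ValidationError

_DELIMS = (",", "\t", ";")


def _split_row(line: str) -> list[str]:
    for d in _DELIMS:
        if d in line:
            return [tok.strip() for tok in line.split(d)]
    return line.split()


def _parse_header_metadata(lines: list[str]) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in lines:
        for tok in line.lstrip("#").replace(",", " ").split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    continue
    return meta


def _read_two_column(path: Union[str, os.PathLike]) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    wavelengths: list[float] = []
    values: list[float] = []
    header_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            toks = _split_row(line)
            if len(toks) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                wavelengths.append(float(toks[0]))
                values.append(float(toks[1]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric row {line!r}") from exc
    if not wavelengths:
        raise ParseError(f"{path}: no data rows found")
    return np.array(wavelengths), np.array(values), _parse_header_metadata(header_lines)


def read_spectrum(
    path: Union[str, os.PathLike],
    *,
    lambda_ex_nm: Optional[float] = None,
    temperature_K: Optional[float] = None,
) -> EmissionSpectrum:
    """Read an emission spectrum from a two-column delimited text file.

    Header metadata (``lambda_ex_nm``, ``temperature_K``) is taken from
    ``#`` comment lines when present; explicit keyword arguments override it.
    ``lambda_ex`` / ``temperature`` are accepted as header aliases.
    """
    w, inten, meta = _read_two_column(path)
    if lambda_ex_nm is None:
        lambda_ex_nm = meta.get("lambda_ex_nm", meta.get("lambda_ex"))
    if temperature_K is None:
        temperature_K = meta.get("temperature_K", meta.get("temperature"))
    if lambda_ex_nm is None or temperature_K is None:
        raise ParseError(
            f"{path}: lambda_ex_nm / temperature_K neither in header nor supplied by caller"
        )
    return EmissionSpectrum(w, inten, float(lambda_ex_nm), float(temperature_K))


def write_spectrum(spectrum: EmissionSpectrum, path: Union[str, os.PathLike], *, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# lambda_ex_nm={spectrum.lambda_ex_nm!r} temperature_K={spectrum.temperature_K!r}\n"
        )
        for w, i in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{float(w)!r}{delimiter}{float(i)!r}\n")


def read_absorbance_spectrum(path: Union[str, os.PathLike]) -> AbsorbanceSpectrum:
    """Read a UV-Vis absorbance scan (two-column text, negatives allowed)."""
    w, a, _ = _read_two_column(path)
    return AbsorbanceSpectrum(w, a)


def read_eem(path: Union[str, os.PathLike]) -> EEM:
    """Read a matrix-form EEM: first row = emission grid, first column = excitation grid."""
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_row(line)
            try:
                # the top-left cell of the header row may be a label
                if not rows and len(toks) >= 2:
                    try:
                        float(toks[0])
                    except ValueError:
                        toks = ["nan"] + toks[1:]
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric row {line!r}") from exc
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    width = len(rows[0])
    for k, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise ParseError(f"{path}: ragged row at data line {k}: {len(r)} fields, expected {width}")
    em = np.array(rows[0][1:], dtype=float)
    ex = np.array([r[0] for r in rows[1:]], dtype=float)
    mat = np.array([r[1:] for r in rows[1:]], dtype=float)
    return EEM(ex, em, mat)


def write_eem(eem: EEM, path: Union[str, os.PathLike], *, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ex/em" + delimiter + delimiter.join(repr(float(v)) for v in eem.em_nm) + "\n")
        for i, ex in enumerate(eem.ex_nm):
            fh.write(repr(float(ex)) + delimiter + delimiter.join(repr(float(v)) for v in eem.intensity[i]) + "\n")


def extract_F(
    spectrum: EmissionSpectrum,
    mode: str = "fixed-wavelength",
    lambda_nm: Optional[float] = None,
) -> float:
    """Extract the analysis intensity F from a spectrum.

    ``mode='peak-max'`` returns the maximum intensity on the grid;
    ``mode='fixed-wavelength'`` returns the intensity at the grid point
    nearest ``lambda_nm`` (which must lie within half a grid step of a node).
    """
    if mode == "peak-max":
        return float(np.max(spectrum.intensities))
    if mode != "fixed-wavelength":
        raise ValidationError(f"unknown extraction mode {mode!r}")
    if lambda_nm is None:
        raise ValidationError("fixed-wavelength extraction needs lambda_nm")
    w = spectrum.wavelengths_nm
    if not (w[0] <= lambda_nm <= w[-1]):
        raise ValidationError(f"lambda_nm={lambda_nm} outside emission grid [{w[0]}, {w[-1]}]")
    idx = int(np.argmin(np.abs(w - lambda_nm)))
    step = np.min(np.diff(w)) if w.size > 1 else np.inf
    if abs(w[idx] - lambda_nm) > step / 2 + 1e-9:
        raise ValidationError(f"lambda_nm={lambda_nm} is not within half a grid step of any grid point")
    return float(spectrum.intensities[idx])


# ---------------------------------------------------------------------------
# titration manifests
# ---------------------------------------------------------------------------

def read_manifest(path: Union[str, os.PathLike]) -> TitrationSeries:
    """Load a titration series from a YAML manifest.

    Schema (concentrations in mol/L, final cuvette values)::

        protein_conc_M: 1.5e-6
        temperature_K: 298.0
        tau0_s: 2.7e-9            # optional
        label: ACV-HSA            # optional
        analysis:                 # optional; defaults shown
          mode: fixed-wavelength  # or peak-max
          lambda_nm: 340.0        # default: peak of the zero-ligand spectrum
        absorbance: {A_ex: 0.1, A_em: 0.02}   # optional single pair, broadcast
        points:
          - {ligand_conc_M: 0.0, spectrum: p0.csv, A_ex: 0.0, A_em: 0.0}
          - {ligand_conc_M: 3.5e-6, F_obs: 912.3, A_ex: 0.012, A_em: 0.001}

    Each point supplies either ``spectrum`` (a file path, relative to the
    manifest) or a pre-extracted ``F_obs``.  When a point omits absorbances,
    the broadcast ``absorbance`` pair is used if present.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: manifest must be a mapping")
    for key in ("protein_conc_M", "temperature_K", "points"):
        if key not in doc:
            raise ParseError(f"{path}: manifest missing required key {key!r}")
    base = os.path.dirname(path)
    analysis = doc.get("analysis") or {}
    mode = analysis.get("mode", "fixed-wavelength")
    lambda_nm = analysis.get("lambda_nm")
    broadcast = doc.get("absorbance") or {}

    temperature_K = float(doc["temperature_K"])
    raw_points = doc["points"]
    if not isinstance(raw_points, list) or not raw_points:
        raise ParseError(f"{path}: 'points' must be a non-empty list")

    points: list[TitrationPoint] = []
    for k, entry in enumerate(raw_points):
        if not isinstance(entry, dict) or "ligand_conc_M" not in entry:
            raise ParseError(f"{path}: point {k} must be a mapping with 'ligand_conc_M'")
        if "F_obs" in entry:
            f_obs = float(entry["F_obs"])
        elif "spectrum" in entry:
            spec_path = os.path.join(base, entry["spectrum"])
            spec = read_spectrum(spec_path, temperature_K=temperature_K,
                                 lambda_ex_nm=entry.get("lambda_ex_nm"))
            if mode == "fixed-wavelength" and lambda_nm is None:
                # locate the analysis wavelength once, from the first spectrum
                lambda_nm = spec.peak_wavelength_nm
            f_obs = extract_F(spec, mode=mode, lambda_nm=lambda_nm)
        else:
            raise ParseError(f"{path}: point {k} supplies neither 'spectrum' nor 'F_obs'")
        a_ex = entry.get("A_ex", broadcast.get("A_ex"))
        a_em = entry.get("A_em", broadcast.get("A_em"))
        points.append(
            TitrationPoint(
                ligand_conc_M=float(entry["ligand_conc_M"]),
                F_obs=f_obs,
                A_ex=None if a_ex is None else float(a_ex),
                A_em=None if a_em is None else float(a_em),
            )
        )
    return TitrationSeries(
        protein_conc_M=float(doc["protein_conc_M"]),
        temperature_K=temperature_K,
        points=tuple(points),
        tau0_s=float(doc.get("tau0_s", DEFAULT_TAU0_S)),
        label=str(doc.get("label", "")),
    )


def write_manifest(
    series: TitrationSeries,
    path: Union[str, os.PathLike],
    *,
    analysis_lambda_nm: Optional[float] = None,
) -> None:
    """Write a titration series as a YAML manifest with inline intensities."""
    doc: dict = {
        "protein_conc_M": float(series.protein_conc_M),
        "temperature_K": float(series.temperature_K),
        "tau0_s": float(series.tau0_s),
        "points": [
            {
                "ligand_conc_M": float(p.ligand_conc_M),
                "F_obs": float(p.F_obs),
                **({"A_ex": float(p.A_ex)} if p.A_ex is not None else {}),
                **({"A_em": float(p.A_em)} if p.A_em is not None else {}),
            }
            for p in series.points
        ],
    }
    if series.label:
        doc["label"] = series.label
    if analysis_lambda_nm is not None:
        doc["analysis"] = {"mode": "fixed-wavelength", "lambda_nm": float(analysis_lambda_nm)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
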