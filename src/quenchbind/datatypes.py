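"""Core data containers for fluorescence titration analysis.

The central objects are :class:`EmissionSpectrum` (one scan at one titration
point), :class:`TitrationSeries` (a protein held at fixed concentration while
the ligand/quencher concentration is stepped up, at one temperature) and
:class:`EEM` (an excitation-emission intensity matrix).  All containers are
frozen dataclasses that validate their invariants on construction; arrays are
stored as read-only ``numpy`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Unquenched fluorescence lifetime of the single-Trp serum-albumin donor, in
#: seconds.  Used to convert a Stern-Volmer constant into a bimolecular
#: quenching rate constant.
DEFAULT_TAU0_S = 2.7e-9


def _as_readonly_float_array(x, name: str, ndim: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


def _require_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan: intensity versus emission wavelength.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing emission wavelength grid in nm.
    intensities : array-like
        Fluorescence intensities (arbitrary units), same length as the grid,
        non-negative.
    lambda_ex_nm : float
        Excitation wavelength in nm.
    temperature_K : float
        Absolute temperature of the measurement.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    lambda_ex_nm: float
    temperature_K: float

    def __post_init__(self) -> None:
        w = _as_readonly_float_array(self.wavelengths_nm, "wavelengths_nm")
        i = _as_readonly_float_array(self.intensities, "intensities")
        _require_strictly_increasing(w, "wavelengths_nm")
        if w.shape != i.shape:
            raise ValidationError(
                f"wavelengths ({w.size}) and intensities ({i.size}) differ in length"
            )
        if np.any(i < 0):
            raise ValidationError("intensities must be non-negative")
        if not (self.temperature_K > 0):
            raise ValidationError("temperature_K must be positive")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def peak_wavelength_nm(self) -> float:
        """Wavelength of the maximum intensity (grid resolution, no refinement)."""
        return float(self.wavelengths_nm[int(np.argmax(self.intensities))])


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A UV-Vis absorbance scan.  Values may be negative (difference spectra)."""

    wavelengths_nm: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        w = _as_readonly_float_array(self.wavelengths_nm, "wavelengths_nm")
        a = _as_readonly_float_array(self.absorbances, "absorbances")
        _require_strictly_increasing(w, "wavelengths_nm")
        if w.shape != a.shape:
            raise ValidationError("wavelengths and absorbances differ in length")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "absorbances", a)

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a quenching titration.

    ``F_obs`` is the intensity read at the analysis wavelength; ``F_corr`` is
    populated by the inner-filter correction and always satisfies
    ``F_corr >= F_obs`` because the decadic antilog factor is >= 1.
    ``A_ex``/``A_em`` are the solution absorbances at the excitation and
    emission wavelengths; ``None`` means "not measured".
    """

    ligand_conc_M: float
    F_obs: float
    A_ex: Optional[float] = None
    A_em: Optional[float] = None
    F_corr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ligand_conc_M < 0:
            raise ValidationError("ligand_conc_M must be >= 0")
        if self.F_obs < 0:
            raise ValidationError("F_obs must be >= 0")
        for name in ("A_ex", "A_em"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 (negative absorbance signals a mis-specified blank)")
        if self.F_corr is not None and self.F_corr < self.F_obs - 1e-12 * max(1.0, self.F_obs):
            raise ValidationError("F_corr must be >= F_obs")

    @property
    def has_absorbances(self) -> bool:
        return self.A_ex is not None and self.A_em is not None


@dataclass(frozen=True)
class TitrationSeries:
    """A full quenching titration at one temperature.

    The first point must be the ligand-free reference (``ligand_conc_M == 0``)
    whose corrected intensity defines F0; subsequent ligand concentrations must
    be strictly increasing.  ``corrected`` flags whether the inner-filter
    correction has been applied (fits refuse uncorrected series by default,
    and re-applying the correction is rejected).
    """

    protein_conc_M: float
    temperature_K: float
    points: tuple[TitrationPoint, ...]
    tau0_s: float = DEFAULT_TAU0_S
    corrected: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        if len(pts) < 2:
            raise ValidationError("a titration series needs the zero-ligand point plus >= 1 ligand point")
        if not (self.protein_conc_M > 0):
            raise ValidationError("protein_conc_M must be positive")
        if not (self.temperature_K > 0):
            raise ValidationError("temperature_K must be positive")
        if not (self.tau0_s > 0):
            raise ValidationError("tau0_s must be positive")
        concs = np.array([p.ligand_conc_M for p in pts], dtype=float)
        if concs[0] != 0.0:
            raise ValidationError("the first titration point must have ligand_conc_M = 0 (defines F0)")
        if np.count_nonzero(concs == 0.0) != 1:
            raise ValidationError("exactly one zero-ligand point is allowed")
        if not np.all(np.diff(concs) > 0):
            raise ValidationError("ligand concentrations must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ligand_concs_M(self) -> np.ndarray:
        return np.array([p.ligand_conc_M for p in self.points], dtype=float)

    @property
    def F_obs(self) -> np.ndarray:
        return np.array([p.F_obs for p in self.points], dtype=float)

    @property
    def F_corr(self) -> np.ndarray:
        """Corrected intensities; raises if the correction has not populated them."""
        vals = [p.F_corr for p in self.points]
        if any(v is None for v in vals):
            raise ValidationError("F_corr is not populated; run correction.apply_correction first")
        return np.array(vals, dtype=float)

    @property
    def F0(self) -> float:
        """Corrected intensity of the ligand-free point."""
        f0 = self.points[0].F_corr
        if f0 is None:
            raise ValidationError("F0 undefined: zero-ligand point has no F_corr")
        if not (f0 > 0):
            raise ValidationError("F0 must be positive")
        return float(f0)

    def with_points(self, points: Sequence[TitrationPoint], *, corrected: Optional[bool] = None) -> "TitrationSeries":
        return replace(
            self,
            points=tuple(points),
            corrected=self.corrected if corrected is None else corrected,
        )


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix: ``intensity[i, j]`` at ``ex_nm[i]``, ``em_nm[j]``."""

    ex_nm: np.ndarray
    em_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ex = _as_readonly_float_array(self.ex_nm, "ex_nm")
        em = _as_readonly_float_array(self.em_nm, "em_nm")
        _require_strictly_increasing(ex, "ex_nm")
        _require_strictly_increasing(em, "em_nm")
        mat = _as_readonly_float_array(self.intensity, "intensity", ndim=2)
        if mat.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity shape {mat.shape} does not match grids ({ex.size}, {em.size})"
            )
        object.__setattr__(self, "ex_nm", ex)
        object.__setattr__(self, "em_nm", em)
        object.__setattr__(self, "intensity", mat)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def value_at(self, lambda_ex_nm: float, lambda_em_nm: float) -> float:
        """Intensity at the grid node nearest to the requested coordinates."""
        i = int(np.argmin(np.abs(self.ex_nm - lambda_ex_nm)))
        j = int(np.argmin(np.abs(self.em_nm - lambda_em_nm)))
        return float(self.intensity[i, j])


@dataclass(frozen=True)
class SyncSpectrum:
    """A synchronous-fluorescence scan at fixed excitation-emission offset.

    An offset of 15 nm reports the tyrosine microenvironment and 60 nm the
    tryptophan microenvironment; other positive offsets are accepted but carry
    no residue assignment.
    """

    delta_lambda_nm: float
    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    ligand_conc_M: float = 0.0

    def __post_init__(self) -> None:
        if not (self.delta_lambda_nm > 0):
            raise ValidationError("delta_lambda_nm must be positive")
        if self.ligand_conc_M < 0:
            raise ValidationError("ligand_conc_M must be >= 0")
        w = _as_readonly_float_array(self.wavelengths_nm, "wavelengths_nm")
        i = _as_readonly_float_array(self.intensities, "intensities")
        _require_strictly_increasing(w, "wavelengths_nm")
        if w.shape != i.shape:
            raise ValidationError("wavelengths and intensities differ in length")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)

    @property
    def residue_assignment(self) -> Optional[str]:
        return {15.0: "Tyr", 60.0: "Trp"}.get(float(self.delta_lambda_nm))
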