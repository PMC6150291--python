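"""Inner-filter correction and UV-Vis difference spectra.

Absorption of the excitation beam and re-absorption of the emitted light by
the ligand attenuate the measured fluorescence.  With decadic absorbances
``A_ex`` and ``A_em`` measured at the excitation and emission wavelengths the
standard correction is

    F_corr = F_obs * 10 ** ((A_ex + A_em) / 2)

The correction depends on the two absorbances only through their sum, is
strictly increasing in each argument, and its factor is always >= 1.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Union

import numpy as np
from scipy.interpolate import CubicSpline

from .datatypes import AbsorbanceSpectrum, EmissionSpectrum, TitrationSeries
from .errors import CorrectionError, ValidationError


def inner_filter_factor(A_ex, A_em):
    """Decadic antilog attenuation factor ``10**((A_ex+A_em)/2)`` (>= 1)."""
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be >= 0 (negative values signal a mis-specified blank)")
    return 10.0 ** ((A_ex + A_em) / 2.0)


def correct_inner_filter(F_obs, A_ex, A_em):
    """Apply the inner-filter correction to one intensity (or an array).

    Returns ``F_obs * 10**((A_ex + A_em)/2)``, which is never smaller than
    ``F_obs``.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    if np.any(F_obs < 0):
        raise ValidationError("F_obs must be >= 0")
    out = F_obs * inner_filter_factor(A_ex, A_em)
    return float(out) if out.ndim == 0 else out


def apply_correction(series: TitrationSeries, *, skip: bool = False) -> TitrationSeries:
    """Populate ``F_corr`` on every point of a titration series.

    With ``skip=True`` the correction is bypassed and ``F_corr = F_obs``
    (for series measured with negligible ligand absorbance).  A series can be
    corrected only once: double application is a real analysis bug and raises.
    """
    if series.corrected:
        raise CorrectionError("series is already inner-filter corrected; refusing to correct twice")
    new_points = []
    for k, p in enumerate(series.points):
        if skip:
            f_corr = p.F_obs
        else:
            if not p.has_absorbances:
                raise CorrectionError(
                    f"point {k} (ligand_conc_M={p.ligand_conc_M:g}) lacks A_ex/A_em; "
                    "supply absorbances or pass skip=True"
                )
            f_corr = correct_inner_filter(p.F_obs, p.A_ex, p.A_em)
        new_points.append(replace(p, F_corr=float(f_corr)))
    return series.with_points(new_points, corrected=True)


def difference_spectrum(
    complex_spec: Union[AbsorbanceSpectrum, EmissionSpectrum],
    ligand_spec: Union[AbsorbanceSpectrum, EmissionSpectrum],
    *,
    interpolate: bool = False,
) -> AbsorbanceSpectrum:
    """Pointwise complex-minus-ligand difference of two UV-Vis scans.

    The grids must match exactly unless ``interpolate=True``, in which case
    the ligand spectrum is resampled onto the overlap of the two grids with a
    cubic spline (accurate to well below 1e-6 for smooth bands on nm-scale
    grids).  Negative differences are preserved.
    """
    wc = complex_spec.wavelengths_nm
    vc = getattr(complex_spec, "absorbances", None)
    if vc is None:
        vc = complex_spec.intensities
    wl = ligand_spec.wavelengths_nm
    vl = getattr(ligand_spec, "absorbances", None)
    if vl is None:
        vl = ligand_spec.intensities

    if wc.shape == wl.shape and np.allclose(wc, wl):
        return AbsorbanceSpectrum(wc, vc - vl)
    if not interpolate:
        raise ValidationError("wavelength grids differ; pass interpolate=True to resample")
    lo, hi = max(wc[0], wl[0]), min(wc[-1], wl[-1])
    mask = (wc >= lo) & (wc <= hi)
    if not np.any(mask):
        raise ValidationError("wavelength grids do not overlap")
    w = wc[mask]
    resampled = CubicSpline(wl, vl)(w)
    return AbsorbanceSpectrum(w, vc[mask] - resampled)
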