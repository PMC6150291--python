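"""Conformational probes: synchronous-scan peak shifts and EEM peak analysis.

A ligand that quenches without perturbing the protein's fold reduces peak
intensities but leaves peak *positions* unchanged.  ``sync_peak_shift``
quantifies the emission-maximum displacement across a concentration series of
synchronous scans; ``eem_find_peaks`` locates the fluorophore peaks of an
excitation-emission matrix after masking Rayleigh scatter; and
``percent_quench`` tabulates the intensity drop of a treated EEM at the
reference peak coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import EEM, SyncSpectrum
from .errors import FitError, ValidationError


@dataclass(frozen=True)
class EEMPeak:
    lambda_ex_nm: float
    lambda_em_nm: float
    intensity: float


@dataclass(frozen=True)
class PeakQuench:
    """Intensity change at one reference peak coordinate."""

    peak: EEMPeak
    intensity_treated: float
    drop: float
    percent: float  # 100 * drop / reference intensity, rounded to 2 decimals


@dataclass(frozen=True)
class EEMPeakSummary:
    """Peaks of an EEM (intensity-descending) and, optionally, their quench."""

    peaks: tuple[EEMPeak, ...]
    quench: tuple[PeakQuench, ...] = ()


@dataclass(frozen=True)
class SyncShiftResult:
    peak_wavelengths_nm: tuple[float, ...]
    max_shift_nm: float
    shifted: bool
    threshold_nm: float


def _refine_peak(w: np.ndarray, y: np.ndarray) -> float:
    """Argmax with 3-point parabolic refinement (grid value at the edges)."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(w[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(w[i])
    delta = 0.5 * (y0 - y2) / denom
    step = (w[i + 1] - w[i - 1]) / 2.0
    return float(w[i] + np.clip(delta, -1, 1) * step)


def sync_peak_shift(
    spectra: Sequence[SyncSpectrum],
    shift_threshold_nm: float = 2.0,
) -> SyncShiftResult:
    """Peak wavelength per synchronous scan and the maximum shift vs the first.

    The scans must share a common wavelength grid and be ordered by ligand
    concentration (the first is the ligand-free reference).  A shift larger
    than ``shift_threshold_nm`` (default 2 nm, about slit-limited resolution)
    is called significant.
    """
    if len(spectra) == 0:
        raise FitError("no synchronous spectra supplied")
    if len(spectra) < 2:
        raise FitError("need the reference scan plus >= 1 ligand scan")
    ref_grid = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if s.wavelengths_nm.shape != ref_grid.shape or not np.allclose(s.wavelengths_nm, ref_grid):
            raise ValidationError("synchronous spectra must share a common wavelength grid")
    peaks = tuple(_refine_peak(s.wavelengths_nm, s.intensities) for s in spectra)
    max_shift = float(max(abs(p - peaks[0]) for p in peaks[1:]))
    return SyncShiftResult(
        peak_wavelengths_nm=peaks,
        max_shift_nm=max_shift,
        shifted=max_shift > shift_threshold_nm,
        threshold_nm=shift_threshold_nm,
    )


def scatter_mask(eem: EEM, half_width_nm: float = 10.0) -> np.ndarray:
    """Boolean mask of nodes within ``half_width_nm`` of the Rayleigh line
    (em == ex) or its first-order harmonic (em == 2*ex)."""
    ex = eem.ex_nm[:, None]
    em = eem.em_nm[None, :]
    return (np.abs(em - ex) <= half_width_nm) | (np.abs(em - 2 * ex) <= half_width_nm)


def eem_find_peaks(
    eem: EEM,
    *,
    min_separation_nm: float = 20.0,
    exclude_scatter: bool = True,
    scatter_half_width_nm: float = 10.0,
    min_intensity_fraction: float = 0.05,
) -> EEMPeakSummary:
    """Locate local maxima of an EEM with greedy non-maximum suppression.

    Scatter ridges are masked first (``exclude_scatter``); candidate maxima
    below ``min_intensity_fraction`` of the global maximum are dropped;
    surviving candidates are accepted intensity-descending unless they fall
    within ``min_separation_nm`` of an accepted peak on *both* axes.
    """
    mat = eem.intensity.copy()
    masked = np.zeros(mat.shape, dtype=bool)
    if exclude_scatter:
        masked = scatter_mask(eem, scatter_half_width_nm)
        if masked.all():
            raise FitError("scatter mask covers the entire EEM; nothing to search")
        mat[masked] = -np.inf

    local_max = mat == ndimage.maximum_filter(mat, size=3, mode="nearest")
    # a node can be a "maximum" merely because its neighbour was masked out;
    # dilating the mask by one node removes such scatter-edge artefacts
    edge = ndimage.binary_dilation(masked) if exclude_scatter else masked
    local_max &= ~edge & np.isfinite(mat)
    if not local_max.any():
        raise FitError("no local maxima found in the EEM")
    floor = float(np.max(mat[np.isfinite(mat)])) * min_intensity_fraction
    idx_ex, idx_em = np.nonzero(local_max & (mat >= floor))
    order = np.argsort(mat[idx_ex, idx_em])[::-1]

    accepted: list[EEMPeak] = []
    for k in order:
        ex = float(eem.ex_nm[idx_ex[k]])
        em = float(eem.em_nm[idx_em[k]])
        if any(
            abs(ex - p.lambda_ex_nm) < min_separation_nm
            and abs(em - p.lambda_em_nm) < min_separation_nm
            for p in accepted
        ):
            continue
        accepted.append(EEMPeak(ex, em, float(mat[idx_ex[k], idx_em[k]])))
    if not accepted:
        raise FitError("no peaks survive scatter masking and the intensity floor")
    return EEMPeakSummary(peaks=tuple(accepted))


def percent_quench(reference: EEMPeakSummary, treated: EEM) -> EEMPeakSummary:
    """Intensity drop of ``treated`` at each reference peak coordinate.

    The treated intensity is read at the *reference* coordinates (no
    re-search), matching the convention of reporting quench at fixed peak
    positions when no peak shift occurs.  Percent drop is
    ``100 * (I_ref - I_treated) / I_ref`` rounded to 2 decimals.
    """
    if not reference.peaks:
        raise FitError("reference summary contains no peaks")
    quench = []
    for p in reference.peaks:
        if p.intensity <= 0:
            raise FitError(f"reference peak at ({p.lambda_ex_nm}, {p.lambda_em_nm}) has non-positive intensity")
        i_treated = treated.value_at(p.lambda_ex_nm, p.lambda_em_nm)
        drop = p.intensity - i_treated
        quench.append(
            PeakQuench(
                peak=p,
                intensity_treated=i_treated,
                drop=drop,
                percent=round(100.0 * drop / p.intensity, 2),
            )
        )
    return EEMPeakSummary(peaks=reference.peaks, quench=tuple(quench))
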