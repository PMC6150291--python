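"""Stern-Volmer / Lineweaver-Burk analysis and quenching-mechanism calls.

A static quencher forms a non-fluorescent ground-state complex, so its
apparent Stern-Volmer constant falls as the temperature rises (the complex
dissociates), and the derived bimolecular rate constant K_q = K_SV / tau0
exceeds the diffusion ceiling of ~2e10 M^-1 s^-1.  A dynamic (collisional)
quencher shows the opposite temperature trend and K_q at or below the
ceiling.  ``classify_mechanism`` encodes exactly this decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import TitrationSeries
from .errors import FitError
from .estimators import LineweaverBurkRegressor, SternVolmerRegressor

#: Maximum bimolecular rate constant of a diffusion-limited (dynamic)
#: quenching process, M^-1 s^-1.
DYNAMIC_QUENCHING_CEILING = 2.0e10


@dataclass(frozen=True)
class QuenchFitResult:
    """Constants from the linearized quenching fits of one titration series.

    ``K_sv`` (Stern-Volmer) and ``K_lb`` (Lineweaver-Burk) are in M^-1,
    ``K_q = K_sv / tau0`` in M^-1 s^-1.  Fields belonging to a fit that was
    not performed are ``None``.
    """

    temperature_K: float
    n_points: int
    tau0_s: float
    K_sv: Optional[float] = None
    K_sv_stderr: Optional[float] = None
    sv_intercept: Optional[float] = None
    sv_intercept_stderr: Optional[float] = None
    r2_sv: Optional[float] = None
    K_q: Optional[float] = None
    K_lb: Optional[float] = None
    K_lb_stderr: Optional[float] = None
    r2_lb: Optional[float] = None
    label: str = ""


@dataclass(frozen=True)
class MechanismCall:
    """Outcome of the static/dynamic decision with its supporting evidence."""

    mechanism: str  # "static" | "dynamic" | "indeterminate"
    evidence: dict = field(default_factory=dict)


def _series_arrays(series: TitrationSeries, *, allow_uncorrected: bool = False):
    if not series.corrected and not allow_uncorrected:
        raise FitError(
            "series has not been inner-filter corrected; run correction.apply_correction "
            "(or pass allow_uncorrected=True if absorbances are negligible and F_corr is set)"
        )
    F = series.F_corr
    if np.any(F <= 0):
        raise FitError("all corrected intensities must be positive")
    C = series.ligand_concs_M
    return C[1:], F[1:], series.F0


def fit_stern_volmer(
    series: TitrationSeries,
    *,
    fit_intercept: bool = False,
    allow_uncorrected: bool = False,
) -> QuenchFitResult:
    """Fit F0/F = 1 + K_SV*C and derive K_q = K_SV/tau0.

    ``fit_intercept=True`` frees the intercept (its deviation from 1 is a
    data-quality diagnostic); the default fixes it at the theoretical 1.
    """
    C, F, F0 = _series_arrays(series, allow_uncorrected=allow_uncorrected)
    est = SternVolmerRegressor(fit_intercept=fit_intercept).fit(C, F0 / F)
    return QuenchFitResult(
        temperature_K=series.temperature_K,
        n_points=est.n_points_,
        tau0_s=series.tau0_s,
        K_sv=est.K_sv_,
        K_sv_stderr=est.K_sv_stderr_,
        sv_intercept=est.intercept_,
        sv_intercept_stderr=est.intercept_stderr_,
        r2_sv=est.r2_,
        K_q=quenching_rate_constant(est.K_sv_, series.tau0_s),
        label=series.label,
    )


def fit_lineweaver_burk(
    series: TitrationSeries,
    *,
    allow_uncorrected: bool = False,
) -> QuenchFitResult:
    """Fit the double-reciprocal plot and return the static constant K_LB."""
    C, F, F0 = _series_arrays(series, allow_uncorrected=allow_uncorrected)
    est = LineweaverBurkRegressor().fit(C, F, F0=F0)
    return QuenchFitResult(
        temperature_K=series.temperature_K,
        n_points=est.n_points_,
        tau0_s=series.tau0_s,
        K_lb=est.K_lb_,
        K_lb_stderr=est.K_lb_stderr_,
        r2_lb=est.r2_,
        label=series.label,
    )


def fit_quenching(
    series: TitrationSeries,
    *,
    fit_intercept: bool = False,
    allow_uncorrected: bool = False,
) -> QuenchFitResult:
    """Run both linearizations on one series and merge the results."""
    sv = fit_stern_volmer(series, fit_intercept=fit_intercept, allow_uncorrected=allow_uncorrected)
    lb = fit_lineweaver_burk(series, allow_uncorrected=allow_uncorrected)
    return QuenchFitResult(
        temperature_K=sv.temperature_K,
        n_points=sv.n_points,
        tau0_s=sv.tau0_s,
        K_sv=sv.K_sv,
        K_sv_stderr=sv.K_sv_stderr,
        sv_intercept=sv.sv_intercept,
        sv_intercept_stderr=sv.sv_intercept_stderr,
        r2_sv=sv.r2_sv,
        K_q=sv.K_q,
        K_lb=lb.K_lb,
        K_lb_stderr=lb.K_lb_stderr,
        r2_lb=lb.r2_lb,
        label=series.label,
    )


def quenching_rate_constant(K_sv: float, tau0_s: float) -> float:
    """Bimolecular quenching rate constant K_q = K_SV / tau0 (M^-1 s^-1)."""
    if tau0_s <= 0:
        raise FitError("tau0_s must be positive")
    return float(K_sv) / float(tau0_s)


def classify_mechanism(
    results: Sequence[QuenchFitResult],
    *,
    ceiling: float = DYNAMIC_QUENCHING_CEILING,
    min_separation_se: float = 0.0,
) -> MechanismCall:
    """Classify quenching as static or dynamic from the temperature trend.

    ``results`` must be ordered by strictly increasing temperature.  The call
    is *static* when K_SV is non-increasing with T and every K_q exceeds the
    diffusion ceiling; *dynamic* when K_SV is non-decreasing and no K_q
    exceeds it; otherwise *indeterminate* with the evidence attached.

    ``min_separation_se > 0`` additionally requires consecutive K_SV values
    to differ by at least that many pooled standard errors before a trend is
    trusted; by default trends are read from the point estimates.
    """
    if len(results) < 2:
        raise FitError("mechanism classification needs results at >= 2 temperatures")
    temps = np.array([r.temperature_K for r in results], dtype=float)
    if not np.all(np.diff(temps) > 0):
        raise FitError("results must be ordered by strictly increasing temperature")
    ksv = np.array([r.K_sv for r in results], dtype=float)
    if np.any(np.isnan(ksv)):
        raise FitError("every result needs a Stern-Volmer constant")
    kq = np.array(
        [r.K_q if r.K_q is not None else quenching_rate_constant(r.K_sv, r.tau0_s) for r in results],
        dtype=float,
    )

    diffs = np.diff(ksv)
    if min_separation_se > 0:
        se = np.array([r.K_sv_stderr or 0.0 for r in results], dtype=float)
        pooled = np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
        significant = np.abs(diffs) >= min_separation_se * pooled
        diffs = np.where(significant, diffs, 0.0)

    non_increasing = bool(np.all(diffs <= 0))
    non_decreasing = bool(np.all(diffs >= 0))
    above_ceiling = bool(np.min(kq) > ceiling)
    below_ceiling = bool(np.max(kq) <= ceiling)

    evidence = {
        "temperatures_K": temps.tolist(),
        "K_sv": ksv.tolist(),
        "K_q": kq.tolist(),
        "dKsv_dT_sign": "non-increasing" if non_increasing else ("non-decreasing" if non_decreasing else "non-monotone"),
        "K_q_ceiling": ceiling,
        "min_K_q_over_ceiling": float(np.min(kq) / ceiling),
    }
    if non_increasing and above_ceiling:
        return MechanismCall("static", evidence)
    if non_decreasing and below_ceiling:
        return MechanismCall("dynamic", evidence)
    return MechanismCall("indeterminate", evidence)
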