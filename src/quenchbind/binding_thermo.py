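"""Binding constants, stoichiometry, and van't Hoff thermodynamics.

The double-log plot log10((F0-F)/F) versus log10(C) yields the binding
constant K (intercept) and the number of binding sites n (slope) under the
static-quenching assumption that free and bound ligand are nearly equal.
Regressing ln K on 1/T (van't Hoff) gives the standard enthalpy and entropy
changes, from which dG0(T) = dH0 - T*dS0.  The sign pattern of (dH0, dS0)
identifies the dominant binding force: (+,+) hydrophobic, (-,-) hydrogen
bonding / van der Waals, (-,+) electrostatic.

Units follow the conventions of the field: dH0 and dG0 in kJ/mol, dS0 in
J/(mol K), K in M^-1, with R = 8.314 J/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .datatypes import TitrationSeries
from .errors import FitError
from .estimators import R_GAS, DoubleLogRegressor, VantHoffRegressor
from .quenching import _series_arrays


@dataclass(frozen=True)
class BindingFitResult:
    """Binding constant K (M^-1) and site count n from the double-log fit."""

    K: float
    K_stderr: float
    n: float
    n_stderr: float
    r2: float
    temperature_K: float
    n_points: int
    label: str = ""


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff regression output: dH0 (kJ/mol), dS0 (J/mol/K), dG0(T)."""

    dH0_kJ: float
    dH0_stderr_kJ: float
    dS0_J: float
    dS0_stderr_J: float
    dG0_by_T_kJ: dict[float, float]
    r2: float
    gas_constant: float = R_GAS


@dataclass(frozen=True)
class ForceCall:
    """Binding-force class from the (sign dH0, sign dS0) rule table."""

    force_class: str  # hydrophobic | hbond_vdw | electrostatic | indeterminate
    near_zero_dH: bool = False
    note: str = ""


def fit_double_log(series: TitrationSeries, *, allow_uncorrected: bool = False) -> BindingFitResult:
    """Fit log10((F0-F)/F) = log10 K + n log10 C on a corrected series."""
    C, F, F0 = _series_arrays(series, allow_uncorrected=allow_uncorrected)
    est = DoubleLogRegressor().fit(C, F, F0=F0)
    return BindingFitResult(
        K=est.K_,
        K_stderr=est.K_stderr_,
        n=est.n_,
        n_stderr=est.n_stderr_,
        r2=est.r2_,
        temperature_K=series.temperature_K,
        n_points=est.n_points_,
        label=series.label,
    )


def fit_vant_hoff(K_by_T: Mapping[float, float]) -> ThermoResult:
    """Regress ln K on 1/T and report dH0, dS0 and dG0 at each input T.

    ``K_by_T`` maps absolute temperature (K) to binding constant (M^-1);
    at least two distinct temperatures with positive K are required.
    """
    temps = list(K_by_T.keys())
    Ks = list(K_by_T.values())
    est = VantHoffRegressor().fit(temps, Ks)
    dG0 = {float(T): gibbs_free_energy(est.dH0_kJ_, est.dS0_J_, T) for T in temps}
    return ThermoResult(
        dH0_kJ=est.dH0_kJ_,
        dH0_stderr_kJ=est.dH0_stderr_kJ_,
        dS0_J=est.dS0_J_,
        dS0_stderr_J=est.dS0_stderr_J_,
        dG0_by_T_kJ=dG0,
        r2=est.r2_,
    )


def gibbs_free_energy(dH0_kJ: float, dS0_J: float, T: float) -> float:
    """dG0 = dH0 - T*dS0, with dH0 in kJ/mol and dS0 in J/(mol K)."""
    if T <= 0:
        raise FitError("temperature must be positive")
    return float(dH0_kJ) - float(T) * float(dS0_J) / 1000.0


def gibbs_from_K(K: float, T: float) -> float:
    """Consistency route dG0 = -R*T*ln(K), in kJ/mol."""
    if K <= 0:
        raise FitError("binding constant must be positive")
    if T <= 0:
        raise FitError("temperature must be positive")
    return -R_GAS * float(T) * math.log(float(K)) / 1000.0


def classify_forces(
    dH0_kJ: float,
    dS0_J: float,
    *,
    near_zero_threshold_kJ: float = 4.0,
) -> ForceCall:
    """Map the signs of (dH0, dS0) to the dominant intermolecular force.

    (+,+) -> hydrophobic; (-,-) -> hydrogen bonding / van der Waals;
    (-,+) -> electrostatic.  The (+,-) quadrant has no assignment in the
    standard rule table and returns an explicit ``indeterminate``.  In an
    electrostatic call, ``near_zero_dH`` is set when |dH0| is *not* close to
    zero (>= ``near_zero_threshold_kJ``), flagging that hydrogen bonding may
    also contribute.
    """
    if dH0_kJ > 0 and dS0_J > 0:
        return ForceCall("hydrophobic")
    if dH0_kJ < 0 and dS0_J < 0:
        return ForceCall("hbond_vdw")
    if dH0_kJ <= 0 and dS0_J > 0:
        flag = abs(dH0_kJ) >= near_zero_threshold_kJ
        note = (
            "|dH0| is not near zero: hydrogen bonding may contribute alongside electrostatic forces"
            if flag
            else ""
        )
        return ForceCall("electrostatic", near_zero_dH=flag, note=note)
    return ForceCall(
        "indeterminate",
        note="(+dH0, -dS0) or boundary sign pattern: not covered by the standard rule table",
    )
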