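"""scikit-learn-style estimators for the linearized quenching and binding fits.

Each estimator wraps one of the classical linearizations used in
protein-ligand fluorescence titrations:

``SternVolmerRegressor``
    F0/F = 1 + K_SV * C  (quench ratio versus quencher concentration)
``LineweaverBurkRegressor``
    1/(F0 - F) = 1/F0 + 1/(K_LB * F0) * 1/C  (double-reciprocal, static K)
``DoubleLogRegressor``
    log10((F0 - F)/F) = log10(K) + n * log10(C)  (binding constant and sites)
``VantHoffRegressor``
    ln K = -dH0/(R T) + dS0/R  (enthalpy and entropy from K(T))

They follow the scikit-learn estimator contract (``get_params`` /
``set_params`` via ``BaseEstimator``, fitted attributes with trailing
underscores, ``fit`` returning ``self``) so they compose with sklearn
pipelines and model-selection utilities.  ``X`` is the independent variable
as a 1-d array or ``(n, 1)`` column; higher-level wrappers in
:mod:`quenchbind.quenching` and :mod:`quenchbind.binding_thermo` feed them
from :class:`~quenchbind.datatypes.TitrationSeries` objects.

All fits are unweighted ordinary least squares on the transformed variables,
mirroring standard practice for these plots; the heteroscedasticity induced
by the reciprocal/log transforms is documented, not corrected.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314


def _as_1d(X, name: str = "X") -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise FitError(f"{name} must be 1-d or a single column, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FitError(f"{name} contains non-finite values")
    return arr


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    # squared Pearson correlation, the "R^2" conventionally quoted for these plots
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope/intercept OLS with standard errors and parameter covariance."""
    if x.size < 2:
        raise FitError("need at least 2 points for a linear fit")
    coeffs, cov = _polyfit_cov(x, y)
    slope, intercept = coeffs
    se_slope, se_intercept = np.sqrt(np.diag(cov))
    return slope, intercept, se_slope, se_intercept, cov[0, 1]


def _polyfit_cov(x: np.ndarray, y: np.ndarray):
    if x.size == 2:
        # exact interpolation: covariance degenerates, report zeros
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return np.array([slope, intercept]), np.zeros((2, 2))
    res = stats.linregress(x, y)
    # reconstruct the full covariance for delta-method propagation
    n = x.size
    dof = n - 2
    resid = y - (res.slope * x + res.intercept)
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    cov = np.empty((2, 2))
    cov[0, 0] = s2 / sxx
    cov[1, 1] = s2 * (1.0 / n + x.mean() ** 2 / sxx)
    cov[0, 1] = cov[1, 0] = -s2 * x.mean() / sxx
    return np.array([res.slope, res.intercept]), cov


class SternVolmerRegressor(RegressorMixin, BaseEstimator):
    """Fit F0/F = intercept + K_SV * C.

    Parameters
    ----------
    fit_intercept : bool, default False
        When False the intercept is fixed at the theoretical value 1 (the
        form used to report Stern-Volmer constants); when True a free
        intercept is fitted and its deviation from 1 serves as a data-quality
        diagnostic.

    Attributes
    ----------
    K_sv_ : float
        Stern-Volmer constant (slope), in M^-1 when C is molar.
    K_sv_stderr_ : float
    intercept_, intercept_stderr_ : float
    r2_ : float
        Squared Pearson correlation of the (C, F0/F) points.
    n_points_ : int
    """

    def __init__(self, fit_intercept: bool = False):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        x = _as_1d(X, "C_Q")
        ratio = _as_1d(y, "F0/F")
        if x.size != ratio.size:
            raise FitError("X and y differ in length")
        if x.size < 3:
            raise FitError("need at least 3 nonzero-ligand points for a Stern-Volmer fit")
        if self.fit_intercept:
            slope, intercept, se_slope, se_intercept, _ = _ols(x, ratio)
        else:
            # regression through the fixed intercept 1
            yy = ratio - 1.0
            sxx = float(x @ x)
            if sxx == 0:
                raise FitError("all concentrations are zero")
            slope = float(x @ yy) / sxx
            resid = yy - slope * x
            dof = x.size - 1
            s2 = float(resid @ resid) / dof if dof > 0 else 0.0
            se_slope = float(np.sqrt(s2 / sxx))
            intercept, se_intercept = 1.0, 0.0
        self.K_sv_ = float(slope)
        self.K_sv_stderr_ = float(se_slope)
        self.intercept_ = float(intercept)
        self.intercept_stderr_ = float(se_intercept)
        self.r2_ = _pearson_r2(x, ratio)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        return self.intercept_ + self.K_sv_ * _as_1d(X, "C_Q")


class LineweaverBurkRegressor(RegressorMixin, BaseEstimator):
    """Fit the double-reciprocal plot 1/(F0-F) versus 1/C.

    ``fit(X, y, F0=...)`` takes nonzero quencher concentrations ``X`` and the
    corresponding quenched intensities ``y``; ``F0`` is the unquenched
    intensity.  The line has slope 1/(K_LB*F0) and intercept 1/F0, so
    K_LB = intercept/slope.  The standard error of K_LB is propagated by the
    delta method from the (slope, intercept) covariance.

    Attributes: ``K_lb_``, ``K_lb_stderr_``, ``F0_implied_`` (1/intercept),
    ``r2_``, ``n_points_``.
    """

    def fit(self, X, y, F0: Optional[float] = None):
        if F0 is None:
            raise FitError("LineweaverBurkRegressor.fit requires the unquenched intensity F0")
        x = _as_1d(X, "C_Q")
        F = _as_1d(y, "F")
        if x.size != F.size:
            raise FitError("X and y differ in length")
        if x.size < 3:
            raise FitError("need at least 3 nonzero-ligand points")
        if np.any(x <= 0):
            raise FitError("Lineweaver-Burk requires strictly positive concentrations")
        bad = np.flatnonzero(F >= F0)
        if bad.size:
            raise FitError(
                f"F >= F0 at point index {bad[0]} (C={x[bad[0]]:g}); "
                "1/(F0-F) undefined — non-quenching or noise-dominated point"
            )
        u = 1.0 / x
        v = 1.0 / (F0 - F)
        slope, intercept, se_slope, se_intercept, cov_si = _ols(u, v)
        if slope <= 0 or intercept <= 0:
            raise FitError("non-positive slope or intercept: data inconsistent with quenching model")
        k = intercept / slope
        # delta method: var(K) = (dK/di)^2 var(i) + (dK/ds)^2 var(s) + 2 cross
        di, ds = 1.0 / slope, -intercept / slope**2
        var_k = di**2 * se_intercept**2 + ds**2 * se_slope**2 + 2 * di * ds * cov_si
        self.K_lb_ = float(k)
        self.K_lb_stderr_ = float(np.sqrt(max(var_k, 0.0)))
        self.F0_implied_ = float(1.0 / intercept)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = _pearson_r2(u, v)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        """Predicted 1/(F0-F) at concentrations X."""
        return self.intercept_ + self.slope_ / _as_1d(X, "C_Q")


class DoubleLogRegressor(RegressorMixin, BaseEstimator):
    """Fit log10((F0-F)/F) = log10(K) + n*log10(C).

    The slope estimates the number of binding sites ``n`` and the intercept
    the base-10 log of the binding constant ``K``.  The standard error of K
    is obtained from the intercept error by the delta method
    (``se_K = ln(10) * K * se_intercept``).

    Attributes: ``n_``, ``n_stderr_``, ``K_``, ``K_stderr_``, ``log10K_``,
    ``r2_``, ``n_points_``.
    """

    def fit(self, X, y, F0: Optional[float] = None):
        if F0 is None:
            raise FitError("DoubleLogRegressor.fit requires the unquenched intensity F0")
        x = _as_1d(X, "C_Q")
        F = _as_1d(y, "F")
        if x.size != F.size:
            raise FitError("X and y differ in length")
        if x.size < 3:
            raise FitError("need at least 3 nonzero-ligand points")
        if np.any(x <= 0):
            raise FitError("double-log fit requires strictly positive concentrations")
        bad = np.flatnonzero((F >= F0) | (F <= 0))
        if bad.size:
            raise FitError(
                f"point index {bad[0]} (C={x[bad[0]]:g}) has F >= F0 or F <= 0; "
                "log((F0-F)/F) undefined"
            )
        lx = np.log10(x)
        ly = np.log10((F0 - F) / F)
        slope, intercept, se_slope, se_intercept, _ = _ols(lx, ly)
        self.n_ = float(slope)
        self.n_stderr_ = float(se_slope)
        self.log10K_ = float(intercept)
        self.log10K_stderr_ = float(se_intercept)
        self.K_ = float(10.0**intercept)
        self.K_stderr_ = float(np.log(10.0) * self.K_ * se_intercept)
        self.r2_ = _pearson_r2(lx, ly)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        """Predicted log10((F0-F)/F) at concentrations X."""
        return self.log10K_ + self.n_ * np.log10(_as_1d(X, "C_Q"))


class VantHoffRegressor(RegressorMixin, BaseEstimator):
    """Fit ln K = -dH0/(R T) + dS0/R from binding constants at several T.

    ``fit(X, y)`` takes temperatures (K) and binding constants (M^-1).
    Slope and intercept of the (1/T, ln K) line give the standard enthalpy
    and entropy changes: dH0 = -R*slope (reported in kJ/mol), dS0 =
    R*intercept (J/mol/K).

    Attributes: ``dH0_kJ_``, ``dH0_stderr_kJ_``, ``dS0_J_``,
    ``dS0_stderr_J_``, ``r2_``, ``n_points_``.
    """

    def fit(self, X, y):
        T = _as_1d(X, "T")
        K = _as_1d(y, "K")
        if T.size != K.size:
            raise FitError("temperatures and binding constants differ in length")
        if T.size < 2:
            raise FitError("need >= 2 distinct temperatures")
        if np.unique(T).size != T.size:
            raise FitError("duplicate temperatures in van't Hoff input")
        if np.any(T <= 0):
            raise FitError("temperatures must be positive (kelvin)")
        if np.any(K <= 0):
            raise FitError("binding constants must be positive")
        x = 1.0 / T
        yl = np.log(K)
        slope, intercept, se_slope, se_intercept, _ = _ols(x, yl)
        self.dH0_kJ_ = float(-R_GAS * slope / 1000.0)
        self.dH0_stderr_kJ_ = float(R_GAS * se_slope / 1000.0)
        self.dS0_J_ = float(R_GAS * intercept)
        self.dS0_stderr_J_ = float(R_GAS * se_intercept)
        self.r2_ = _pearson_r2(x, yl)
        self.n_points_ = int(T.size)
        return self

    def predict(self, X):
        """Predicted binding constant at temperatures X."""
        T = _as_1d(X, "T")
        return np.exp(-self.dH0_kJ_ * 1000.0 / (R_GAS * T) + self.dS0_J_ / R_GAS)

    def gibbs_kJ(self, T) -> float:
        """dG0(T) = dH0 - T*dS0, in kJ/mol."""
        return self.dH0_kJ_ - np.asarray(T, dtype=float) * self.dS0_J_ / 1000.0
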