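"""Forward simulator of quenching titrations, synchronous scans and EEMs.

The generator emulates the standard experimental design for drug-albumin
quenching work: a single-Trp protein held at 1.5 uM is titrated with five
ligand aliquots spanning 3.5-35 uM at 288, 298 and 309 K, excitation 280 nm,
emission read at the 340 nm band maximum.

Static mechanism (the default) assumes a non-fluorescent 1:1 ground-state
complex: the emitted intensity is proportional to the unbound protein
fraction, which under the free-ligand approximation reproduces the linear
Stern-Volmer form F0/F = 1 + K*C exactly.  ``ligand_depletion=True``
replaces the approximation with the exact 1:1 equilibrium (quadratic solve
on total concentrations), producing the one-signed downward bias that the
approximation-based fits then exhibit.  The temperature dependence of K
follows ln K = -dH0/(RT) + dS0/R when enthalpy/entropy are supplied.

Inner-filter attenuation is simulated with absorbances linear in ligand
concentration (Beer's law with configurable molar absorptivities), i.e. the
exact inverse of the decadic correction, so the correction module can undo
it to machine precision.  Measurement noise is multiplicative Gaussian
(shot-noise-like at high signal).  One integer seed governs all draws;
replicate indices offset it deterministically.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .datatypes import EEM, EmissionSpectrum, SyncSpectrum, TitrationPoint, TitrationSeries, DEFAULT_TAU0_S
from .errors import ValidationError
from .estimators import R_GAS

#: Default study design: final cuvette concentrations (mol/L).
DEFAULT_LIGAND_CONCS_M = (3.5e-6, 7.0e-6, 15.0e-6, 25.0e-6, 35.0e-6)
DEFAULT_TEMPERATURES_K = (288.0, 298.0, 309.0)


class SynthConfig(BaseModel):
    """Ground-truth parameters of a simulated titration study.

    Supply either an explicit ``K_true`` (temperature-independent) or the
    van't Hoff pair ``dH0_true_kJ``/``dS0_true_J`` (K then varies with T);
    supplying both with several temperatures is ambiguous and rejected.
    """

    model_config = ConfigDict(frozen=True)

    K_true: Optional[float] = None          # M^-1
    n_true: float = 1.0                     # binding sites
    dH0_true_kJ: Optional[float] = None     # kJ/mol
    dS0_true_J: Optional[float] = None      # J/(mol K)
    temperatures_K: tuple[float, ...] = DEFAULT_TEMPERATURES_K
    protein_conc_M: float = 1.5e-6
    ligand_concs_M: tuple[float, ...] = DEFAULT_LIGAND_CONCS_M
    mechanism: str = "static"               # "static" | "dynamic"
    complex_fluorescence_fraction: float = 0.0
    ligand_depletion: bool = False
    inner_filter: bool = False
    eps_ex_M_cm: float = 3500.0             # ligand molar absorptivity at lambda_ex, M^-1 cm^-1
    eps_em_M_cm: float = 250.0              # at the emission analysis wavelength
    path_cm: float = 1.0
    F0: float = 1000.0                      # unquenched intensity at the band maximum, a.u.
    lambda_ex_nm: float = 280.0
    band_center_nm: float = 340.0
    band_width_nm: float = 25.0
    ligand_band_amplitude: float = 0.0      # optional additive ligand fluorescence per mol/L
    dynamic_activation_kJ: float = 12.0     # Arrhenius-like T-dependence for dynamic K_SV
    tau0_s: float = DEFAULT_TAU0_S
    noise_sd_rel: float = 0.0
    seed: int = 0

    @field_validator("ligand_concs_M")
    @classmethod
    def _concs_positive(cls, v):
        if any(c <= 0 for c in v):
            raise ValueError("ligand_concs_M must all be positive (the zero point is added automatically)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("ligand_concs_M must be strictly increasing")
        return v

    @field_validator("noise_sd_rel")
    @classmethod
    def _noise_nonneg(cls, v):
        if v < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        return v

    @field_validator("mechanism")
    @classmethod
    def _mechanism_known(cls, v):
        if v not in ("static", "dynamic"):
            raise ValueError("mechanism must be 'static' or 'dynamic'")
        return v

    @model_validator(mode="after")
    def _k_specification(self):
        have_thermo = self.dH0_true_kJ is not None or self.dS0_true_J is not None
        if have_thermo and (self.dH0_true_kJ is None or self.dS0_true_J is None):
            raise ValueError("supply dH0_true_kJ and dS0_true_J together")
        if self.K_true is None and not have_thermo:
            raise ValueError("supply K_true or the (dH0_true_kJ, dS0_true_J) pair")
        if self.K_true is not None and have_thermo and len(self.temperatures_K) > 1:
            raise ValueError(
                "ambiguous configuration: both K_true and (dH0, dS0) given with several temperatures"
            )
        if self.K_true is not None and self.K_true < 0:
            raise ValueError("K_true must be >= 0")
        return self

    def K_at(self, T: float) -> float:
        """True binding (or Stern-Volmer) constant at temperature T."""
        if self.dH0_true_kJ is not None:
            return math.exp(
                -self.dH0_true_kJ * 1000.0 / (R_GAS * T) + self.dS0_true_J / R_GAS
            )
        assert self.K_true is not None
        if self.mechanism == "dynamic":
            T_ref = 298.0
            ea = self.dynamic_activation_kJ * 1000.0
            return self.K_true * math.exp(ea / R_GAS * (1.0 / T_ref - 1.0 / T))
        return self.K_true


def _rng(config: SynthConfig, *offsets: int) -> np.random.Generator:
    parts = [int(config.seed) % (2**31)] + [int(o) % (2**31) for o in offsets]
    return np.random.default_rng(parts)


def _bound_fraction(config: SynthConfig, K: float, C_total: float) -> float:
    """Fraction of protein bound at one titration point (static model)."""
    if C_total == 0.0 or K == 0.0:
        return 0.0
    if config.ligand_depletion:
        if config.n_true != 1.0:
            raise ValidationError("exact ligand-depletion model is defined for 1:1 stoichiometry only")
        P, L = config.protein_conc_M, C_total
        # [PL] from K = PL / ((P-PL)(L-PL)): smaller root of the quadratic
        b = P + L + 1.0 / K
        pl = (b - math.sqrt(b * b - 4.0 * P * L)) / 2.0
        return pl / P
    # free-ligand approximation with Hill-type generalization K*C^n
    x = K * C_total**config.n_true
    return x / (1.0 + x)


def generate_titration(
    config: SynthConfig,
    T: float,
    *,
    replicate: int = 0,
) -> TitrationSeries:
    """Simulate one titration series at temperature ``T``.

    The emitted series carries the true per-point absorbances, leaving the
    inner-filter correction to the analysis pipeline; ``F_corr`` is *not*
    populated.  ``replicate`` offsets the random stream deterministically.
    """
    if not any(abs(T - t) < 1e-9 for t in config.temperatures_K):
        raise ValidationError(f"T={T} K is not among config.temperatures_K={config.temperatures_K}")
    K = config.K_at(T)
    concs = (0.0,) + tuple(config.ligand_concs_M)
    rng = _rng(config, int(round(T * 1000)), replicate)
    points = []
    for C in concs:
        if config.mechanism == "dynamic":
            F_true = config.F0 / (1.0 + K * C)
        else:
            fb = _bound_fraction(config, K, C)
            F_true = config.F0 * ((1.0 - fb) + config.complex_fluorescence_fraction * fb)
        F_true += config.ligand_band_amplitude * C
        if config.inner_filter:
            A_ex = config.eps_ex_M_cm * C * config.path_cm
            A_em = config.eps_em_M_cm * C * config.path_cm
        else:
            A_ex = A_em = 0.0
        F_obs = F_true * 10.0 ** (-(A_ex + A_em) / 2.0)
        if config.noise_sd_rel > 0:
            F_obs *= max(1.0 + config.noise_sd_rel * rng.standard_normal(), 1e-6)
        points.append(TitrationPoint(ligand_conc_M=C, F_obs=F_obs, A_ex=A_ex, A_em=A_em))
    return TitrationSeries(
        protein_conc_M=config.protein_conc_M,
        temperature_K=float(T),
        points=tuple(points),
        tau0_s=config.tau0_s,
        label=f"synthetic {config.mechanism} T={T:g}K",
    )


def generate_spectrum(
    config: SynthConfig,
    F_peak: float,
    *,
    temperature_K: float,
    grid_nm: Optional[np.ndarray] = None,
) -> EmissionSpectrum:
    """Gaussian emission band with the requested peak intensity."""
    if grid_nm is None:
        grid_nm = np.arange(285.0, 500.0 + 1e-9, 1.0)
    band = F_peak * np.exp(-0.5 * ((grid_nm - config.band_center_nm) / config.band_width_nm) ** 2)
    return EmissionSpectrum(grid_nm, band, config.lambda_ex_nm, temperature_K)


def generate_eem(
    peaks: Sequence[tuple[float, float, float, tuple[float, float]]],
    ex_nm,
    em_nm,
    *,
    rayleigh_amplitude: float = 0.0,
    rayleigh_width_nm: float = 6.0,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
) -> EEM:
    """Sum of bivariate Gaussian blobs, optional Rayleigh ridge, and noise.

    ``peaks`` is a sequence of ``(lambda_ex, lambda_em, amplitude,
    (sigma_ex, sigma_em))``; every peak centre must lie inside both grids.
    """
    ex = np.asarray(ex_nm, dtype=float)
    em = np.asarray(em_nm, dtype=float)
    mat = np.zeros((ex.size, em.size))
    for (pex, pem, amp, (sx, sy)) in peaks:
        if not (ex[0] <= pex <= ex[-1]) or not (em[0] <= pem <= em[-1]):
            raise ValidationError(f"peak centre ({pex}, {pem}) lies outside the grids")
        mat += amp * np.exp(
            -0.5 * (((ex[:, None] - pex) / sx) ** 2 + ((em[None, :] - pem) / sy) ** 2)
        )
    if rayleigh_amplitude > 0:
        mat += rayleigh_amplitude * np.exp(
            -0.5 * ((em[None, :] - ex[:, None]) / rayleigh_width_nm) ** 2
        )
    if noise_sd_rel > 0:
        rng = np.random.default_rng([int(seed) % (2**31)])
        mat = np.clip(mat * (1.0 + noise_sd_rel * rng.standard_normal(mat.shape)), 0.0, None)
    return EEM(ex, em, mat)


def generate_sync_series(
    config: SynthConfig,
    delta_lambda_nm: float,
    *,
    shift_per_conc_nm: float = 0.0,
    grid_nm: Optional[np.ndarray] = None,
) -> list[SyncSpectrum]:
    """Synchronous-scan series quenched by the static model.

    Peak intensities follow F0/(1 + K*C^n) at the first configured
    temperature; ``shift_per_conc_nm`` translates the band centre by that
    amount per titration step to exercise the peak-shift detector.
    """
    # synchronous scans are plotted against excitation wavelength; the band
    # sits delta-lambda below the emission maximum
    center0 = config.band_center_nm - delta_lambda_nm
    if grid_nm is None:
        grid_nm = np.arange(center0 - 60.0, center0 + 60.0 + 1e-9, 1.0)
    T = config.temperatures_K[0]
    K = config.K_at(T)
    out = []
    for k, C in enumerate((0.0,) + tuple(config.ligand_concs_M)):
        fb = _bound_fraction(config, K, C)
        amp = config.F0 * ((1.0 - fb) + config.complex_fluorescence_fraction * fb)
        center = center0 + k * shift_per_conc_nm
        band = amp * np.exp(-0.5 * ((grid_nm - center) / (config.band_width_nm / 2.0)) ** 2)
        out.append(
            SyncSpectrum(
                delta_lambda_nm=delta_lambda_nm,
                wavelengths_nm=grid_nm,
                intensities=band,
                ligand_conc_M=C,
            )
        )
    return out
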