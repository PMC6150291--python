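import numpy as np
import pytest

from quenchbind import (
    EmissionSpectrum,
    SynthConfig,
    TitrationPoint,
    TitrationSeries,
    apply_correction,
)


@pytest.fixture
def gaussian_spectrum():
    """Factory for a Gaussian emission band on a 1-nm grid."""

    def make(center=340.0, peak=100.0, width=25.0, lo=285.0, hi=500.0, step=1.0,
             lambda_ex=280.0, T=298.0):
        w = np.arange(lo, hi + 1e-9, step)
        return EmissionSpectrum(w, peak * np.exp(-0.5 * ((w - center) / width) ** 2),
                                lambda_ex, T)

    return make


@pytest.fixture
def make_series():
    """Factory for a corrected titration series from (C, F) arrays."""

    def make(concs, F, T=298.0, protein=1.5e-6, tau0=2.7e-9, corrected=True):
        pts = [TitrationPoint(ligand_conc_M=c, F_obs=f, A_ex=0.0, A_em=0.0)
               for c, f in zip(concs, F)]
        series = TitrationSeries(protein_conc_M=protein, temperature_K=T,
                                 points=tuple(pts), tau0_s=tau0)
        return apply_correction(series) if corrected else series

    return make


@pytest.fixture
def study_config():
    """The default simulated study: single-Trp albumin + 1:1 static quencher."""
    return SynthConfig(dH0_true_kJ=-1.79, dS0_true_J=79.40, inner_filter=True, seed=1234)
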