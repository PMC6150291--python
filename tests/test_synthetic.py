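"""Forward-generator contracts: round trips, bias signs, seeding."""

import numpy as np
import pytest
from pydantic import ValidationError as PydanticValidationError

import quenchbind as qb


class TestConfigValidation:
    def test_requires_some_K_specification(self):
        with pytest.raises(PydanticValidationError):
            qb.SynthConfig()

    def test_ambiguous_K_and_thermo_rejected(self):
        with pytest.raises(PydanticValidationError, match="ambiguous"):
            qb.SynthConfig(K_true=2.9e4, dH0_true_kJ=-1.79, dS0_true_J=79.4)

    def test_nonpositive_concentrations_rejected(self):
        with pytest.raises(PydanticValidationError):
            qb.SynthConfig(K_true=2.9e4, ligand_concs_M=(0.0, 1e-6))


class TestTitrationGeneration:
    def test_noiseless_round_trip_recovers_K_exactly(self):
        cfg = qb.SynthConfig(K_true=2.89e4, temperatures_K=(298.0,))
        s = qb.apply_correction(qb.generate_titration(cfg, 298.0))
        assert qb.fit_stern_volmer(s).K_sv == pytest.approx(2.89e4, rel=1e-9)
        assert qb.fit_double_log(s).K == pytest.approx(2.89e4, rel=1e-9)

    def test_inner_filter_attenuation_is_exactly_invertible(self):
        cfg = qb.SynthConfig(K_true=2.89e4, temperatures_K=(298.0,), inner_filter=True)
        raw = qb.generate_titration(cfg, 298.0)
        corrected = qb.apply_correction(raw)
        assert qb.fit_stern_volmer(corrected).K_sv == pytest.approx(2.89e4, rel=1e-9)
        # skipping the correction overstates quenching: the attenuation grows
        # with ligand concentration, steepening the apparent F0/F line
        uncorrected = qb.apply_correction(raw, skip=True)
        assert qb.fit_stern_volmer(uncorrected).K_sv > 2.89e4 * (1 + 1e-6)

    def test_zero_affinity_gives_flat_series(self):
        cfg = qb.SynthConfig(K_true=0.0, temperatures_K=(298.0,))
        s = qb.apply_correction(qb.generate_titration(cfg, 298.0))
        assert np.allclose(s.F_corr, s.F0)
        assert qb.fit_stern_volmer(s).K_sv == pytest.approx(0.0, abs=1e-12)

    def test_ligand_depletion_bias_is_one_signed(self):
        """With exact 1:1 equilibrium, free ligand < total ligand at every
        point, so the total-concentration Stern-Volmer slope underestimates K.
        (The double-log intercept is exempt: its 5-decade extrapolation can
        tilt either way.)"""
        for K in (1e4, 2.89e4, 1e5):
            cfg = qb.SynthConfig(K_true=K, temperatures_K=(298.0,), ligand_depletion=True)
            s = qb.apply_correction(qb.generate_titration(cfg, 298.0))
            # pointwise: observed quench ratio sits below the ideal line
            C, F, F0 = s.ligand_concs_M[1:], s.F_corr[1:], s.F0
            assert np.all(F0 / F - 1 < K * C)
            assert qb.fit_stern_volmer(s).K_sv < K

    def test_dynamic_mechanism_increases_with_temperature(self):
        cfg = qb.SynthConfig(K_true=1.0e4, mechanism="dynamic")
        ksv = []
        for T in cfg.temperatures_K:
            s = qb.apply_correction(qb.generate_titration(cfg, T))
            ksv.append(qb.fit_stern_volmer(s).K_sv)
        assert ksv[0] < ksv[1] < ksv[2]

    def test_seeding_is_reproducible_and_replicates_differ(self):
        cfg = qb.SynthConfig(K_true=2.89e4, temperatures_K=(298.0,), noise_sd_rel=0.01, seed=5)
        a = qb.generate_titration(cfg, 298.0)
        b = qb.generate_titration(cfg, 298.0)
        c = qb.generate_titration(cfg, 298.0, replicate=1)
        assert np.array_equal(a.F_obs, b.F_obs)
        assert not np.array_equal(a.F_obs, c.F_obs)

    def test_unconfigured_temperature_rejected(self):
        cfg = qb.SynthConfig(K_true=2.89e4, temperatures_K=(298.0,))
        with pytest.raises(qb.ValidationError):
            qb.generate_titration(cfg, 400.0)


class TestThermoRoundTrip:
    def test_vant_hoff_parameters_recovered_noiselessly(self, study_config):
        K_by_T = {}
        for T in study_config.temperatures_K:
            s = qb.apply_correction(qb.generate_titration(study_config.model_copy(update={"noise_sd_rel": 0.0}), T))
            K_by_T[T] = qb.fit_double_log(s).K
        t = qb.fit_vant_hoff(K_by_T)
        assert t.dH0_kJ == pytest.approx(-1.79, rel=1e-6)
        assert t.dS0_J == pytest.approx(79.40, rel=1e-6)

    def test_double_log_estimator_is_median_unbiased(self):
        """At the study design with 1% intensity noise the double-log K is
        median-unbiased.  Individual fits scatter widely (the intercept is
        extrapolated ~5 decades beyond the uM data), so resolving the median
        to a few percent needs thousands of replicates."""
        K_true = 2.89e4
        cfg = qb.SynthConfig(K_true=K_true, temperatures_K=(298.0,), noise_sd_rel=0.01,
                             inner_filter=True, seed=7)
        Ks, ns = [], []
        for rep in range(5000):
            s = qb.apply_correction(qb.generate_titration(cfg, 298.0, replicate=rep))
            b = qb.fit_double_log(s)
            Ks.append(b.K)
            ns.append(b.n)
        assert abs(np.median(Ks) / K_true - 1) < 0.03
        assert abs(np.median(ns) - 1.0) < 0.05


class TestEEMGeneration:
    def test_zero_amplitude_gives_zero_matrix(self):
        eem = qb.generate_eem([(280.0, 340.0, 0.0, (10.0, 10.0))],
                              np.arange(210.0, 351.0, 5.0), np.arange(240.0, 611.0, 5.0))
        assert np.all(eem.intensity == 0.0)

    def test_seed_contract(self):
        grids = (np.arange(210.0, 351.0, 5.0), np.arange(240.0, 611.0, 5.0))
        peaks = [(280.0, 340.0, 1000.0, (10.0, 15.0))]
        a = qb.generate_eem(peaks, *grids, noise_sd_rel=0.05, seed=3)
        b = qb.generate_eem(peaks, *grids, noise_sd_rel=0.05, seed=3)
        c = qb.generate_eem(peaks, *grids, noise_sd_rel=0.05, seed=4)
        assert np.array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(qb.ValidationError):
            qb.generate_eem([(100.0, 340.0, 10.0, (10.0, 10.0))],
                            np.arange(210.0, 351.0, 5.0), np.arange(240.0, 611.0, 5.0))


class TestSyncGeneration:
    def test_quench_fractions_follow_configured_K(self, study_config):
        spectra = qb.generate_sync_series(study_config, 60.0)
        concs = np.array([s.ligand_conc_M for s in spectra])
        peaks = np.array([s.intensities.max() for s in spectra])
        pts = [qb.TitrationPoint(ligand_conc_M=c, F_obs=f, A_ex=0.0, A_em=0.0)
               for c, f in zip(concs, peaks)]
        series = qb.apply_correction(qb.TitrationSeries(1.5e-6, study_config.temperatures_K[0], tuple(pts)))
        K_true = study_config.K_at(study_config.temperatures_K[0])
        assert qb.fit_double_log(series).K == pytest.approx(K_true, rel=1e-6)
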