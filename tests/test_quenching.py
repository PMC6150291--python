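"""Stern-Volmer / Lineweaver-Burk fits, K_q, and mechanism classification."""

import numpy as np
import pytest

import quenchbind as qb
from quenchbind.errors import FitError

CONCS = np.array([0.0, 3.5e-6, 7e-6, 15e-6, 25e-6, 35e-6])


def _static_F(K, F0=1000.0, concs=CONCS):
    """Ideal non-fluorescent-complex intensities: F = F0 / (1 + K*C)."""
    return F0 / (1.0 + K * concs)


class TestSternVolmer:
    def test_exact_linear_input_recovered(self, make_series):
        K = 3.0e4
        s = make_series(CONCS, _static_F(K))
        r = qb.fit_stern_volmer(s)
        assert r.K_sv == pytest.approx(K, rel=1e-12)
        assert r.r2_sv == pytest.approx(1.0, abs=1e-12)
        free = qb.fit_stern_volmer(s, fit_intercept=True)
        assert free.K_sv == pytest.approx(K, rel=1e-9)
        assert free.sv_intercept == pytest.approx(1.0, abs=1e-9)

    def test_constant_intensity_gives_zero_slope(self, make_series):
        s = make_series(CONCS, np.full(CONCS.size, 1000.0))
        assert qb.fit_stern_volmer(s).K_sv == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_series_refused(self, make_series):
        s = make_series(CONCS, _static_F(3e4), corrected=False)
        with pytest.raises(FitError, match="corrected"):
            qb.fit_stern_volmer(s)

    def test_too_few_points_rejected(self, make_series):
        s = make_series([0, 1e-6, 2e-6], [1000, 950, 900])
        with pytest.raises(FitError, match="at least 3"):
            qb.fit_stern_volmer(s)

    def test_synthetic_static_series_round_trip(self, make_series):
        # generator-inversion oracle at the study's 298 K binding constant
        K = 2.89e4
        cfg = qb.SynthConfig(K_true=K, temperatures_K=(298.0,))
        s = qb.apply_correction(qb.generate_titration(cfg, 298.0))
        assert qb.fit_stern_volmer(s).K_sv == pytest.approx(K, rel=1e-9)


class TestLineweaverBurk:
    def test_constructed_input_recovers_K_and_intercept(self, make_series):
        # F0 - F = K*C*F0/(1+K*C)  =>  1/(F0-F) = 1/F0 + (1/(K*F0)) * 1/C
        K, F0 = 2.64e4, 1000.0
        s = make_series(CONCS, F0 / (1.0 + K * CONCS))
        r = qb.fit_lineweaver_burk(s)
        assert r.K_lb == pytest.approx(K, rel=1e-9)
        assert r.r2_lb == pytest.approx(1.0, abs=1e-10)
        est = qb.LineweaverBurkRegressor().fit(CONCS[1:], F0 / (1 + K * CONCS[1:]), F0=F0)
        assert est.intercept_ == pytest.approx(1.0 / F0, rel=1e-9)

    def test_unquenched_point_is_an_error(self, make_series):
        F = _static_F(3e4)
        F[2] = 1000.0  # F == F0 at a nonzero concentration
        s = make_series(CONCS, F)
        with pytest.raises(FitError, match="F >= F0"):
            qb.fit_lineweaver_burk(s)

    def test_agrees_with_stern_volmer_on_ideal_static_data(self, make_series):
        s = make_series(CONCS, _static_F(2.89e4))
        sv = qb.fit_stern_volmer(s).K_sv
        lb = qb.fit_lineweaver_burk(s).K_lb
        assert abs(sv / lb - 1) < 1e-6


class TestQuenchingRateConstant:
    @pytest.mark.parametrize(
        "K_sv, expected_1e13",
        [(2.96e4, 1.10), (2.60e4, 0.96), (0.0, 0.0)],
    )
    def test_reported_values(self, K_sv, expected_1e13):
        kq = qb.quenching_rate_constant(K_sv, 2.7e-9)
        assert round(kq / 1e13, 2) == expected_1e13

    def test_scales_inversely_with_lifetime(self):
        assert qb.quenching_rate_constant(1e4, 1.35e-9) == 2 * qb.quenching_rate_constant(1e4, 2.7e-9)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(FitError):
            qb.quenching_rate_constant(1e4, 0.0)


def _result(T, K_sv, tau0=2.7e-9):
    return qb.QuenchFitResult(temperature_K=T, n_points=5, tau0_s=tau0,
                              K_sv=K_sv, K_q=K_sv / tau0)


class TestClassifyMechanism:
    def test_decreasing_Ksv_above_ceiling_is_static(self):
        # the albumin/antiviral titrations: K_SV falls with T, K_q ~ 1e13
        results = [_result(T, K) for T, K in zip((288, 298, 309), (2.96e4, 2.84e4, 2.75e4))]
        call = qb.classify_mechanism(results)
        assert call.mechanism == "static"
        assert call.evidence["min_K_q_over_ceiling"] > 1

    def test_increasing_Ksv_below_ceiling_is_dynamic(self):
        # tau0 chosen so K_q stays below the diffusion ceiling
        results = [_result(T, K, tau0=1e-6) for T, K in zip((288, 298, 309), (1.0e4, 1.2e4, 1.4e4))]
        assert all(r.K_q < qb.DYNAMIC_QUENCHING_CEILING for r in results)
        assert qb.classify_mechanism(results).mechanism == "dynamic"

    def test_non_monotone_trend_is_indeterminate(self):
        results = [_result(T, K) for T, K in zip((288, 298, 309), (2.0e4, 3.0e4, 2.5e4))]
        assert qb.classify_mechanism(results).mechanism == "indeterminate"

    def test_unordered_temperatures_rejected(self):
        results = [_result(298, 2.8e4), _result(288, 2.9e4)]
        with pytest.raises(FitError, match="increasing temperature"):
            qb.classify_mechanism(results)

    def test_single_temperature_rejected(self):
        with pytest.raises(FitError):
            qb.classify_mechanism([_result(298, 2.8e4)])


class TestNoiseRobustness:
    def test_one_percent_noise_bias_below_three_percent(self):
        """Median K_SV over many noisy replicates stays within 3% of truth."""
        K = 2.89e4
        cfg = qb.SynthConfig(K_true=K, temperatures_K=(298.0,), noise_sd_rel=0.01, seed=42)
        fits = []
        for rep in range(500):
            s = qb.apply_correction(qb.generate_titration(cfg, 298.0, replicate=rep))
            fits.append(qb.fit_stern_volmer(s).K_sv)
        assert abs(np.median(fits) / K - 1) < 0.03
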