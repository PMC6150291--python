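"""Double-log binding fit, van't Hoff thermodynamics, force classification."""

import numpy as np
import pytest

import quenchbind as qb
from quenchbind.errors import FitError

CONCS = np.array([0.0, 3.5e-6, 7e-6, 15e-6, 25e-6, 35e-6])


class TestDoubleLog:
    def test_one_to_one_binding_recovered_exactly(self, make_series):
        K = 2.89e4
        s = make_series(CONCS, 1000.0 / (1.0 + K * CONCS))  # (F0-F)/F = K*C
        b = qb.fit_double_log(s)
        assert b.K == pytest.approx(K, rel=1e-10)
        assert b.n == pytest.approx(1.0, abs=1e-10)
        assert b.r2 == pytest.approx(1.0, abs=1e-12)

    def test_squared_law_doubles_the_slope(self, make_series):
        K = 2.89e4
        ratio = (K * CONCS[1:]) ** 2  # (F0-F)/F = (K*C)^2  =>  n = 2
        F = np.concatenate([[1000.0], 1000.0 / (1.0 + ratio)])
        b = qb.fit_double_log(make_series(CONCS, F))
        assert b.n == pytest.approx(2.0, abs=1e-10)

    def test_concentration_rescaling_leaves_n_invariant(self, make_series):
        K = 2.89e4
        F = 1000.0 / (1.0 + K * CONCS)
        b1 = qb.fit_double_log(make_series(CONCS, F))
        b2 = qb.fit_double_log(make_series(CONCS * 10.0, F))
        assert b2.n == pytest.approx(b1.n, rel=1e-12)
        # intercept shifts by n*log10(c): K scales by c^-n
        assert b2.K == pytest.approx(b1.K / 10.0, rel=1e-9)

    def test_unquenched_point_rejected(self, make_series):
        F = 1000.0 / (1.0 + 2.89e4 * CONCS)
        F[3] = 1000.0
        with pytest.raises(FitError, match="F >= F0"):
            qb.fit_double_log(make_series(CONCS, F))

    def test_noisy_replicates_recover_unit_stoichiometry(self):
        cfg = qb.SynthConfig(K_true=2.89e4, temperatures_K=(298.0,), noise_sd_rel=0.01, seed=7)
        ns = []
        for rep in range(500):
            s = qb.apply_correction(qb.generate_titration(cfg, 298.0, replicate=rep))
            ns.append(qb.fit_double_log(s).n)
        assert 0.95 < np.mean(ns) < 1.05


class TestVantHoff:
    def test_study_constants_reproduce_printed_thermodynamics(self):
        # regression on the reported ACV binding constants
        t = qb.fit_vant_hoff({288.0: 2.97e4, 298.0: 2.89e4, 309.0: 2.82e4})
        assert t.dH0_kJ == pytest.approx(-1.79, abs=0.29)
        assert t.dS0_J == pytest.approx(79.40, abs=0.95)

    def test_temperature_independent_K_is_pure_entropy(self):
        K = 5.0e4
        t = qb.fit_vant_hoff({288.0: K, 298.0: K, 309.0: K})
        assert t.dH0_kJ == pytest.approx(0.0, abs=1e-9)
        assert t.dS0_J == pytest.approx(qb.R_GAS * np.log(K), rel=1e-12)

    def test_two_point_closed_form(self):
        K1, K2, T1, T2 = 2.0e4, 3.0e4, 288.0, 309.0
        slope = (np.log(K2) - np.log(K1)) / (1 / T2 - 1 / T1)
        t = qb.fit_vant_hoff({T1: K1, T2: K2})
        assert t.dH0_kJ == pytest.approx(-qb.R_GAS * slope / 1000.0, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            qb.fit_vant_hoff({298.0: 2.9e4})
        with pytest.raises(FitError):
            qb.fit_vant_hoff({288.0: 2.9e4, 298.0: -1.0})

    def test_noiseless_parameter_recovery(self):
        dH, dS = -1.79, 79.40
        temps = (288.0, 298.0, 309.0)
        K = {T: np.exp(-dH * 1000 / (qb.R_GAS * T) + dS / qb.R_GAS) for T in temps}
        t = qb.fit_vant_hoff(K)
        assert t.dH0_kJ == pytest.approx(dH, rel=1e-6)
        assert t.dS0_J == pytest.approx(dS, rel=1e-6)
        # internal consistency of dG0(T)
        for T in temps:
            assert t.dG0_by_T_kJ[T] == pytest.approx(qb.gibbs_free_energy(t.dH0_kJ, t.dS0_J, T), abs=1e-12)


class TestGibbs:
    @pytest.mark.parametrize(
        "dH, dS, T, expected",
        [(-1.79, 79.40, 298.0, -25.45), (-4.47, 69.95, 298.0, -25.32), (0.0, 0.0, 310.0, 0.0)],
    )
    def test_enthalpy_entropy_route(self, dH, dS, T, expected):
        assert qb.gibbs_free_energy(dH, dS, T) == pytest.approx(expected, abs=0.005)

    def test_equilibrium_constant_route(self):
        assert qb.gibbs_from_K(2.89e4, 298.0) == pytest.approx(-25.45, abs=0.005)
        assert qb.gibbs_from_K(1.0, 298.0) == 0.0

    def test_routes_agree_when_K_generated_from_thermo(self):
        dH, dS = -1.79, 79.40
        for T in (288.0, 298.0, 309.0):
            K = np.exp(-dH * 1000 / (qb.R_GAS * T) + dS / qb.R_GAS)
            assert abs(qb.gibbs_from_K(K, T) - qb.gibbs_free_energy(dH, dS, T)) < 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(FitError):
            qb.gibbs_from_K(-1.0, 298.0)
        with pytest.raises(FitError):
            qb.gibbs_free_energy(-1.79, 79.40, 0.0)


class TestClassifyForces:
    @pytest.mark.parametrize(
        "dH, dS, expected",
        [
            (-1.79, 79.40, "electrostatic"),
            (-4.47, 69.95, "electrostatic"),
            (5.0, 50.0, "hydrophobic"),
            (-10.0, -20.0, "hbond_vdw"),
            (10.0, -5.0, "indeterminate"),
        ],
    )
    def test_rule_table(self, dH, dS, expected):
        assert qb.classify_forces(dH, dS).force_class == expected

    def test_near_zero_flag_marks_possible_hydrogen_bonding(self):
        # |dH| below the 4 kJ/mol threshold: clean electrostatic call
        assert not qb.classify_forces(-1.79, 79.40).near_zero_dH
        # |dH| above it: electrostatic but hydrogen bonding may contribute
        call = qb.classify_forces(-4.47, 69.95)
        assert call.near_zero_dH and "hydrogen bonding" in call.note
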