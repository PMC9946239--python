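"""Membrane model: currents, calcium dynamics, integration, rest, noise."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from paramecium.constants import (CA_REST, FARADAY, RT_OVER_F, V_CILIA,
                                  ca_influx_rate_per_nA)
from paramecium.ephys import (BatchStepper, MembraneState, PulseProtocol,
                              ca_current, ca_h, calcium_derivative,
                              electrode_inject, ghk_factor, kca_current,
                              kd_rates, kir_current, kir_steady,
                              membrane_currents, membrane_derivatives,
                              ou_noise_step, run_protocol, simulate_membrane,
                              steady_state_init, step_euler)
from paramecium.params import (CaChannelParams, CaDynParams, CellParams,
                               ElectrodeParams, KCaParams, NoiseParams,
                               preset)


class TestGhkFactor:
    def test_unity_at_zero_and_continuity(self):
        assert ghk_factor(0.0) == 1.0
        eps = 1e-7
        assert ghk_factor(eps) == pytest.approx(1.0, abs=1e-6)
        assert ghk_factor(-eps) == pytest.approx(1.0, abs=1e-6)

    def test_reference_values_at_unit_argument(self):
        # x = 2V/(RT/F) = +-1  ->  1/(e-1) and e/(e-1)
        V1 = RT_OVER_F / 2.0
        assert ghk_factor(V1) == pytest.approx(1.0 / (math.e - 1.0), rel=1e-12)
        assert ghk_factor(-V1) == pytest.approx(math.e / (math.e - 1.0),
                                                rel=1e-12)

    def test_positive_and_monotone_decreasing(self):
        V = np.linspace(-300.0, 300.0, 4001)
        f = ghk_factor(V)
        assert np.all(f > 0)
        assert np.all(np.diff(f) < 0)

    def test_overflow_safe_tails(self):
        assert ghk_factor(1e5) == 0.0
        assert ghk_factor(-1e5) == pytest.approx(2e5 / RT_OVER_F)


class TestGatingCurves:
    def test_kd_boltzmann_midpoint_and_tau_peak(self, table3):
        kd = table3.kd
        n_inf, tau = kd_rates(kd.VKd, kd)
        assert n_inf == pytest.approx(0.5)
        assert tau == pytest.approx(kd.aKd + kd.bKd)     # cosh(0) = 1
        _, tau_far = kd_rates(kd.VKd + 500.0, kd)
        assert tau_far == pytest.approx(kd.aKd, abs=1e-6)
        # bell shape: strictly below the peak away from the center
        _, tau_off = kd_rates(kd.VKd + 10.0, kd)
        assert kd.aKd < tau_off < kd.aKd + kd.bKd

    def test_kir_midpoint_gives_quarter_conductance(self):
        kir = preset("table1_median").kir
        n = kir_steady(kir.VKir, kir)
        assert n == pytest.approx(0.5)
        assert n ** kir.p_gates == pytest.approx(0.25)


class TestCurrents:
    def test_currents_vanish_at_reversal(self, table3):
        EK = table3.passive.EK
        assert kir_current(EK, 0.7, preset("table1_median").kir, EK) == 0.0
        assert kca_current(EK, 2.0, table3.kca, EK) == 0.0

    def test_kir_median_value_matches_direct_formula(self):
        # independent evaluation of g n_inf^2 (EK - V) at the medians
        kir = preset("table1_median").kir
        EK, V = -48.0, -100.0
        n = 1.0 / (1.0 + math.exp((V - (-120.75)) / 30.23))
        expected = 873.36 * n * n * (EK - V) * 1e-3
        assert kir_current(V, kir_steady(V, kir), kir, EK) == \
            pytest.approx(expected, rel=1e-12)

    def test_ca_inactivation_hill(self, table3):
        ca = table3.ca
        pK = math.log10(ca.KCa / CA_REST)
        assert ca_h(pK, ca) == pytest.approx(0.5)
        ca4 = CaChannelParams(nCa=4.0, KCa=ca.KCa)
        p2 = math.log10(2.0 * ca.KCa / CA_REST)
        assert ca_h(p2, ca4) == pytest.approx(1.0 / 17.0, rel=1e-9)

    def test_ca_current_scale_and_sign(self, table3):
        ca = table3.ca
        # V=0, full activation, negligible calcium -> current = gCa
        assert ca_current(0.0, 1.0, -5.0, ca) == pytest.approx(ca.gCa,
                                                               rel=1e-4)
        V = np.linspace(-80.0, 60.0, 50)
        assert np.all(ca_current(V, 0.5, 0.0, ca) > 0)   # always depolarizing

    def test_kca_hill_midpoint_and_closed_limit(self, table3):
        kca = table3.kca
        pK = math.log10(kca.KKCa / CA_REST)
        I_mid = kca_current(-20.0, pK, kca, -48.0)
        I_full = kca_current(-20.0, pK + 6.0, kca, -48.0)
        assert I_mid == pytest.approx(0.5 * I_full, rel=1e-6)
        assert kca_current(-20.0, -6.0, kca, -48.0) == pytest.approx(0.0,
                                                                     abs=1e-9)
        assert I_full < 0  # hyperpolarizing above EK


class TestCalciumDynamics:
    def test_rest_balance_is_exact(self):
        # J = I_rest/(F v)  <=>  zero derivative at [Ca] = Ca0
        I_rest = 0.0354
        J = I_rest * 1e12 / (FARADAY * V_CILIA)
        d = calcium_derivative(0.0, I_rest, CaDynParams(lambda_=7.79, J=J))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_influx_rate_per_nA(self):
        # 1 nA into 1700 um^3: I/(2Fv) = 3049 uM/s
        assert ca_influx_rate_per_nA() == pytest.approx(3048.8, rel=1e-3)

    def test_rectangular_pulse_charge_conversion(self):
        # 1 nA for 1 ms with removal off raises [Ca] by 3.05 uM
        dyn = CaDynParams(lambda_=0.0, J=0.0)
        pca, dt = 0.0, 1e-3
        for _ in range(1000):
            pca += dt * calcium_derivative(pca, 1.0, dyn) * 1e-3
        dCa = CA_REST * 10 ** pca - CA_REST
        assert dCa == pytest.approx(3.0488, rel=2e-3)

    def test_pca_form_equivalent_to_concentration_form(self):
        """The log-variable formulation integrates the same ODE as the
        direct concentration equation (oracle: tightly converged solve_ivp
        of both forms under a 100 ms calcium-current pulse)."""
        dyn = CaDynParams(lambda_=7.79, J=86.6)
        I_of_t = lambda t: 1.0 * (t < 100.0) * math.exp(-t / 30.0)  # nA, t ms
        rate = ca_influx_rate_per_nA() * 1e-3                       # uM/ms

        def conc_form(t, y):
            Ca = y[0]
            return [I_of_t(t) * rate - dyn.lambda_ * 1e-3 * (Ca - CA_REST)
                    - dyn.J * 1e-3 / (1.0 + CA_REST / Ca)]

        def pca_form(t, y):
            return [calcium_derivative(y[0], I_of_t(t), dyn) * 1e-3]

        kw = dict(rtol=1e-12, atol=1e-14, dense_output=False, method="LSODA",
                  t_eval=np.linspace(0.0, 100.0, 201))
        a = solve_ivp(conc_form, (0.0, 100.0), [CA_REST], **kw)
        b = solve_ivp(pca_form, (0.0, 100.0), [0.0], **kw)
        Ca_b = CA_REST * 10.0 ** b.y[0]
        assert np.max(np.abs(a.y[0] - Ca_b)) < 1e-6


class TestIntegration:
    def test_zero_derivatives_leave_state_unchanged(self, balanced3):
        state, params = balanced3
        new = step_euler(state.copy(), params, I_ext=0.0, dt=0.1)
        assert float(new.V) == pytest.approx(float(state.V), abs=1e-12)
        assert float(new.pCa) == pytest.approx(float(state.pCa), abs=1e-12)

    def test_pure_leak_decays_with_rc_time_constant(self):
        cell = CellParams()
        cell.kd.gKd = 0.0
        cell.ca.gCa = 0.0
        cell.kca.gKCa = 0.0
        _, cell = steady_state_init(cell, balance=False)
        tau = cell.passive.C / cell.passive.gL     # pF/nS = ms
        st = MembraneState(V=cell.passive.EL + 10.0, pCa=0.0)
        T = tau  # decay for one time constant
        n = int(T / 0.01)
        for _ in range(n):
            st = step_euler(st, cell, dt=0.01)
        dV = float(st.V) - cell.passive.EL
        assert dV == pytest.approx(10.0 * math.exp(-1.0), rel=1e-3)

    def test_dt_halving_changes_peak_by_less_than_1pct(self, table3):
        pr1 = PulseProtocol([1.5], duration=100.0, t_post=200.0, dt=0.1)
        pr2 = PulseProtocol([1.5], duration=100.0, t_post=200.0, dt=0.05)
        v1 = run_protocol(table3, pr1)[0].V.max()
        v2 = run_protocol(table3, pr2)[0].V.max()
        assert abs(v1 - v2) / abs(v2) < 0.01

    def test_nonfinite_state_raises(self, table3):
        st = MembraneState(V=np.inf)
        with pytest.raises(FloatingPointError):
            step_euler(st, table3)

    def test_gating_stays_in_unit_interval_under_random_protocols(
            self, table3, rng):
        """Gating bounds hold for arbitrary (strong, bipolar) stimuli."""
        for _ in range(3):
            I = rng.uniform(-6.0, 6.0, size=(3000, 4)) * \
                (rng.random((3000, 4)) < 0.02)
            I = np.cumsum(I, axis=0) * 0.0 + I  # sparse impulses
            st, params = steady_state_init(table3)
            state = MembraneState(V=np.full(4, st.V), nKd=np.full(4, st.nKd),
                                  mCa=np.full(4, st.mCa),
                                  pCa=np.full(4, st.pCa), In=np.zeros(4))
            for i in range(0, 3000, 50):
                state = step_euler(state, params, I_ext=I[i], dt=0.1)
                for g in (state.nKd, state.mCa, state.nKir):
                    assert np.all((np.asarray(g) >= 0.0)
                                  & (np.asarray(g) <= 1.0))


class TestRestingState:
    def test_default_cell_rests_at_configured_potential(self, balanced3):
        state, params = balanced3
        assert float(state.V) == params.V_rest
        assert float(state.Ca()) == pytest.approx(CA_REST)
        d = membrane_derivatives(state, params)
        for key, val in d.items():
            assert abs(float(val)) < 1e-9, key

    def test_leak_only_cell_rests_at_EL(self):
        cell = CellParams()
        cell.kd.gKd = 0.0
        cell.ca.gCa = 0.0
        cell.kca.gKCa = 0.0
        st, bal = steady_state_init(cell, balance=False)
        assert float(st.V) == pytest.approx(cell.passive.EL, abs=1e-8)

    def test_ten_second_noise_free_persistence(self, balanced3):
        state, params = balanced3
        st = state.copy()
        stepper = BatchStepper(params)
        stepper.run(st, 0.0, 0.1, 100_000)     # 10 s
        assert abs(float(st.V) - float(state.V)) < 0.01
        assert abs(float(st.Ca()) - CA_REST) < 1e-3


class TestNoiseAndElectrode:
    def test_ou_deterministic_decay_with_zero_sigma(self):
        p = NoiseParams(tau_n=20.0, sigma_n=0.0)
        rng = np.random.default_rng(0)
        x = ou_noise_step(8.0, 10.0, p, rng)
        assert x == pytest.approx(8.0 * math.exp(-0.5))

    def test_ou_stationary_sd_and_autocorrelation(self):
        p = NoiseParams(tau_n=20.0, sigma_n=9.0)
        rng = np.random.default_rng(7)
        n_lanes, n_steps, dt = 4000, 400, 1.0
        x = np.zeros(n_lanes)
        xs = []
        for _ in range(n_steps):
            x = ou_noise_step(x, dt, p, rng, size=n_lanes)
            xs.append(x.copy())
        tail = np.array(xs[100:])
        sd = tail.std()
        assert sd == pytest.approx(9.0, rel=0.03)
        lag = 10
        a, b = tail[:-lag].ravel(), tail[lag:].ravel()
        rho = np.corrcoef(a, b)[0, 1]
        assert rho == pytest.approx(math.exp(-lag * dt / p.tau_n), abs=0.02)

    def test_electrode_steady_state_and_offset_invariance(self):
        p = ElectrodeParams(Re=121.0, tau_e=1.0, dV=7.0)
        V, V2, I = -22.0, -22.0 + 121.0 * 0.4 + 7.0, 0.4
        V2n, Ie = electrode_inject(I, V, V2, p, dt=0.1)
        assert Ie == pytest.approx(I, rel=1e-12)        # fixed point
        p0 = ElectrodeParams(Re=121.0, tau_e=1.0, dV=0.0)
        _, Ie0 = electrode_inject(I, V, V2 - 7.0, p0, dt=0.1)
        assert Ie0 == pytest.approx(Ie, rel=1e-12)      # dV cancels

    def test_electrode_current_approaches_command_exponentially(self):
        p = ElectrodeParams(Re=100.0, tau_e=2.0)
        V, V2 = -20.0, -20.0
        dt, I = 0.01, 1.0
        ts, Ies = [], []
        t = 0.0
        for _ in range(1000):
            V2, Ie = electrode_inject(I, V, V2, p, dt)
            t += dt
            ts.append(t)
            Ies.append(Ie)
        Ies = np.array(Ies)
        expected = I * (1.0 - np.exp(-np.array(ts) / p.tau_e))
        assert np.max(np.abs(Ies - expected)) < 1e-9


class TestProtocols:
    def test_zero_amplitude_gives_flat_trace(self, table3):
        tr = run_protocol(table3, PulseProtocol([0.0], t_post=100.0))[0]
        assert np.ptp(tr.V) < 1e-6
        assert np.ptp(tr.Ca) < 1e-9

    def test_inward_rectifier_activates_only_below_EK(self):
        cell = preset("table1_median")
        # -0.1 nA keeps V above EK (input resistance ~125 MOhm); -4 nA
        # drives it far below
        pr = PulseProtocol([-0.1, -4.0], duration=100.0, t_post=150.0)
        weak, strong = run_protocol(cell, pr)
        EK = cell.passive.EK
        assert weak.V.min() > EK       # small pulse stays above EK
        assert strong.V.min() < EK
        assert np.abs(weak.currents["I_Kir"]).max() < \
            0.1 * np.abs(strong.currents["I_Kir"]).max()

    def test_depolarizing_pulse_evokes_transient_calcium_current(self, table3):
        """A 1.5 nA pulse drives a transient inward (depolarizing) calcium
        current of order a few nA, peaking within a few ms of onset."""
        pr = PulseProtocol([1.5], duration=100.0, t_pre=100.0, t_post=500.0)
        tr = run_protocol(table3, pr)[0]
        ICa = tr.currents["I_Ca"]
        peak = ICa.max()
        assert 0.5 < peak < 5.0
        t_peak = tr.t[np.argmax(ICa)]
        assert 100.0 < t_peak < 120.0
        # transient: falls well below peak during the pulse
        assert ICa[(tr.t > 150.0) & (tr.t < 200.0)].max() < 0.5 * peak

    def test_ciliary_reversal_outlasts_the_pulse(self, table3):
        pr = PulseProtocol([1.5], duration=100.0, t_pre=100.0, t_post=500.0)
        tr = run_protocol(table3, pr)[0]
        reversed_ = tr.alpha > 90.0
        assert reversed_.any()
        assert tr.t[reversed_][-1] > 200.0     # beyond pulse end
        assert tr.Ca.max() > table3.electromotor.Kmotor
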