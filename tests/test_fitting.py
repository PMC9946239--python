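"""Fitting harness: electrode recovery, QC, determinism, model variants.

The heavier staged recoveries (hyperpolarized, deciliated, ciliated) run in
the acceptance suite; here the machinery itself is exercised at small
problem sizes.
"""

import numpy as np
import pytest

import paramecium.fitting as F
from paramecium.ephys import PulseProtocol
from paramecium.params import CellParams, ElectrodeParams, preset


def _passive_cell():
    cell = preset("table3_median").copy()
    cell.kd.gKd = 0.0
    cell.ca.gCa = 0.0
    cell.kca.gKCa = 0.0
    cell.kir_enabled = False
    return cell


@pytest.fixture(scope="module")
def electrode_ds():
    return F.generate_synthetic_dataset(
        _passive_cell(), PulseProtocol([-0.3, 0.3], duration=100.0,
                                       t_post=100.0),
        electrode=ElectrodeParams(Re=121.0, tau_e=1.0, dV=5.0), seed=11)


class TestElectrodeFit:
    def test_noiseless_recovery_within_1pct(self, electrode_ds):
        res = F.fit_electrode(electrode_ds)
        assert res.values["Re"] == pytest.approx(121.0, rel=0.01)
        assert res.values["tau_e"] == pytest.approx(1.0, rel=0.01)

    def test_tip_potential_offset_does_not_bias_Re_tau(self):
        ds0 = F.generate_synthetic_dataset(
            _passive_cell(), PulseProtocol([-0.3, 0.3], t_post=100.0),
            electrode=ElectrodeParams(Re=121.0, tau_e=1.0, dV=0.0), seed=11)
        r0 = F.fit_electrode(ds0)
        r5 = F.fit_electrode(F.generate_synthetic_dataset(
            _passive_cell(), PulseProtocol([-0.3, 0.3], t_post=100.0),
            electrode=ElectrodeParams(Re=121.0, tau_e=1.0, dV=5.0), seed=11))
        assert r5.values["Re"] == pytest.approx(r0.values["Re"], rel=0.01)
        assert r5.values["tau_e"] == pytest.approx(r0.values["tau_e"],
                                                   rel=0.02)

    def test_recovery_under_measurement_noise(self):
        ds = F.generate_synthetic_dataset(
            _passive_cell(), PulseProtocol([-0.3, 0.3], t_post=100.0),
            electrode=ElectrodeParams(Re=121.0, tau_e=1.0), noise_sd=0.5,
            seed=13)
        res = F.fit_electrode(ds)
        assert res.values["Re"] == pytest.approx(121.0, rel=0.05)
        assert res.values["tau_e"] == pytest.approx(1.0, rel=0.05)

    def test_objective_history_monotone_nonincreasing(self, electrode_ds):
        res = F.fit_electrode(electrode_ds)
        h = np.array(res.history)
        assert np.all(np.diff(h) <= 0)


class TestSyntheticGeneration:
    def test_identical_seeds_are_byte_identical(self):
        kw = dict(noise_sd=0.4, seed=77)
        pr = PulseProtocol([0.5], duration=50.0, t_post=50.0)
        a = F.generate_synthetic_dataset(preset("table2_median"), pr, **kw)
        b = F.generate_synthetic_dataset(preset("table2_median"), pr, **kw)
        np.testing.assert_array_equal(a.traces[0].V_read, b.traces[0].V_read)
        np.testing.assert_array_equal(a.traces[0].V_inject,
                                      b.traces[0].V_inject)

    def test_angle_series_crosses_reversal_on_suprathreshold_pulse(self):
        ds = F.generate_synthetic_dataset(
            preset("table3_median"),
            PulseProtocol([2.0], duration=100.0, t_post=300.0),
            with_angles=True, balance=True, seed=0)
        alpha = np.deg2rad(ds.angles[0].alpha_deg)
        assert np.cos(alpha).max() > 0 and np.cos(alpha).min() < 0


class TestQC:
    def _result(self, cell):
        return F.FitResult(cell=cell, electrode=ElectrodeParams(),
                           values={}, rms_mV=0.0)

    def test_large_capacitance_rejected(self):
        cell = preset("table1_median").copy()
        cell.passive.C = 600.0
        qc = F.qc_filter(self._result(cell))
        assert not qc["passed"]
        assert any("500 pF" in r for r in qc["reasons"])

    def test_reversed_potassium_gradient_rejected(self):
        cell = preset("table1_median").copy()
        cell.passive.EK = -40.0
        cell.passive.EL = -45.0
        qc = F.qc_filter(self._result(cell))
        assert not qc["passed"]
        assert any("impossible" in r for r in qc["reasons"])

    def test_median_parameters_pass(self):
        cell = preset("table1_median").copy()
        from paramecium.ephys import steady_state_init
        _, cell = steady_state_init(cell, balance=False)
        qc = F.qc_filter(self._result(cell))
        assert qc["passed"], qc["reasons"]
        assert 30.0 < qc["R_MOhm"] < 500.0


class TestDeciliatedVariants:
    def test_flat_dataset_flagged_degenerate(self):
        # hand-built flat sweeps: no excitable response at all
        cell = preset("table2_median")
        pr = PulseProtocol([0.3, 0.6], duration=50.0, t_pre=100.0,
                           t_post=50.0)
        t = np.arange(0.0, pr.total, pr.dt)
        I = pr.command(t)
        traces = [F.CurrentClampTrace(
            t=t.copy(), I_command=I[:, j],
            V_read=np.full_like(t, -22.0),
            V_inject=np.full_like(t, -22.0), amplitude=a)
            for j, a in enumerate(pr.amplitudes)]
        ds = F.Dataset(traces=traces, protocol=pr, truth=cell,
                       truth_electrode=cell.electrode)
        spec = F.FitSpec(free={"kd.gKd": (10.0, 200.0)}, ls_max_nfev=3)
        res = F.fit_deciliated(ds, C=cell.passive.C, EK=cell.passive.EK,
                               spec=spec)
        assert res.degenerate

    def test_simplified_variant_costs_little_on_unsimplified_truth(self):
        """Forcing VtauKd=VKd and ktauKd=2 kKd on data whose tau curve is
        centered elsewhere raises the error, but by less than 2x (nested
        model with a nearly flat likelihood along the tau parameters)."""
        cell = preset("table2_median")    # VtauKd=23.09 != VKd, unsimplified
        pr = PulseProtocol([1.0, 2.0, 3.0, 4.0], duration=100.0, t_post=100.0)
        ds = F.generate_synthetic_dataset(cell, pr, seed=1)
        x0 = {"passive.gL": 11.0, "passive.EL": -20.0, "kd.gKd": 150.0,
              "kd.VKd": 25.0, "kd.kKd": 8.0, "kd.bKd": 5.0}
        free = {"passive.gL": (1.0, 50.0), "passive.EL": (-40.0, -5.0),
                "kd.gKd": (10.0, 5000.0), "kd.VKd": (-20.0, 60.0),
                "kd.kKd": (1.0, 25.0), "kd.bKd": (0.5, 30.0)}
        full_x0 = dict(x0, **{"kd.VtauKd": 25.0, "kd.ktauKd": 14.0})
        full_free = dict(free, **{"kd.VtauKd": (-20.0, 80.0),
                                  "kd.ktauKd": (2.0, 40.0)})
        r_full = F.fit_deciliated(
            ds, C=cell.passive.C, EK=cell.passive.EK,
            spec=F.FitSpec(free=full_free, x0=full_x0, ls_max_nfev=60))
        r_simp = F.fit_deciliated(
            ds, C=cell.passive.C, EK=cell.passive.EK, simplified=True,
            spec=F.FitSpec(free=free, x0=x0, ls_max_nfev=60))
        assert r_simp.rms_mV >= r_full.rms_mV - 1e-9
        assert r_simp.rms_mV < max(2.0 * max(r_full.rms_mV, 0.05), 0.5)


def test_log_parameterization_round_trip():
    spec = F.FitSpec(free={"ca.gCa": (10.0, 1000.0), "ca.VCa": (-20.0, 20.0)})
    x = spec.encode({"ca.gCa": 226.63, "ca.VCa": -1.33})
    back = spec.decode(x)
    assert back["ca.gCa"] == pytest.approx(226.63, rel=1e-12)
    assert back["ca.VCa"] == pytest.approx(-1.33)


def test_set_get_param_paths():
    cell = CellParams()
    F.set_param(cell, "kd.VKd", 12.5)
    assert F.get_param(cell, "kd.VKd") == 12.5
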