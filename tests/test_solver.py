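import numpy as np
import pytest

from ephapsim import (ChannelSet, CurrentInjection, FieldSpec, PassiveSpec,
                      SolverConfig, assemble, build_membrane, detect_spikes,
                      place_synapses, run, steady_state_attenuation,
                      uniform_cylinder)
from ephapsim.solver import NumericalError
from ephapsim.stimulation import assign_onsets


def _passive_membrane(n=10, length=200.0, diam=1.0):
    model = uniform_cylinder(n, length, diam)
    return build_membrane(model, ChannelSet("passive", []),
                          PassiveSpec(tau_m=28.0, Rm=28.0, Ra=150.0, Cm=1.0))


def _psp_system(membrane, v_o=0.0, f_s=0.8, phi_s=3 * np.pi / 10, seed=3,
                rate=2750.0, region="basal"):
    rng = np.random.default_rng(seed)
    pl = place_synapses(membrane.model, 100, region, rng)
    assign_onsets(pl, rate, 1100.0, rng)
    f = FieldSpec(v_o=v_o, f_t=10.0, f_s=f_s, phi_s=phi_s) if v_o > 0 else None
    return assemble(membrane, pl, [], f)


class TestPassiveLimits:
    def test_rest_is_equilibrium(self, passive_cylinder):
        res = run(assemble(passive_cylinder, [], [], None),
                  SolverConfig(dt=0.025, duration=200.0, settle=0.0))
        assert np.max(np.abs(res.vm[0] + 65.0)) < 1e-9

    def test_static_uniform_field_leaves_membrane_at_rest(self):
        mem = _passive_membrane(n=2)
        # f_s = 0, phi_s = pi/2: V_e identical in both compartments
        f = FieldSpec(v_o=4.0, f_t=10.0, f_s=0.0, phi_s=np.pi / 2)
        res = run(assemble(mem, [], [], f),
                  SolverConfig(dt=0.025, duration=300.0, settle=0.0, record=(1,)))
        for c in (0, 1):
            assert np.max(np.abs(res.vm[c] + 65.0)) < 1e-9

    def test_isolated_compartment_ignores_any_field(self):
        # no axial neighbors: only V_i follows V_e, V_m is untouched
        mem = _passive_membrane(n=1)
        f = FieldSpec(v_o=4.0, f_t=10.0, f_s=0.8, phi_s=0.7)
        res = run(assemble(mem, [], [], f),
                  SolverConfig(dt=0.025, duration=300.0, settle=0.0))
        assert np.max(np.abs(res.vm[0] + 65.0)) < 1e-9
        vi = res.v_i(0, mem.model.x_mm[0])
        assert np.max(np.abs(vi - res.vm[0])) > 1.0  # V_i does follow the field

    def test_subthreshold_response_linear_in_amplitude(self):
        mem = _passive_membrane(n=20, length=1000.0)
        out = {}
        for v_o in (1.0, 2.0):
            f = FieldSpec(v_o=v_o, f_t=10.0, f_s=0.8, phi_s=np.pi / 4)
            res = run(assemble(mem, [], [], f),
                      SolverConfig(dt=0.05, duration=300.0, settle=200.0))
            out[v_o] = res.vm[0] + 65.0
        scale = np.max(np.abs(out[2.0]))
        assert scale > 1e-3  # the gradient actually polarizes the cable
        assert np.max(np.abs(out[2.0] - 2 * out[1.0])) < 1e-6 * scale

    def test_charge_balance_residual(self):
        """The discrete update satisfies the implicit balance each step."""
        mem = _passive_membrane(n=5)
        f = FieldSpec(v_o=2.0, f_t=10.0, f_s=0.8, phi_s=0.3)
        cfg = SolverConfig(dt=0.1, duration=50.0, settle=0.0,
                           record=tuple(range(5)))
        res = run(assemble(mem, [], [], f), cfg)
        model = mem.model
        inv_r = np.zeros(5)
        inv_r[1:] = 1.0 / model.r_axial[1:]
        vm = np.array([res.vm[i] for i in range(5)])
        for step in range(1, vm.shape[1]):
            t = res.t[step]
            ve = f.evaluate(model.x_mm, t)
            v_new, v_old = vm[:, step], vm[:, step - 1]
            resid = mem.cap_nF / cfg.dt * (v_new - v_old) \
                + mem.g_pas_uS * (v_new + 65.0)
            for i in range(1, 5):
                ax = inv_r[i] * ((v_new[i] + ve[i]) - (v_new[i - 1] + ve[i - 1]))
                resid[i] += ax
                resid[i - 1] -= ax
            scale = np.max(np.abs(mem.g_pas_uS * (v_new + 65.0))) + 1e-12
            assert np.max(np.abs(resid)) < max(1e-9, 1e-9 * scale)


class TestCableOracle:
    @pytest.mark.parametrize("n_comp", [20, 30])
    def test_steady_state_attenuation_matches_cosh(self, n_comp):
        x, profile = steady_state_attenuation(n_comp=n_comp, length_um=1000.0,
                                              diam_um=1.0, Rm=28.0, Ra=150.0)
        lam = np.sqrt(28e3 * 1e-4 / (4 * 150.0)) * 1e4  # um
        pred = np.cosh((1000.0 - x) / lam) / np.cosh((1000.0 - x[0]) / lam)
        meas = profile / profile[0]
        assert np.max(np.abs(meas - pred) / pred) < 0.01

    def test_short_cable_is_isopotential(self):
        x, profile = steady_state_attenuation(n_comp=20, length_um=10.0)
        assert np.max(profile) / np.min(profile) < 1.001


class TestActiveDynamics:
    def test_uniform_field_leaves_spikes_unchanged(self, ca3_membrane):
        base = run(_psp_system(ca3_membrane, v_o=0.0),
                   SolverConfig(duration=1000.0)).spike_times
        unif = run(_psp_system(ca3_membrane, v_o=4.0, f_s=0.0, phi_s=np.pi / 2),
                   SolverConfig(duration=1000.0)).spike_times
        assert len(base) == len(unif)
        assert len(base) > 3
        assert np.max(np.abs(base - unif)) <= 0.025  # within one dt

    def test_determinism_bit_identical(self, ca3_membrane):
        a = run(_psp_system(ca3_membrane, v_o=2.0, seed=9),
                SolverConfig(duration=500.0)).spike_times
        b = run(_psp_system(ca3_membrane, v_o=2.0, seed=9),
                SolverConfig(duration=500.0)).spike_times
        assert np.array_equal(a, b)

    def test_dt_convergence_of_spike_times(self, ca1_membrane):
        """Halving the 25 us step moves every tonic spike by less than 0.5 ms.

        Asserted on the tonically firing injection configuration (with and
        without the field); synaptically driven runs are chaotic, so their
        individual spike times cannot converge pointwise — see the companion
        statistical test below.
        """
        for v_o in (0.0, 4.0):
            f = FieldSpec(v_o=v_o, f_t=10.0) if v_o else None
            sys_ = assemble(ca1_membrane, [],
                            [CurrentInjection(0, 0.2, 0.0, 1200.0)], f)
            coarse = run(sys_, SolverConfig(dt=0.025, duration=1000.0,
                                            method="crank_nicolson")).spike_times
            fine = run(sys_, SolverConfig(dt=0.0125, duration=1000.0,
                                          method="crank_nicolson")).spike_times
            assert len(coarse) == len(fine)
            assert len(coarse) > 5
            assert np.max(np.abs(coarse - fine)) < 0.5

    def test_dt_stability_of_psp_driven_statistics(self, ca3_membrane):
        """For synaptic drive the step-size check is statistical: halving dt
        leaves the spike count essentially unchanged."""
        sys_ = _psp_system(ca3_membrane, v_o=4.0, seed=3)
        coarse = run(sys_, SolverConfig(dt=0.025, duration=1000.0)).spike_times
        fine = run(sys_, SolverConfig(dt=0.0125, duration=1000.0)).spike_times
        assert len(coarse) > 3
        assert abs(len(coarse) - len(fine)) <= 1

    def test_crank_nicolson_matches_steady_state(self):
        mem = _passive_membrane(n=5)
        inj = [CurrentInjection(0, 0.01, 0.0, 1000.0)]
        out = {}
        for method in ("implicit_euler", "crank_nicolson"):
            res = run(assemble(mem, [], inj, None),
                      SolverConfig(dt=0.05, duration=500.0, settle=0.0,
                                   method=method))
            out[method] = res.vm[0][-1]
        assert out["crank_nicolson"] == pytest.approx(out["implicit_euler"],
                                                      abs=1e-6)

    def test_somatic_step_evokes_spike(self, ca3_membrane):
        res = run(assemble(ca3_membrane, [],
                           [CurrentInjection(0, 0.35, 0.0, 800.0)], None),
                  SolverConfig(duration=600.0))
        assert len(res.spike_times) >= 1
        assert res.vm[res.soma_index].max() > 0.0


class TestSpikeDetection:
    def test_interpolated_crossing_and_refractory(self):
        t = np.arange(0, 20.0, 0.5)
        trace = np.full_like(t, -65.0)
        trace[10] = 10.0   # crossing between 4.5 and 5.0 ms
        trace[12] = 20.0   # within the 2 ms lockout
        trace[30] = 5.0    # second spike at ~15 ms
        spikes = detect_spikes(trace, t)
        assert len(spikes) == 2
        assert 4.5 < spikes[0] < 5.0
        assert 14.5 < spikes[1] < 15.0

    def test_no_spikes_below_threshold(self):
        t = np.arange(0, 10, 0.1)
        assert detect_spikes(np.full_like(t, -30.0), t).size == 0


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0)
        with pytest.raises(ValueError):
            SolverConfig(settle=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(method="rk4")
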