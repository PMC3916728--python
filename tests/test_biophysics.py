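import numpy as np
import pytest
import yaml

from ephapsim import (ChannelSet, PassiveSpec, build_membrane, ca1_channel_set,
                      ca1_passive, ca3_channel_set, ca3_passive,
                      channel_set_from_dict, channel_set_to_dict, gating_step,
                      ionic_current, uniform_cylinder)
from ephapsim.biophysics import V_GRID, GatingVariable, REQUIRED_CHANNELS


class TestPassive:
    def test_ca1_time_constant_is_exact(self):
        p = ca1_passive()
        assert p.Rm * p.Cm == 28.0
        assert p.tau_m == 28.0

    def test_ca3_time_constant(self):
        p = ca3_passive()
        assert p.Rm * p.Cm == pytest.approx(35.0, rel=1e-12)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            PassiveSpec(tau_m=28.0, Rm=28.0, Ra=150.0, Cm=2.0)
        with pytest.raises(ValueError):
            PassiveSpec(tau_m=-1.0, Rm=1.0, Ra=150.0, Cm=-1.0)


def _all_v_gates():
    for cs in (ca1_channel_set(), ca3_channel_set()):
        for ch in cs.channels:
            for gv in ch.gates:
                if gv.kind == "v":
                    yield f"{cs.label}.{ch.name}.{gv.name}", gv


@pytest.mark.parametrize("label, gate", list(_all_v_gates()))
class TestGatingFunctions:
    def test_steady_state_bounded_and_finite(self, label, gate):
        inf = np.asarray(gate.minf(V_GRID))
        assert np.all(np.isfinite(inf)), label
        assert np.all((inf >= 0) & (inf <= 1)), label

    def test_time_constant_positive_and_finite(self, label, gate):
        tau = np.asarray(gate.tau(V_GRID))
        assert np.all(np.isfinite(tau)), label
        assert np.all(tau > 0), label

    def test_continuity_on_dense_grid(self, label, gate):
        # no singular rate ratios: adjacent 0.05 mV samples stay close
        inf = np.asarray(gate.minf(V_GRID))
        tau = np.asarray(gate.tau(V_GRID))
        assert np.max(np.abs(np.diff(inf))) < 0.01, label
        assert np.max(np.abs(np.diff(tau)) / np.maximum(tau[:-1], 1e-6)) < 0.2, label


class TestGatingStep:
    def setup_method(self):
        self.gate = GatingVariable("n", "borg",
                                   dict(vh=13.0, zeta=-3.0, gm=0.7, a0=0.02))

    def test_fixed_point(self):
        v = -40.0
        m = float(self.gate.minf(v))
        assert gating_step(m, v, 0.1, self.gate) == pytest.approx(m, rel=1e-12)

    def test_relaxation_to_steady_state(self):
        v = -30.0
        m = 0.0
        for _ in range(5000):
            m = gating_step(m, v, 1.0, self.gate)
        assert m == pytest.approx(float(self.gate.minf(v)), abs=1e-6)

    def test_one_tau_step_closed_form(self):
        # inf -> 1 far above vh; tau = tau0 = 5 ms; dt = tau from m = 0
        gate = GatingVariable("x", "boltz_belltau",
                              dict(vh=0.0, k=1.0, tau0=5.0, amp=0.0, vth=0.0,
                                   s1=1.0, s2=1.0))
        m = gating_step(0.0, 1000.0, 5.0, gate)
        assert m == pytest.approx(1 - np.e ** -1, rel=1e-6)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            gating_step(0.5, -65.0, 0.0, self.gate)


class TestIonicCurrent:
    def test_zero_conductance(self):
        assert ionic_current(0.0, -50.0, 2.0, -77.0) == 0.0

    def test_zero_driving_force(self):
        assert ionic_current(5.0, -75.0, 2.0, -77.0) == 0.0

    def test_known_value(self):
        # 10 nS, V_i = -50, V_e = 2, V_k = -77 -> 0.01 uS * 25 mV = 0.25 nA
        assert ionic_current(0.01, -50.0, 2.0, -77.0) == pytest.approx(0.25)

    def test_linear_in_conductance_and_driving_force(self, rng):
        g = rng.uniform(0, 1, 50)
        vi = rng.uniform(-80, 40, 50)
        i1 = ionic_current(g, vi, 1.0, -77.0)
        assert np.allclose(ionic_current(2 * g, vi, 1.0, -77.0), 2 * i1)
        # superposition over the driving-force terms
        assert np.allclose(i1, ionic_current(g, vi, 0.0, 0.0)
                           - ionic_current(g, 1.0, 0.0, 0.0)
                           - ionic_current(g, -77.0, 0.0, 0.0))


class TestChannelSets:
    def test_required_channels_present(self):
        assert ca1_channel_set().names() >= REQUIRED_CHANNELS["CA1"]
        assert ca3_channel_set().names() >= REQUIRED_CHANNELS["CA3"]

    def test_ca3_has_calcium_pool_and_ca_gates(self):
        cs = ca3_channel_set()
        assert cs.ca_pool is not None
        kinds = {gv.kind for ch in cs.channels for gv in ch.gates}
        assert {"v", "ca", "vca"} <= kinds

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            from ephapsim.biophysics import ChannelSpec
            ChannelSpec("bad", -1e-3, -90.0, [])


class TestBuildMembrane:
    def test_dendrites_carry_full_ca1_set(self, ca1_membrane):
        model = ca1_membrane.model
        dend = np.isin(model.structure, [3, 4])
        for name in ("na", "kdr", "ka", "h"):
            assert np.all(ca1_membrane.gbar_uS[name][dend] > 0)

    def test_axon_carries_only_na_kdr(self, ca1_membrane):
        model = ca1_membrane.model
        axon = model.structure == 2
        assert axon.any()
        assert np.all(ca1_membrane.gbar_uS["na"][axon] > 0)
        assert np.all(ca1_membrane.gbar_uS["kdr"][axon] > 0)
        assert np.all(ca1_membrane.gbar_uS["ka"][axon] == 0)
        assert np.all(ca1_membrane.gbar_uS["h"][axon] == 0)

    def test_ka_and_h_gradients_increase_distally(self, ca1_membrane):
        model = ca1_membrane.model
        apical = model.structure == 4
        dist = ca1_membrane.path_um[apical]
        for name in ("ka", "h"):
            density = ca1_membrane.gbar_uS[name][apical] / model.area[apical]
            prox = density[dist < 100].mean()
            far = density[dist > 400].mean()
            assert far > 2 * prox

    def test_passive_input_conductance_is_area_over_rm(self):
        model = uniform_cylinder(1, 100.0, 2.0)
        p = PassiveSpec(tau_m=28.0, Rm=28.0, Ra=150.0, Cm=1.0)
        mem = build_membrane(model, ChannelSet("passive", []), p)
        # g = area/Rm: area cm^2 * 1e3/kOhm cm^2 -> uS
        assert mem.g_pas_uS[0] == pytest.approx(model.area[0] * 1e3 / 28.0)

    def test_unknown_override_rejected(self, ca3_model):
        with pytest.raises(KeyError):
            build_membrane(ca3_model, ca3_channel_set(), ca3_passive(),
                           density_overrides={"nax": 1e-3})


class TestConfigRoundTrip:
    @pytest.mark.parametrize("factory", [ca1_channel_set, ca3_channel_set])
    def test_yaml_roundtrip_preserves_gating(self, factory):
        cs = factory()
        text = yaml.safe_dump(channel_set_to_dict(cs))
        cs2 = channel_set_from_dict(yaml.safe_load(text))
        assert cs2.label == cs.label
        assert cs2.names() == cs.names()
        v = np.linspace(-100, 40, 57)
        for ch, ch2 in zip(cs.channels, cs2.channels):
            assert ch2.gbar == ch.gbar and ch2.erev == ch.erev
            for g, g2 in zip(ch.gates, ch2.gates):
                if g.kind == "v":
                    assert np.allclose(g2.minf(v), g.minf(v))
                    assert np.allclose(g2.tau(v), g.tau(v))
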