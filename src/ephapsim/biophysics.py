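"""Passive membrane properties and CA1/CA3 active conductance sets.

The two hippocampal channel repertoires follow the standard published
functional forms for these channel families (thermodynamic/Borg-Graham rate
models for the K channels, trap-style Na kinetics, a Moczydlowski-Latorre
two-state model for the Ca-activated BK current and a submembrane calcium
pool driving the slow AHP current).  All rate functions are finite and
continuous on the physiological voltage range; every parameter lives in the
tables below and can be round-tripped through YAML/JSON.

Sign conventions: outward current positive; every transmembrane element sees
the *membrane* potential V_m = V_i - V_e, so the current through channel k is

    I_k = gbar_k * (gating product) * (V_i - V_e - V_k)

which reduces to the textbook Hodgkin-Huxley current when the extracellular
potential V_e is zero.

Units: mV, ms, nA, uS, nF, MOhm, mM; densities in S/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import yaml

from .morphology import CompartmentalModel, Structure

V_GRID = np.arange(-120.0, 60.0 + 1e-9, 0.05)  # mV, gating lookup grid
_FRT = 0.03780  # F/RT at 34 C, 1/mV

# ---------------------------------------------------------------------------
# passive membrane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveSpec:
    """Uniform passive properties. tau_m = Rm * Cm (kOhm cm^2 * uF/cm^2 = ms)."""

    tau_m: float   # ms
    Rm: float      # kOhm cm^2
    Ra: float      # Ohm cm
    Cm: float      # uF/cm^2
    e_pas: float = -65.0  # mV

    def __post_init__(self):
        for name in ("tau_m", "Rm", "Ra", "Cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(self.tau_m - self.Rm * self.Cm) > 1e-6 * self.tau_m:
            raise ValueError(
                f"inconsistent passive spec: tau_m={self.tau_m} != Rm*Cm={self.Rm * self.Cm}"
            )


def ca1_passive() -> PassiveSpec:
    return PassiveSpec(tau_m=28.0, Rm=28.0, Ra=150.0, Cm=1.0)


def ca3_passive() -> PassiveSpec:
    # Rm = 25 kOhm cm^2 with tau_m = 35 ms forces Cm = 1.4 uF/cm^2
    return PassiveSpec(tau_m=35.0, Rm=25.0, Ra=150.0, Cm=1.4)


# ---------------------------------------------------------------------------
# gating-variable functional forms
# ---------------------------------------------------------------------------

def _trap0(v, th, a, q):
    """a*(v-th)/(1-exp(-(v-th)/q)), continuous through v = th."""
    v = np.asarray(v, dtype=float)
    x = (v - th) / q
    out = np.where(np.abs(x) > 1e-6, a * q * x / (1 - np.exp(-x)), a * q * (1 + x / 2))
    return out


def _boltz(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vh) / k))


def _form_trap_rates(tha, qa, Ra, Rb, qt=1.0, taumin=0.02, inf_vh=None, inf_k=None):
    """Na-style kinetics: alpha/beta are trap functions of v; the steady state
    is alpha/(alpha+beta) unless a separate Boltzmann (inf_vh, inf_k) is given."""
    def rates(v):
        a = _trap0(v, tha, Ra, qa)
        b = _trap0(-np.asarray(v, dtype=float), -tha, Rb, qa)
        return a, b

    def minf(v):
        if inf_vh is not None:
            return _boltz(v, inf_vh, inf_k)
        a, b = rates(v)
        return a / (a + b)

    def tau(v):
        a, b = rates(v)
        return np.maximum(1.0 / (qt * (a + b)), taumin)

    return minf, tau


def _form_borg(vh, zeta, gm, a0, qt=1.0, taumin=0.1, pw=0.0, tq=-40.0, qq=5.0):
    """Borg-Graham thermodynamic rate model (used by the K_DR / K_A family).

    alpha = exp(zeta_eff*(v-vh)*F/RT), zeta_eff = zeta + pw/(1+exp((v-tq)/qq));
    inf = 1/(1+alpha), tau = beta/(a0*qt*(1+alpha)) with beta the gm-scaled
    exponential.  zeta < 0 gives activation, zeta > 0 inactivation.
    """
    def zeta_eff(v):
        return zeta + pw / (1.0 + np.exp((np.asarray(v, dtype=float) - tq) / qq))

    def minf(v):
        return 1.0 / (1.0 + np.exp(zeta_eff(v) * (np.asarray(v, dtype=float) - vh) * _FRT))

    def tau(v):
        v = np.asarray(v, dtype=float)
        al = np.exp(zeta_eff(v) * (v - vh) * _FRT)
        be = np.exp(zeta_eff(v) * gm * (v - vh) * _FRT)
        return np.maximum(be / (a0 * qt * (1.0 + al)), taumin)

    return minf, tau


def _form_linear_tau(vh, k, slope, v0, taumin):
    """Boltzmann steady state with piecewise-linear tau (K_A inactivation)."""
    def minf(v):
        return _boltz(v, vh, k)

    def tau(v):
        return np.maximum(slope * (np.asarray(v, dtype=float) - v0), taumin)

    return minf, tau


def _form_boltz_belltau(vh, k, tau0, amp, vth, s1, s2):
    """Boltzmann steady state with a bell-shaped tau (generic Ca/K channels)."""
    def minf(v):
        return _boltz(v, vh, k)

    def tau(v):
        v = np.asarray(v, dtype=float)
        return tau0 + amp / (np.exp((v - vth) / s1) + np.exp(-(v - vth) / s2))

    return minf, tau


def _form_kahp(a, b, taumin=10.0, n=1.0):
    """Calcium-pool-driven sAHP gate: forward rate a*[Ca]^n, backward b."""
    def winf(ca):
        x = a * np.asarray(ca, dtype=float) ** n
        return x / (x + b)

    def tau(ca):
        x = a * np.asarray(ca, dtype=float) ** n
        return np.maximum(1.0 / (x + b), taumin)

    return winf, tau


def _form_cagk(abar, bbar, k1, k2, d1, d2):
    """Moczydlowski-Latorre BK gate: voltage- and calcium-dependent rates."""
    def rates(v, ca):
        v = np.asarray(v, dtype=float)
        ca = np.asarray(ca, dtype=float)
        a = abar / (1.0 + k1 * np.exp(-2.0 * d1 * _FRT * v) / ca)
        b = bbar / (1.0 + ca / (k2 * np.exp(-2.0 * d2 * _FRT * v)))
        return a, b

    def oinf(v, ca):
        a, b = rates(v, ca)
        return a / (a + b)

    def tau(v, ca):
        a, b = rates(v, ca)
        return 1.0 / (a + b)

    return oinf, tau


GATE_FORMS: dict[str, Callable] = {
    "trap_rates": _form_trap_rates,
    "borg": _form_borg,
    "linear_tau": _form_linear_tau,
    "boltz_belltau": _form_boltz_belltau,
    "kahp": _form_kahp,
    "cagk": _form_cagk,
}


@dataclass
class GatingVariable:
    """One first-order Hodgkin-Huxley gate: dm/dt = (m_inf - m)/tau."""

    name: str
    form: str
    params: dict
    exponent: int = 1
    kind: str = "v"  # "v" | "ca" (calcium-only) | "vca" (BK)

    def __post_init__(self):
        self._inf, self._tau = GATE_FORMS[self.form](**self.params)

    def minf(self, *args):
        return self._inf(*args)

    def tau(self, *args):
        return self._tau(*args)


def gating_step(m, v, dt: float, gv: GatingVariable):
    """Exponential (exact for frozen v) relaxation toward m_inf(v)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    inf = gv.minf(v)
    tau = gv.tau(v)
    return inf + (m - inf) * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# channels and channel sets
# ---------------------------------------------------------------------------

DENDRITES = (Structure.BASAL, Structure.APICAL)
SOMATODENDRITIC = (Structure.SOMA, Structure.BASAL, Structure.APICAL)
ALL_BUT_AXON = SOMATODENDRITIC
WITH_AXON = (Structure.SOMA, Structure.AXON, Structure.BASAL, Structure.APICAL)


@dataclass
class ChannelSpec:
    name: str
    gbar: float                      # S/cm^2
    erev: float                      # mV
    gates: list[GatingVariable]
    structures: tuple = SOMATODENDRITIC
    is_calcium: bool = False         # current feeds the submembrane Ca pool
    # optional linear somatodendritic gradient: factor 1 + slope*path_um,
    # capped at max_factor, applied to dendritic compartments only
    gradient: dict | None = None
    # optional per-structure density multipliers, keyed by Structure int code
    structure_factors: dict | None = None

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError(f"channel {self.name}: gbar must be >= 0")


@dataclass
class CaPoolParams:
    """Single-exponential submembrane calcium pool."""

    ca0: float = 5e-5    # mM resting
    tau_ms: float = 40.0
    depth_um: float = 0.1


@dataclass
class ChannelSet:
    label: str
    channels: list[ChannelSpec]
    ca_pool: CaPoolParams | None = None

    def names(self) -> set[str]:
        return {c.name for c in self.channels}

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)


def ionic_current(g_uS, v_i, v_e, v_k):
    """Eq-level channel current (nA, outward positive): g*(V_i - V_e - V_k).

    ``g_uS`` is the fully scaled conductance (density x area x gating
    product), in uS.
    """
    return np.asarray(g_uS) * (np.asarray(v_i) - np.asarray(v_e) - v_k)


# -- gate constructors shared between the two sets ---------------------------

def _na_gates(qt=2.0):
    return [
        GatingVariable("m", "trap_rates",
                       dict(tha=-30.0, qa=7.2, Ra=0.4, Rb=0.124, qt=qt, taumin=0.02),
                       exponent=3),
        GatingVariable("h", "trap_rates",
                       dict(tha=-45.0, qa=1.5, Ra=0.03, Rb=0.01, qt=qt, taumin=0.5,
                            inf_vh=-50.0, inf_k=-4.0),
                       exponent=1),
    ]


def _kdr_gate():
    return [GatingVariable("n", "borg",
                           dict(vh=13.0, zeta=-3.0, gm=0.7, a0=0.02, qt=1.0, taumin=1.0))]


def _ka_gates():
    return [
        GatingVariable("n", "borg",
                       dict(vh=11.0, zeta=-1.5, gm=0.55, a0=0.05, qt=5.0, taumin=0.1,
                            pw=-1.0, tq=-40.0, qq=5.0)),
        GatingVariable("l", "linear_tau",
                       dict(vh=-56.0, k=-8.8, slope=0.26, v0=-50.0, taumin=2.0)),
    ]


def _h_gate():
    return [GatingVariable("l", "borg",
                           dict(vh=-81.0, zeta=2.2, gm=0.4, a0=0.011, qt=1.0, taumin=5.0))]


def ca1_channel_set() -> ChannelSet:
    """Na, K_DR, K_A (with the somatodendritic density gradient) and I_h.

    K_A and I_h densities increase linearly with path distance from the
    soma, the hallmark distribution of CA1 apical dendrites.
    """
    return ChannelSet("CA1", [
        ChannelSpec("na", 0.025, 55.0, _na_gates(), structures=WITH_AXON,
                    structure_factors={3: 0.5, 4: 0.5}),
        ChannelSpec("kdr", 0.010, -90.0, _kdr_gate(), structures=WITH_AXON),
        ChannelSpec("ka", 0.030, -90.0, _ka_gates(),
                    gradient=dict(slope_per_um=1.0 / 100.0, max_factor=6.5)),
        ChannelSpec("h", 2.5e-5, -30.0, _h_gate(),
                    gradient=dict(slope_per_um=3.0 / 100.0, max_factor=9.0)),
    ])


def ca3_channel_set() -> ChannelSet:
    """The broad CA3 repertoire: Na, K_DR, K_M, K_A, K_D, Ca_N/L/T, K_C
    (BK), K_AHP and I_h, with a submembrane Ca pool for the two
    calcium-dependent K currents."""
    return ChannelSet("CA3", [
        ChannelSpec("na", 0.022, 55.0, _na_gates(), structures=WITH_AXON,
                    structure_factors={3: 0.5, 4: 0.5}),
        ChannelSpec("kdr", 0.010, -90.0, _kdr_gate(), structures=WITH_AXON),
        ChannelSpec("km", 2e-5, -90.0, [
            GatingVariable("n", "boltz_belltau",
                           dict(vh=-35.0, k=10.0, tau0=8.0, amp=60.0, vth=-35.0,
                                s1=20.0, s2=20.0)),
        ]),
        ChannelSpec("ka", 0.020, -90.0, _ka_gates()),
        ChannelSpec("kd", 5e-4, -90.0, [
            GatingVariable("m", "boltz_belltau",
                           dict(vh=-33.0, k=7.0, tau0=2.0, amp=0.0, vth=-33.0,
                                s1=10.0, s2=10.0)),
            GatingVariable("h", "boltz_belltau",
                           dict(vh=-58.0, k=-7.0, tau0=500.0, amp=0.0, vth=-58.0,
                                s1=10.0, s2=10.0)),
        ]),
        ChannelSpec("can", 5e-5, 120.0, [
            GatingVariable("m", "boltz_belltau",
                           dict(vh=-15.0, k=6.0, tau0=1.0, amp=3.0, vth=-25.0,
                                s1=10.0, s2=12.0), exponent=2),
            GatingVariable("h", "boltz_belltau",
                           dict(vh=-50.0, k=-10.0, tau0=80.0, amp=0.0, vth=-50.0,
                                s1=10.0, s2=10.0)),
        ], is_calcium=True),
        ChannelSpec("cal", 4e-5, 120.0, [
            GatingVariable("m", "boltz_belltau",
                           dict(vh=-10.0, k=6.0, tau0=1.5, amp=0.0, vth=-10.0,
                                s1=10.0, s2=10.0), exponent=2),
        ], is_calcium=True),
        ChannelSpec("cat", 4e-5, 120.0, [
            GatingVariable("m", "boltz_belltau",
                           dict(vh=-32.0, k=7.0, tau0=1.0, amp=20.0, vth=-70.0,
                                s1=10.0, s2=15.0), exponent=2),
            GatingVariable("h", "boltz_belltau",
                           dict(vh=-70.0, k=-6.5, tau0=20.0, amp=50.0, vth=-60.0,
                                s1=10.0, s2=10.0)),
        ], is_calcium=True),
        ChannelSpec("kc", 1e-4, -90.0, [
            GatingVariable("o", "cagk",
                           dict(abar=0.48, bbar=0.28, k1=0.18, k2=0.011, d1=0.84, d2=1.0),
                           kind="vca"),
        ]),
        ChannelSpec("kahp", 5.65e-5, -90.0, [
            GatingVariable("w", "kahp", dict(a=16.7, b=0.005, taumin=10.0, n=1.0), kind="ca"),
        ]),
        ChannelSpec("h", 1.5e-5, -30.0, _h_gate()),
    ], ca_pool=CaPoolParams())


REQUIRED_CHANNELS = {
    "CA1": {"na", "kdr", "ka", "h"},
    "CA3": {"na", "kdr", "km", "ka", "kd", "can", "cal", "cat", "kc", "kahp", "h"},
}


# ---------------------------------------------------------------------------
# membrane assembly
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """A compartmental model equipped with passive and active membrane."""

    model: CompartmentalModel
    passive: PassiveSpec
    channel_set: ChannelSet
    cap_nF: np.ndarray           # per compartment
    g_pas_uS: np.ndarray
    e_pas: float
    gbar_uS: dict[str, np.ndarray]   # channel name -> per-compartment uS
    path_um: np.ndarray              # path distance from the soma

    @property
    def n_compartments(self) -> int:
        return self.model.n_compartments


def path_distances(model: CompartmentalModel) -> np.ndarray:
    """Center-to-center path distance (um) of each compartment from the soma."""
    n = model.n_compartments
    path = np.zeros(n)
    soma = model.structure == int(Structure.SOMA)
    for i in range(n):
        p = model.parent[i]
        if p < 0 or soma[i]:
            path[i] = 0.0
        elif soma[p]:
            path[i] = model.length[i] / 2
        else:
            path[i] = path[p] + (model.length[i] + model.length[p]) / 2
    return path


def build_membrane(model: CompartmentalModel, channel_set: ChannelSet,
                   passive: PassiveSpec,
                   density_overrides: dict[str, float] | None = None) -> MembraneModel:
    """Attach leak and the set's channels to every compartment.

    Every compartment carries the leak (1/Rm toward e_pas); each channel is
    placed on the structures it declares, with optional linear density
    gradients along the dendritic path.  ``density_overrides`` maps channel
    name -> gbar (S/cm^2).
    """
    overrides = dict(density_overrides or {})
    unknown = set(overrides) - channel_set.names()
    if unknown:
        raise KeyError(f"unknown channel name(s) in overrides: {sorted(unknown)}")
    path = path_distances(model)
    cap = passive.Cm * model.area * 1e3          # uF -> nF
    g_pas = model.area * 1e3 / passive.Rm        # uS
    gbar: dict[str, np.ndarray] = {}
    dendritic = np.isin(model.structure, [int(s) for s in DENDRITES])
    for spec in channel_set.channels:
        density = overrides.get(spec.name, spec.gbar)
        on = np.isin(model.structure, [int(s) for s in spec.structures])
        g = np.where(on, density, 0.0)
        if spec.structure_factors:
            for code, fac in spec.structure_factors.items():
                g = np.where(model.structure == int(code), g * fac, g)
        if spec.gradient:
            factor = np.minimum(1.0 + spec.gradient["slope_per_um"] * path,
                                spec.gradient["max_factor"])
            g = np.where(dendritic, g * factor, g)
        gbar[spec.name] = g * model.area * 1e6   # S -> uS
    return MembraneModel(model=model, passive=passive, channel_set=channel_set,
                         cap_nF=cap, g_pas_uS=g_pas, e_pas=passive.e_pas,
                         gbar_uS=gbar, path_um=path)


# ---------------------------------------------------------------------------
# config (YAML/JSON) round-trip
# ---------------------------------------------------------------------------

def channel_set_to_dict(cs: ChannelSet) -> dict:
    out = {"label": cs.label, "channels": []}
    for c in cs.channels:
        out["channels"].append({
            "name": c.name, "gbar": c.gbar, "erev": c.erev,
            "structures": [int(s) for s in c.structures],
            "is_calcium": c.is_calcium, "gradient": c.gradient,
            "structure_factors": ({int(k): v for k, v in c.structure_factors.items()}
                                  if c.structure_factors else None),
            "gates": [{"name": g.name, "form": g.form, "params": g.params,
                       "exponent": g.exponent, "kind": g.kind} for g in c.gates],
        })
    if cs.ca_pool:
        out["ca_pool"] = {"ca0": cs.ca_pool.ca0, "tau_ms": cs.ca_pool.tau_ms,
                          "depth_um": cs.ca_pool.depth_um}
    return out


def channel_set_from_dict(d: dict) -> ChannelSet:
    channels = []
    for c in d["channels"]:
        gates = [GatingVariable(g["name"], g["form"], g["params"],
                                g.get("exponent", 1), g.get("kind", "v"))
                 for g in c["gates"]]
        channels.append(ChannelSpec(
            c["name"], c["gbar"], c["erev"], gates,
            structures=tuple(Structure(s) for s in c.get("structures", [1, 3, 4])),
            is_calcium=c.get("is_calcium", False), gradient=c.get("gradient"),
            structure_factors=c.get("structure_factors")))
    pool = d.get("ca_pool")
    return ChannelSet(d["label"], channels,
                      CaPoolParams(**pool) if pool else None)


def load_channel_set(path) -> ChannelSet:
    with open(path) as fh:
        return channel_set_from_dict(yaml.safe_load(fh))


def dump_channel_set(cs: ChannelSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(channel_set_to_dict(cs), fh, sort_keys=False)
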