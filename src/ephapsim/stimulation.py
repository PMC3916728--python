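"""Synaptic drive, somatic current injection and the extracellular field.

The neuron is driven by excitatory postsynaptic conductances placed
uniformly at random on thin (< 0.35 um) dendritic compartments, each firing
a homogeneous-Poisson event train; each event contributes an alpha-function
conductance

    g(t) = g_max * ((t - t0)/tau) * exp(-(t - t0 - tau)/tau),   t >= t0

which peaks at g_max one tau after onset (g = 0 before onset; overlapping
events from one synapse sum linearly).

The imposed extracellular oscillation is a separable sinusoid along the
somatodendritic axis x (mm):

    V_e(x, t) = V_o sin(2 pi f_t t) sin(2 pi f_s x + phi_s)

independent of y and z.  It is evaluated at each compartment's center; the
soma (x = 0) value serves as the phase reference for all spike statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentalModel, Structure

THIN_DIAMETER_UM = 0.35  # synapse-hosting threshold
RATE_SEARCH_HZ = (200.0, 7000.0)


@dataclass(frozen=True)
class SynapseSpec:
    tau: float = 0.1     # ms
    g_max: float = 1.0   # uS
    e_syn: float = 0.0   # mV, excitatory

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass
class SynapsePlacement:
    compartment: int
    fraction: float               # within-compartment position in [0, 1]
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))  # ms, sorted


@dataclass(frozen=True)
class FieldSpec:
    v_o: float = 0.0      # mV
    f_t: float = 10.0     # Hz
    f_s: float = 0.8      # 1/mm
    phi_s: float = 3 * np.pi / 10  # rad

    def __post_init__(self):
        if self.v_o < 0 or self.f_t < 0 or self.f_s < 0:
            raise ValueError("v_o, f_t and f_s must be >= 0")

    def evaluate(self, x_mm, t_ms):
        return extracellular_potential(x_mm, t_ms, self)

    def summary(self) -> tuple:
        return (self.v_o, self.f_t, self.f_s, round(float(self.phi_s), 6))


@dataclass(frozen=True)
class CurrentInjection:
    compartment: int
    amplitude: float      # nA
    start: float          # ms
    stop: float

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError("stop must be > start")


def extracellular_potential(x_mm, t_ms, fieldspec: FieldSpec):
    """V_e (mV) at somatodendritic position x (mm) and time t (ms)."""
    x = np.asarray(x_mm, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    return (fieldspec.v_o
            * np.sin(2 * np.pi * fieldspec.f_t * t * 1e-3)
            * np.sin(2 * np.pi * fieldspec.f_s * x + fieldspec.phi_s))


def alpha_conductance(t, t_onset, spec: SynapseSpec):
    """Conductance (uS) of a single alpha event; vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    dt = t - t_onset
    g = np.where(dt >= 0,
                 spec.g_max * (dt / spec.tau) * np.exp(-(dt - spec.tau) / spec.tau),
                 0.0)
    return g if g.shape else float(g)


def eligible_compartments(model: CompartmentalModel, region: str) -> np.ndarray:
    """Indices of synapse-hosting compartments: dendritic, thinner than
    0.35 um, of the requested region ('basal' | 'apical' | 'all')."""
    thin = model.diameter < THIN_DIAMETER_UM
    if region == "basal":
        mask = thin & (model.structure == int(Structure.BASAL))
    elif region == "apical":
        mask = thin & (model.structure == int(Structure.APICAL))
    elif region == "all":
        mask = thin & np.isin(model.structure,
                              [int(Structure.BASAL), int(Structure.APICAL)])
    else:
        raise ValueError(f"unknown region {region!r}")
    return np.flatnonzero(mask)


def place_synapses(model: CompartmentalModel, n_synapses: int, region: str,
                   rng: np.random.Generator) -> list[SynapsePlacement]:
    """Uniform placement over eligible compartments, uniform within each."""
    hosts = eligible_compartments(model, region)
    if hosts.size == 0:
        raise ValueError(
            f"no compartment thinner than {THIN_DIAMETER_UM} um in region {region!r}")
    comp = rng.choice(hosts, size=n_synapses, replace=True)
    frac = rng.uniform(0.0, 1.0, size=n_synapses)
    return [SynapsePlacement(int(c), float(f)) for c, f in zip(comp, frac)]


def poisson_onsets(rate_hz: float, duration_ms: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times (ms, sorted) on [0, duration)."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    n = rng.poisson(rate_hz * duration_ms * 1e-3)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def assign_onsets(placements: list[SynapsePlacement], total_rate_hz: float,
                  duration_ms: float, rng: np.random.Generator) -> list[SynapsePlacement]:
    """Split the aggregate PSP rate evenly over the synapses and draw each
    synapse's Poisson train (in place; returns the list)."""
    per = total_rate_hz / max(len(placements), 1)
    for p in placements:
        p.onsets = poisson_onsets(per, duration_ms, rng)
    return placements


class RateTuningError(RuntimeError):
    pass


def tune_rate_for_band(membrane, band: str, rng: np.random.Generator,
                       n_synapses: int = 100, region: str = "all",
                       probe_duration_ms: float = 1000.0, settle_ms: float = 100.0,
                       dt_ms: float = 0.025, max_iter: int = 12):
    """Bisect the aggregate PSP rate in [200, 7000] Hz until the no-field
    firing rate lands in the requested band ('low' <= 5 Hz, 'medium' 5-15 Hz,
    'high' >= 15 Hz).  Returns (rate_hz, measured_f_hz)."""
    from .solver import SolverConfig, assemble, run  # deferred: solver uses our types
    from .synthetic import FIRING_BANDS

    lo_f, hi_f = FIRING_BANDS[band]
    placements = place_synapses(membrane.model, n_synapses, region, rng)
    onset_rng_state = rng.bit_generator.state

    def measure(rate):
        r = np.random.Generator(np.random.PCG64())
        r.bit_generator.state = onset_rng_state  # same train geometry per probe
        assign_onsets(placements, rate, probe_duration_ms + settle_ms, r)
        system = assemble(membrane, placements, [], None)
        cfg = SolverConfig(dt=dt_ms, duration=probe_duration_ms, settle=settle_ms)
        res = run(system, cfg)
        return len(res.spike_times) / (probe_duration_ms * 1e-3)

    def in_band(f):
        if band == "low":
            return f <= hi_f
        if band == "high":
            return f >= lo_f
        return lo_f < f < hi_f

    # aim for the middle of the band, not its edge: an edge rate makes every
    # downstream statistic fragile (e.g. medium-band F ~ 5 Hz quantizes
    # 1-s spike counts in 20 % steps)
    target = {"low": 2.5, "medium": 0.5 * (lo_f + hi_f), "high": 25.0}[band]

    lo, hi = RATE_SEARCH_HZ
    f_lo, f_hi = measure(lo), measure(hi)
    if (f_lo > target and not in_band(f_lo)) or (f_hi < target and not in_band(f_hi)):
        raise RateTuningError(
            f"band {band!r} unreachable in [{lo}, {hi}] Hz: F({lo})={f_lo}, F({hi})={f_hi}")
    best = None
    for rate, f in ((lo, f_lo), (hi, f_hi)):
        if in_band(f):
            best = (abs(f - target), rate, f)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = measure(mid)
        if in_band(f) and (best is None or abs(f - target) < best[0]):
            best = (abs(f - target), mid, f)
        if f < target:
            lo = mid
        else:
            hi = mid
        if best is not None and best[0] <= 0.15 * (target - lo_f if band != "low" else target):
            break
    if best is None:
        raise RateTuningError(f"bisection failed to reach band {band!r} "
                              f"(last F = {f} Hz at {mid} Hz)")
    return best[1], best[2]
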