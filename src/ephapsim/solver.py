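"""Cable-equation integrator with an imposed extracellular potential.

Every transmembrane element (capacitance, leak, active channels, synapses)
is driven by the membrane potential V_m = V_i - V_e, while axial currents
flow down gradients of the *intracellular* potential V_i.  Writing the
balance of compartment i in terms of V_m,

    C_i dV_m,i/dt + I_ion,i(V_m,i) + I_syn,i(V_m,i)
        = sum_j (V_m,j - V_m,i)/r_ij + sum_j (V_e,j - V_e,i)/r_ij + I_inj,i

so the extracellular field enters solely through the axial drive term
sum_j (V_e,j - V_e,i)/r_ij: a spatially uniform field cancels exactly and
leaves V_m untouched, while a field that varies along the somatodendritic
axis polarizes the tree.  Because V_e is a known closed form, the drive is
evaluated analytically at each time step (no numerical differentiation).

Integration is fixed-step implicit Euler (default) or Crank-Nicolson on the
tree-structured linear system, solved exactly in linear time per step with
Hines ordering (leaf-to-root elimination, root-to-leaf back-substitution),
with staggered exponential gating updates.  Gating rates are evaluated by
linear interpolation in dense voltage tables (0.05 mV grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .biophysics import MembraneModel, V_GRID
from .morphology import Structure, SwcStructureError
from .stimulation import (CurrentInjection, FieldSpec, SynapsePlacement,
                          SynapseSpec, extracellular_potential)

E_CONST = float(np.e)


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.025          # ms
    duration: float = 1000.0   # ms, reported window
    settle: float = 100.0      # ms, simulated but discarded
    method: str = "implicit_euler"  # or "crank_nicolson"
    record: tuple = ()         # extra compartments to record (soma always)
    v_init: float = -65.0      # mV
    spike_threshold: float = 0.0   # mV, upward crossing on somatic V_m
    refractory: float = 2.0        # ms lockout between detected spikes

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.settle < 0:
            raise ValueError("settle must be >= 0")
        if self.method not in ("implicit_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")


class NumericalError(RuntimeError):
    pass


@dataclass
class System:
    """Flattened integrable system (membrane + stimuli + field)."""

    membrane: MembraneModel
    field: FieldSpec | None
    synspec: SynapseSpec
    soma_index: int
    # flat arrays for the kernel
    parent: np.ndarray
    inv_r: np.ndarray
    cap: np.ndarray
    g_pas: np.ndarray
    e_pas: float
    chan_gbar: np.ndarray      # (nchan, n)
    chan_erev: np.ndarray
    chan_iscal: np.ndarray     # uint8
    gate_chan: np.ndarray
    gate_exp: np.ndarray
    gate_kind: np.ndarray      # 0 = V table, 1 = Ca, 2 = V+Ca (BK)
    gate_inf: np.ndarray       # (ngate, nv)
    gate_tau: np.ndarray
    gate_par: np.ndarray       # (ngate, 6) params for kinds 1, 2
    ca_enabled: bool
    ca0: float
    ca_tau: float
    ca_factor: np.ndarray      # mM per (nA ms)
    syn_events: tuple          # (steps, comps, z_inc, y_inc) built per dt
    syn_onsets: list           # raw (comp, onset_ms) event list
    inj: list[CurrentInjection]
    ve_spatial: np.ndarray     # V_o * sin(2 pi f_s x + phi_s) per compartment
    meta: dict = field(default_factory=dict)


def assemble(membrane: MembraneModel, synapses: list[SynapsePlacement] | None,
             injections: list[CurrentInjection] | None,
             fieldspec: FieldSpec | None,
             synspec: SynapseSpec | None = None) -> System:
    """Build the integrable system from membrane, stimuli and field."""
    model = membrane.model
    model.validate()  # raises on disconnected / mis-ordered trees
    n = model.n_compartments
    synspec = synspec or SynapseSpec()
    inv_r = np.zeros(n)
    with np.errstate(invalid="ignore"):
        inv_r[1:] = 1.0 / model.r_axial[1:]

    cs = membrane.channel_set
    nchan = len(cs.channels)
    chan_gbar = np.zeros((nchan, n))
    chan_erev = np.zeros(nchan)
    chan_iscal = np.zeros(nchan, dtype=np.uint8)
    gate_chan, gate_exp, gate_kind, gate_par = [], [], [], []
    gate_inf, gate_tau = [], []
    nv = len(V_GRID)
    for k, spec in enumerate(cs.channels):
        chan_gbar[k] = membrane.gbar_uS[spec.name]
        chan_erev[k] = spec.erev
        chan_iscal[k] = 1 if spec.is_calcium else 0
        for gv in spec.gates:
            gate_chan.append(k)
            gate_exp.append(gv.exponent)
            par = np.zeros(6)
            if gv.kind == "v":
                gate_kind.append(0)
                gate_inf.append(np.asarray(gv.minf(V_GRID), dtype=float))
                gate_tau.append(np.asarray(gv.tau(V_GRID), dtype=float))
            elif gv.kind == "ca":
                gate_kind.append(1)
                p = gv.params
                par[:4] = (p["a"], p["b"], p.get("taumin", 1.0), p.get("n", 1.0))
                gate_inf.append(np.zeros(nv))
                gate_tau.append(np.ones(nv))
            elif gv.kind == "vca":
                gate_kind.append(2)
                p = gv.params
                par[:6] = (p["abar"], p["bbar"], p["k1"], p["k2"], p["d1"], p["d2"])
                gate_inf.append(np.zeros(nv))
                gate_tau.append(np.ones(nv))
            else:
                raise ValueError(f"unknown gate kind {gv.kind!r}")
            gate_par.append(par)

    pool = cs.ca_pool
    if pool is not None:
        # dCa (mM/ms) = -I_Ca(nA) * factor - (Ca - ca0)/tau
        depth_cm = pool.depth_um * 1e-4
        with np.errstate(divide="ignore"):
            ca_factor = 1e-9 / (2 * 96485.0 * model.area * depth_cm * 1e-3)
        ca_enabled, ca0, ca_tau = True, pool.ca0, pool.tau_ms
    else:
        ca_factor = np.zeros(n)
        ca_enabled, ca0, ca_tau = False, 5e-5, 100.0

    soma = np.flatnonzero(model.structure == int(Structure.SOMA))
    if soma.size == 0:
        raise SwcStructureError("model has no soma compartment")

    onsets = []
    for p in (synapses or []):
        for t0 in np.atleast_1d(p.onsets):
            onsets.append((p.compartment, float(t0)))
    onsets.sort(key=lambda e: e[1])

    if fieldspec is not None and fieldspec.v_o > 0:
        ve_spatial = fieldspec.v_o * np.sin(
            2 * np.pi * fieldspec.f_s * model.x_mm + fieldspec.phi_s)
    else:
        ve_spatial = np.zeros(n)

    return System(
        membrane=membrane, field=fieldspec, synspec=synspec,
        soma_index=int(soma[0]),
        parent=model.parent.astype(np.int64), inv_r=inv_r,
        cap=membrane.cap_nF, g_pas=membrane.g_pas_uS, e_pas=membrane.e_pas,
        chan_gbar=chan_gbar, chan_erev=chan_erev, chan_iscal=chan_iscal,
        gate_chan=np.array(gate_chan, dtype=np.int64),
        gate_exp=np.array(gate_exp, dtype=np.int64),
        gate_kind=np.array(gate_kind, dtype=np.int64),
        gate_inf=np.array(gate_inf).reshape(-1, nv) if gate_chan else np.zeros((0, nv)),
        gate_tau=np.array(gate_tau).reshape(-1, nv) if gate_chan else np.ones((0, nv)),
        gate_par=np.array(gate_par).reshape(-1, 6) if gate_chan else np.zeros((0, 6)),
        ca_enabled=ca_enabled, ca0=ca0, ca_tau=ca_tau, ca_factor=ca_factor,
        syn_events=(), syn_onsets=onsets, inj=list(injections or []),
        ve_spatial=ve_spatial,
    )


@njit(cache=True)
def _run_kernel(nsteps, dt, theta, parent, inv_r, cap, g_pas, e_pas,
                chan_gbar, chan_erev, chan_iscal,
                gate_chan, gate_exp, gate_kind, gate_inf, gate_tau, gate_par,
                ca_enabled, ca0, ca_tau, ca_factor,
                ev_step, ev_comp, ev_z, ev_y, syn_scale, e_syn, syn_tau,
                inj_comp, inj_amp, inj_start, inj_stop,
                ve_spatial, omega_per_ms, t_field_offset,
                rec_idx, v_init, vmin, dv):
    n = parent.shape[0]
    ngate = gate_chan.shape[0]
    nchan = chan_gbar.shape[0]
    nv = gate_inf.shape[1]

    vm = np.full(n, v_init)
    m = np.empty((ngate, n))
    ca = np.full(n, ca0)
    # dt-specific decay tables for V gates
    gexp = np.empty((ngate, nv))
    for g in range(ngate):
        if gate_kind[g] == 0:
            for j in range(nv):
                gexp[g, j] = np.exp(-dt / gate_tau[g, j])
    # initialize gates at steady state for v_init / resting calcium
    u = (v_init - vmin) / dv
    j0 = int(u)
    w = u - j0
    for g in range(ngate):
        if gate_kind[g] == 0:
            m[g, :] = gate_inf[g, j0] * (1 - w) + gate_inf[g, j0 + 1] * w
        elif gate_kind[g] == 1:
            a, b, nca = gate_par[g, 0], gate_par[g, 1], gate_par[g, 3]
            x = a * ca0 ** nca
            m[g, :] = x / (x + b)
        else:
            abar, bbar = gate_par[g, 0], gate_par[g, 1]
            k1, k2 = gate_par[g, 2], gate_par[g, 3]
            d1, d2 = gate_par[g, 4], gate_par[g, 5]
            aa = abar / (1.0 + k1 * np.exp(-2.0 * d1 * 0.0378 * v_init) / ca0)
            bb = bbar / (1.0 + ca0 / (k2 * np.exp(-2.0 * d2 * 0.0378 * v_init)))
            m[g, :] = aa / (aa + bb)

    syn_y = np.zeros(n)
    syn_z = np.zeros(n)
    decay = np.exp(-dt / syn_tau)

    nrec = rec_idx.shape[0]
    record = np.empty((nrec, nsteps + 1))
    for r in range(nrec):
        record[r, 0] = vm[rec_idx[r]]

    # static axial diagonal
    ax_diag = np.zeros(n)
    for i in range(1, n):
        ax_diag[i] += inv_r[i]
        ax_diag[parent[i]] += inv_r[i]

    diag = np.empty(n)
    rhs = np.empty(n)
    gsum = np.empty(n)
    rhsb = np.empty(n)
    gprod = np.empty(n)
    ica = np.empty(n)

    ev_ptr = 0
    nev = ev_step.shape[0]
    err_step = -1
    vm_prev = np.empty(n)

    for step in range(1, nsteps + 1):
        t = step * dt
        for i in range(n):
            vm_prev[i] = vm[i]
        # synaptic alpha states (exact two-state recursion)
        for i in range(n):
            syn_y[i] = decay * (syn_y[i] + dt * syn_z[i])
            syn_z[i] = decay * syn_z[i]
        while ev_ptr < nev and ev_step[ev_ptr] == step:
            c = ev_comp[ev_ptr]
            syn_z[c] += ev_z[ev_ptr]
            syn_y[c] += ev_y[ev_ptr]
            ev_ptr += 1

        # gating update (staggered: rates at the previous voltage/calcium)
        for g in range(ngate):
            kind = gate_kind[g]
            if kind == 0:
                for i in range(n):
                    v = vm[i]
                    if v < vmin:
                        v = vmin
                    elif v > vmin + dv * (nv - 1):
                        v = vmin + dv * (nv - 1)
                    uu = (v - vmin) / dv
                    jj = int(uu)
                    if jj >= nv - 1:
                        jj = nv - 2
                    ww = uu - jj
                    inf = gate_inf[g, jj] * (1 - ww) + gate_inf[g, jj + 1] * ww
                    ex = gexp[g, jj] * (1 - ww) + gexp[g, jj + 1] * ww
                    m[g, i] = inf + (m[g, i] - inf) * ex
            elif kind == 1:
                a, b, taumin = gate_par[g, 0], gate_par[g, 1], gate_par[g, 2]
                nca = gate_par[g, 3]
                for i in range(n):
                    x = a * ca[i] ** nca
                    s = x + b
                    inf = x / s
                    tau = 1.0 / s
                    if tau < taumin:
                        tau = taumin
                    m[g, i] = inf + (m[g, i] - inf) * np.exp(-dt / tau)
            else:
                abar, bbar = gate_par[g, 0], gate_par[g, 1]
                k1, k2 = gate_par[g, 2], gate_par[g, 3]
                d1, d2 = gate_par[g, 4], gate_par[g, 5]
                for i in range(n):
                    cai = ca[i]
                    if cai < 1e-8:
                        cai = 1e-8
                    aa = abar / (1.0 + k1 * np.exp(-2.0 * d1 * 0.0378 * vm[i]) / cai)
                    bb = bbar / (1.0 + cai / (k2 * np.exp(-2.0 * d2 * 0.0378 * vm[i])))
                    s = aa + bb
                    inf = aa / s
                    m[g, i] = inf + (m[g, i] - inf) * np.exp(-dt * s)

        # channel conductances, reversal-weighted sums, calcium current
        for i in range(n):
            gsum[i] = 0.0
            rhsb[i] = 0.0
            ica[i] = 0.0
        for k in range(nchan):
            for i in range(n):
                gprod[i] = chan_gbar[k, i]
            for g in range(ngate):
                if gate_chan[g] == k:
                    e = gate_exp[g]
                    for i in range(n):
                        mg = m[g, i]
                        pw = mg
                        for _ in range(e - 1):
                            pw *= mg
                        gprod[i] *= pw
            ek = chan_erev[k]
            for i in range(n):
                gsum[i] += gprod[i]
                rhsb[i] += gprod[i] * ek
            if chan_iscal[k] == 1:
                for i in range(n):
                    ica[i] += gprod[i] * (vm[i] - ek)

        # calcium pool (exponential update toward the current-driven target)
        if ca_enabled:
            for i in range(n):
                target = ca0 - ca_factor[i] * ica[i] * ca_tau
                ca[i] = target + (ca[i] - target) * np.exp(-dt / ca_tau)
                if ca[i] < 1e-8:
                    ca[i] = 1e-8

        # synapses
        for i in range(n):
            gs = syn_scale * syn_y[i]
            gsum[i] += gs
            rhsb[i] += gs * e_syn

        # injections and field drive; Crank-Nicolson (theta = 0.5) solves for
        # the midpoint voltage with midpoint sources, then extrapolates
        cn = theta < 1.0
        t_src = t - 0.5 * dt if cn else t
        s_t = np.sin(omega_per_ms * (t_src - t_field_offset))
        for i in range(1, n):
            pi = parent[i]
            dr = inv_r[i] * s_t * (ve_spatial[pi] - ve_spatial[i])
            rhsb[i] += dr
            rhsb[pi] -= dr
        for j in range(inj_comp.shape[0]):
            if t_src >= inj_start[j] and t_src < inj_stop[j]:
                rhsb[inj_comp[j]] += inj_amp[j]

        c_fac = 2.0 / dt if cn else 1.0 / dt
        for i in range(n):
            diag[i] = cap[i] * c_fac + g_pas[i] + gsum[i] + ax_diag[i]
            rhs[i] = cap[i] * c_fac * vm[i] + rhsb[i] + g_pas[i] * e_pas

        # Hines elimination (parent[i] < i, so children are visited first)
        for i in range(n - 1, 0, -1):
            pi = parent[i]
            piv = inv_r[i] / diag[i]
            diag[pi] -= piv * inv_r[i]
            rhs[pi] += piv * rhs[i]
        vm[0] = rhs[0] / diag[0]
        for i in range(1, n):
            vm[i] = (rhs[i] + inv_r[i] * vm[parent[i]]) / diag[i]
        if cn:
            # vm currently holds the midpoint solution; extrapolate to t_{n+1}
            for i in range(n):
                vm[i] = 2.0 * vm[i] - vm_prev[i]

        if not np.isfinite(vm[0]):
            err_step = step
            break

        for r in range(nrec):
            record[r, step] = vm[rec_idx[r]]

    return record, err_step


def _build_events(system: System, dt: float, nsteps: int):
    """Snap synaptic events onto the step grid with exact sub-step offsets."""
    tau = system.synspec.tau
    steps, comps, zinc, yinc = [], [], [], []
    for comp, t0 in system.syn_onsets:
        s = int(np.ceil(t0 / dt - 1e-12))
        if s < 1:
            s = 1
        if s > nsteps:
            continue
        off = s * dt - t0
        w = np.exp(-off / tau)
        steps.append(s)
        comps.append(comp)
        zinc.append(w)
        yinc.append(off * w)
    order = np.argsort(np.array(steps, dtype=np.int64), kind="stable")
    return (np.array(steps, dtype=np.int64)[order],
            np.array(comps, dtype=np.int64)[order],
            np.array(zinc)[order], np.array(yinc)[order])


@dataclass
class SimulationResult:
    t: np.ndarray                  # ms, reported window, origin at settle end
    vm: dict                       # compartment -> V_m trace (mV)
    ve_soma: np.ndarray            # field reference at the soma
    spike_times: np.ndarray        # ms, post-settle
    soma_index: int
    field: FieldSpec | None
    dt: float
    meta: dict = field(default_factory=dict)

    def v_i(self, comp: int, x_mm: float) -> np.ndarray:
        """Intracellular potential V_i = V_m + V_e at a recorded compartment."""
        if self.field is None:
            return self.vm[comp]
        return self.vm[comp] + extracellular_potential(x_mm, self.t, self.field)


def detect_spikes(trace: np.ndarray, t: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout; crossing times
    are linearly interpolated between samples."""
    below = trace[:-1] < threshold
    above = trace[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - trace[idx]) / (trace[idx + 1] - trace[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    out = [times[0]]
    for tt in times[1:]:
        if tt - out[-1] >= refractory:
            out.append(tt)
    return np.array(out)


def run(system: System, cfg: SolverConfig | None = None,
        rng: np.random.Generator | None = None) -> SimulationResult:
    """Integrate the assembled system; the first ``settle`` ms are simulated
    with all stimuli active but dropped from the outputs, and reported time
    (and the field phase) starts at the settle end."""
    cfg = cfg or SolverConfig()
    model = system.membrane.model
    n = model.n_compartments
    dt = cfg.dt
    total = cfg.settle + cfg.duration
    nsteps = int(round(total / dt))
    theta = 1.0 if cfg.method == "implicit_euler" else 0.5

    rec = [system.soma_index] + [c for c in cfg.record if c != system.soma_index]
    rec_idx = np.array(rec, dtype=np.int64)

    ev_step, ev_comp, ev_z, ev_y = _build_events(system, dt, nsteps)
    syn_scale = system.synspec.g_max * E_CONST / system.synspec.tau

    inj = system.inj
    inj_comp = np.array([i.compartment for i in inj], dtype=np.int64)
    inj_amp = np.array([i.amplitude for i in inj])
    inj_start = np.array([i.start + cfg.settle for i in inj])
    inj_stop = np.array([i.stop + cfg.settle for i in inj])

    f = system.field
    omega = 2 * np.pi * f.f_t * 1e-3 if f is not None else 0.0

    record, err_step = _run_kernel(
        nsteps, dt, theta,
        system.parent, system.inv_r, system.cap, system.g_pas, system.e_pas,
        system.chan_gbar, system.chan_erev, system.chan_iscal,
        system.gate_chan, system.gate_exp, system.gate_kind,
        system.gate_inf, system.gate_tau, system.gate_par,
        system.ca_enabled, system.ca0, system.ca_tau, system.ca_factor,
        ev_step, ev_comp, ev_z, ev_y,
        syn_scale, system.synspec.e_syn, system.synspec.tau,
        inj_comp, inj_amp, inj_start, inj_stop,
        system.ve_spatial, omega, cfg.settle,
        rec_idx, cfg.v_init, float(V_GRID[0]), float(V_GRID[1] - V_GRID[0]))

    if err_step >= 0:
        raise NumericalError(
            f"non-finite membrane potential at step {err_step} "
            f"(t = {err_step * dt - cfg.settle:.3f} ms, soma)")

    t_all = np.arange(nsteps + 1) * dt
    keep = t_all >= cfg.settle - 1e-9
    t_rep = t_all[keep] - cfg.settle
    vm = {int(c): record[r][keep] for r, c in enumerate(rec_idx)}
    if not np.all(np.isfinite(record[:, keep])):
        raise NumericalError("non-finite values in recorded traces")

    soma_vm = vm[system.soma_index]
    spikes = detect_spikes(soma_vm, t_rep, cfg.spike_threshold, cfg.refractory)

    if f is not None:
        ve_soma = extracellular_potential(
            model.x_mm[system.soma_index], t_rep, f)
    else:
        ve_soma = np.zeros_like(t_rep)

    return SimulationResult(
        t=t_rep, vm=vm, ve_soma=ve_soma, spike_times=spikes,
        soma_index=system.soma_index, field=f, dt=dt,
        meta={"method": cfg.method, "settle": cfg.settle,
              "duration": cfg.duration,
              "field": f.summary() if f else (0.0, 0.0, 0.0, 0.0)})


def steady_state_attenuation(n_comp: int = 30, length_um: float = 1000.0,
                             diam_um: float = 1.0, Rm: float = 28.0,
                             Ra: float = 150.0, i_inj_nA: float = 0.01,
                             duration_ms: float = 400.0) -> tuple[np.ndarray, np.ndarray]:
    """DC voltage profile of a sealed-end passive cylinder injected at one
    end (solver validation against V(x) = V(0) cosh((L-x)/lambda)/cosh(L/lambda)).

    Returns (x_um at compartment centers, steady-state deflection mV).
    """
    from .biophysics import ChannelSet, PassiveSpec, build_membrane
    from .morphology import uniform_cylinder

    model = uniform_cylinder(n_comp, length_um, diam_um, Ra=Ra)
    passive = PassiveSpec(tau_m=Rm * 1.0, Rm=Rm, Ra=Ra, Cm=1.0)
    membrane = build_membrane(model, ChannelSet("passive", []), passive)
    # inject past the end of the run so the final step still carries the DC
    system = assemble(membrane, [],
                      [CurrentInjection(0, i_inj_nA, 0.0, duration_ms + 10.0)], None)
    res = run(system, SolverConfig(dt=0.1, duration=duration_ms, settle=0.0,
                                   record=tuple(range(n_comp))))
    profile = np.array([res.vm[i][-1] for i in range(n_comp)]) - passive.e_pas
    x = (np.arange(n_comp) + 0.5) * length_um / n_comp
    return x, profile


def save_result_h5(result: SimulationResult, path) -> None:
    """Write traces + metadata to HDF5 (config echoed for provenance)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("t_ms", data=result.t)
        fh.create_dataset("ve_soma_mV", data=result.ve_soma)
        fh.create_dataset("spike_times_ms", data=result.spike_times)
        g = fh.create_group("vm_mV")
        for comp, trace in result.vm.items():
            g.create_dataset(str(comp), data=trace)
        fh.attrs["soma_index"] = result.soma_index
        fh.attrs["dt_ms"] = result.dt
        for k, v in result.meta.items():
            fh.attrs[k] = str(v)


def spikes_to_csv(result: SimulationResult, path, iteration: int = 0,
                  condition_id: str = "") -> None:
    """Append spike times as CSV rows (iteration, condition_id, spike_ms)."""
    import csv
    from pathlib import Path as _P

    new = not _P(path).exists()
    with open(path, "a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(["iteration", "condition_id", "spike_ms"])
        for t in result.spike_times:
            w.writerow([iteration, condition_id, f"{t:.4f}"])
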