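"""Experiment orchestration: condition grids, seed-paired ensembles, tables.

The ensemble design pairs every field condition with a no-field baseline
that shares the *same* synapse placements and PSP onset times: the per-
(morphology, iteration) random seed fully determines the stimulus, and only
the field parameters differ between conditions.  Seeds are spawned from a
master seed with ``numpy`` ``SeedSequence`` children keyed by (morphology,
iteration), so adding iterations never perturbs existing ones.

Runs are independent over (morphology, iteration, condition); ``execute``
processes them serially and is resumable when given an output directory
(completed keys are skipped).  Results come back as a long-format pandas
table (morphology, iteration, condition, statistic, value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .analysis import compute_phase_stats, relative_rate_change
from .biophysics import (build_membrane, ca1_channel_set, ca1_passive,
                         ca3_channel_set, ca3_passive)
from .morphology import DiscretizationConfig, discretize, read_swc
from .solver import SolverConfig, assemble, run
from .stimulation import (CurrentInjection, FieldSpec, assign_onsets,
                          place_synapses, tune_rate_for_band)

log = logging.getLogger("ephapsim")

DEFAULT_N_SYNAPSES = 100


@dataclass
class ExperimentPlan:
    name: str
    morphologies: list            # (kind, index) pairs, kind in {"ca3", "ca1"}
    iterations: int
    conditions: list              # (v_o, f_t, f_s, phi_s) tuples, baseline first
    region: str                   # synapse target: basal | apical | all
    band: str                     # firing band for rate tuning
    master_seed: int
    duration_ms: float = 1000.0
    settle_ms: float = 100.0
    dt_ms: float = 0.025
    n_synapses: int = DEFAULT_N_SYNAPSES
    injection_nA: float | None = None   # set for the current-injection protocol

    @property
    def n_pairs(self) -> int:
        """Number of (morphology, iteration) simulation pairs."""
        return len(self.morphologies) * self.iterations

    def pair_seed(self, m_index: int, iteration: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.master_seed,
                                    spawn_key=(m_index, iteration))
        return np.random.default_rng(ss)


def plan(experiment: str | dict, scale: float = 1.0, master_seed: int = 0,
         region: str = "basal", morphologies: list | None = None) -> ExperimentPlan:
    """Build an :class:`ExperimentPlan` from a canonical experiment bundle.

    ``scale`` in (0, 1] reduces the iteration count (never the condition
    grid); at scale 1 the amplitude sweep enumerates the full 10-morphology
    x 48-iteration ensemble.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    bundle = synthetic.canonical_experiment(experiment) \
        if isinstance(experiment, str) else dict(experiment)
    conditions = list(bundle["conditions"])
    if not conditions:
        raise ValueError("empty condition grid")
    if not any(c[0] == 0 for c in conditions):
        conditions.insert(0, (0.0, 10.0, synthetic.DEFAULT_FS_PER_MM,
                              synthetic.DEFAULT_PHIS_RAD))
    conditions.sort(key=lambda c: (c[0] != 0,))  # baseline first, order kept
    if morphologies is None:
        morphologies = [("ca3", i) for i in range(5)] + [("ca1", i) for i in range(5)]
    iterations = max(1, int(round(bundle.get("iterations", 48) * scale)))
    return ExperimentPlan(
        name=bundle.get("name", "custom"),
        morphologies=list(morphologies),
        iterations=iterations,
        conditions=conditions,
        region=region,
        band=bundle.get("firing_band", "medium"),
        master_seed=master_seed,
        duration_ms=bundle.get("duration_ms", 1000.0),
        settle_ms=bundle.get("settle_ms", 100.0),
        injection_nA=bundle.get("injection_nA"),
    )


def build_model(kind: str, index: int):
    """Discretized membrane-equipped model for one canonical morphology."""
    if kind == "ca3":
        cfg = synthetic.ca3_like_config(index)
        passive, cset = ca3_passive(), ca3_channel_set()
    elif kind == "ca1":
        cfg = synthetic.ca1_like_config(index)
        passive, cset = ca1_passive(), ca1_channel_set()
    else:
        raise ValueError(f"unknown morphology kind {kind!r}")
    tree = read_swc(synthetic.generate_morphology(cfg))
    model = discretize(tree, DiscretizationConfig(Ra=passive.Ra, Cm=passive.Cm))
    return build_membrane(model, cset, passive)


def _condition_id(cond) -> str:
    v_o, f_t, f_s, phi_s = cond
    return f"Vo{v_o:g}_ft{f_t:g}_fs{f_s:g}_phi{phi_s:.4f}"


def execute(p: ExperimentPlan, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run every (morphology, iteration, condition) of the plan.

    Per pair: one rate tuning (no field), one set of placements/onsets from
    the pair seed, then every condition with identical stimuli.  Solver
    failures are recorded as ``failed`` rows and the run continues.  With
    ``out_dir``, each pair writes a CSV keyed by (morphology, iteration) and
    completed pairs are skipped on re-execution.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    tuned_rate: dict = {}
    for m_idx, (kind, index) in enumerate(p.morphologies):
        membrane = None
        for it in range(p.iterations):
            key = f"{kind}{index}_it{it}"
            cache = out / f"{p.name}_{key}.csv" if out is not None else None
            if cache is not None and cache.exists():
                rows.append(pd.read_csv(cache, keep_default_na=False))
                log.info("skip completed %s", key)
                continue
            if membrane is None:
                membrane = build_model(kind, index)
            rng = p.pair_seed(m_idx, it)
            if p.injection_nA is None:
                if (kind, index) not in tuned_rate:
                    tune_rng = np.random.default_rng(
                        np.random.SeedSequence(p.master_seed,
                                               spawn_key=(1000 + m_idx,)))
                    rate, f_probe = tune_rate_for_band(
                        membrane, p.band, tune_rng, n_synapses=p.n_synapses,
                        region=p.region, probe_duration_ms=p.duration_ms,
                        settle_ms=p.settle_ms, dt_ms=p.dt_ms)
                    tuned_rate[(kind, index)] = rate
                    log.info("tuned %s%s: %.0f Hz -> F=%.1f Hz", kind, index,
                             rate, f_probe)
                rate = tuned_rate[(kind, index)]
                placements = place_synapses(membrane.model, p.n_synapses,
                                            p.region, rng)
                assign_onsets(placements, rate,
                              p.duration_ms + p.settle_ms, rng)
                injections = []
            else:
                placements = []
                injections = None  # filled per condition below
            pair_rows = []
            for cond in p.conditions:
                v_o, f_t, f_s, phi_s = cond
                fieldspec = FieldSpec(v_o=v_o, f_t=f_t, f_s=f_s, phi_s=phi_s) \
                    if v_o > 0 else None
                if p.injection_nA is not None:
                    injections = [CurrentInjection(
                        0, p.injection_nA, 0.0,
                        p.duration_ms + p.settle_ms + p.dt_ms)]
                cfg = SolverConfig(dt=p.dt_ms, duration=p.duration_ms,
                                   settle=p.settle_ms)
                try:
                    res = run(assemble(membrane, placements, injections,
                                       fieldspec), cfg)
                    spikes = res.spike_times
                    status = "ok"
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    log.warning("%s %s failed: %s", key, _condition_id(cond), exc)
                    spikes, status = np.empty(0), "failed"
                pair_rows.append(dict(
                    morphology=f"{kind}{index}", iteration=it,
                    condition=_condition_id(cond), v_o=v_o, f_t=f_t, f_s=f_s,
                    phi_s=phi_s, status=status, n_spikes=len(spikes),
                    spike_times=";".join(f"{t:.3f}" for t in spikes)))
                log.info("ran %s %s: %d spikes", key, _condition_id(cond),
                         len(spikes))
            df = pd.DataFrame(pair_rows)
            base = df[df.v_o == 0].n_spikes.iloc[0]
            dur_s = p.duration_ms * 1e-3
            df["rate_hz"] = df.n_spikes / dur_s
            df["rate_change_pct"] = [
                relative_rate_change(n / dur_s, base / dur_s) for n in df.n_spikes]
            if cache is not None:
                df.to_csv(cache, index=False)
            rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table.attrs["plan"] = p.name
    return table


def spike_trains_from_table(table: pd.DataFrame, condition: str) -> list[np.ndarray]:
    """Extract the per-iteration spike-time arrays of one condition."""
    sel = table[(table.condition == condition) & (table.status == "ok")]
    return [np.array([float(x) for x in s.split(";") if x])
            for s in sel.spike_times]


def ensemble_phase_stats(table: pd.DataFrame, condition: str, baseline: str,
                         f_t: float, duration_ms: float):
    """Pooled condition-vs-baseline statistics over the whole ensemble."""
    return compute_phase_stats(
        spike_trains_from_table(table, condition),
        spike_trains_from_table(table, baseline),
        f_t=f_t, duration_ms=duration_ms)


def match_spikes(baseline: np.ndarray, shifted: np.ndarray) -> np.ndarray:
    """Per-spike timing shifts: nearest neighbor within half the baseline ISI.

    Returns the signed shifts of matched spikes (unmatched spikes dropped).
    """
    baseline = np.asarray(baseline, dtype=float)
    shifted = np.asarray(shifted, dtype=float)
    if baseline.size == 0 or shifted.size == 0:
        return np.empty(0)
    half_isi = (np.median(np.diff(baseline)) / 2
                if baseline.size > 1 else np.inf)
    shifts = []
    for t in baseline:
        j = np.argmin(np.abs(shifted - t))
        d = shifted[j] - t
        if abs(d) <= half_isi:
            shifts.append(d)
    return np.array(shifts)


@dataclass
class InjectionProtocolResult:
    amplitudes: list
    spike_times: dict             # v_o -> spike-time array
    shifts: dict                  # v_o -> signed per-spike shifts vs baseline
    isi_mean_ms: float
    isi_cv: float


def current_injection_protocol(membrane=None, amplitudes=synthetic.AMPLITUDES_MV,
                               injection_nA: float = synthetic.INJECTION_NA,
                               duration_ms: float = 2000.0,
                               f_t: float = 10.0,
                               f_s: float = synthetic.DEFAULT_FS_PER_MM,
                               phi_s: float = synthetic.DEFAULT_PHIS_RAD,
                               dt_ms: float = 0.025,
                               settle_ms: float = 100.0) -> InjectionProtocolResult:
    """Somatic DC injection under a grid of field amplitudes.

    The no-field run must spike tonically (it anchors the matched-spike
    pairing); each field amplitude reports per-spike shifts against it.
    """
    if membrane is None:
        membrane = build_model("ca3", 0)
    inj = [CurrentInjection(0, injection_nA, 0.0, duration_ms + settle_ms + dt_ms)]
    cfg = SolverConfig(dt=dt_ms, duration=duration_ms, settle=settle_ms)
    spike_times, shifts = {}, {}
    for v_o in amplitudes:
        fieldspec = FieldSpec(v_o=v_o, f_t=f_t, f_s=f_s, phi_s=phi_s) \
            if v_o > 0 else None
        res = run(assemble(membrane, [], inj, fieldspec), cfg)
        spike_times[v_o] = res.spike_times
    base = spike_times[0.0]
    if len(base) < 3:
        raise RuntimeError(
            f"baseline injection produced only {len(base)} spikes; "
            "tonic firing is required")
    isi = np.diff(base)
    for v_o in amplitudes:
        shifts[v_o] = (np.zeros(len(base)) if v_o == 0
                       else match_spikes(base, spike_times[v_o]))
    return InjectionProtocolResult(
        amplitudes=list(amplitudes), spike_times=spike_times, shifts=shifts,
        isi_mean_ms=float(isi.mean()), isi_cv=float(isi.std() / isi.mean()))
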