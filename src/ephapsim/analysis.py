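"""Spike-train statistics quantifying field entrainment.

All statistics compare a field condition against its matched no-field
*baseline* (same synapse placements and PSP times, V_o = 0):

* PSTH: spikes pooled across iterations/morphologies into half-open
  ``[a, b)`` time bins (default 10 ms).
* Baseline difference: per-bin ``condition - baseline`` counts, so a
  positive value means the field added spikes in that bin.
* Phase folding: bins sharing the same oscillation phase are summed across
  cycles, collapsing the run onto one field period (100 ms at 10 Hz).
* Phase correlation: Pearson r between the folded difference at 1 ms
  resolution and the soma-referenced field phase sin(2 pi f_t t).
* Half-wave statistics: spike counts and mean folded timings computed
  separately for the positive ([0, T/2), soma V_e > 0) and negative
  half-waves of the oscillation.

The phase reference throughout is the field at the soma (x = 0), whose
positive half-wave occupies the first half of the folded window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "psth", "baseline_difference", "phase_fold", "phase_correlation",
    "halfwave_stats", "relative_rate_change", "compute_phase_stats",
    "HalfwaveStats", "PhaseStats",
]


def psth(trains, bin_ms: float, duration_ms: float) -> np.ndarray:
    """Peristimulus time histogram summed over a collection of spike trains.

    ``bin_ms`` must divide ``duration_ms``; bins are half-open [a, b).
    """
    nbin = duration_ms / bin_ms
    if abs(nbin - round(nbin)) > 1e-9:
        raise ValueError(f"bin {bin_ms} ms does not divide duration {duration_ms} ms")
    nbin = int(round(nbin))
    counts = np.zeros(nbin, dtype=np.int64)
    edges = np.arange(nbin + 1) * bin_ms
    for train in _as_trains(trains):
        h, _ = np.histogram(train, bins=edges)
        counts += h
    return counts


def _as_trains(trains):
    if isinstance(trains, dict):
        return list(trains.values())
    trains = list(trains)
    if trains and np.isscalar(trains[0]):
        return [np.asarray(trains)]
    return [np.asarray(t) for t in trains]


def baseline_difference(psth_condition: np.ndarray,
                        psth_baseline: np.ndarray) -> np.ndarray:
    """Per-bin ``condition - baseline``: positive where the field added spikes."""
    a = np.asarray(psth_condition)
    b = np.asarray(psth_baseline)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def phase_fold(histogram: np.ndarray, f_t: float, bin_ms: float) -> np.ndarray:
    """Sum histogram bins sharing the same oscillation phase.

    The histogram must span an integer number of field periods (e.g. 10
    cycles of a 10 Hz field over 1 s fold into a 100 ms window).
    """
    if f_t <= 0:
        raise ValueError("f_t must be > 0")
    h = np.asarray(histogram)
    period_ms = 1000.0 / f_t
    per = period_ms / bin_ms
    if abs(per - round(per)) > 1e-9:
        raise ValueError(f"bin {bin_ms} ms does not divide the period {period_ms} ms")
    per = int(round(per))
    cycles = len(h) / per
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError(
            f"histogram spans {cycles:.3f} periods; an integer count is required")
    return h.reshape(int(round(cycles)), per).sum(axis=0)


def phase_correlation(folded_difference: np.ndarray, f_t: float,
                      bin_ms: float = 1.0) -> float:
    """Pearson r between a phase-folded histogram and the soma field phase.

    The reference is sin(2 pi f_t t) at bin centers (the field at x = 0).
    Returns NaN for a zero-variance histogram (undefined correlation).
    """
    d = np.asarray(folded_difference, dtype=float)
    period_ms = 1000.0 / f_t
    if abs(len(d) * bin_ms - period_ms) > 1e-6:
        raise ValueError(
            f"expected one full period ({period_ms} ms) at {bin_ms} ms bins, "
            f"got {len(d)} bins")
    if np.std(d) == 0:
        return float("nan")
    centers = (np.arange(len(d)) + 0.5) * bin_ms
    ref = np.sin(2 * np.pi * f_t * centers * 1e-3)
    return float(np.corrcoef(d, ref)[0, 1])


@dataclass
class HalfwaveStats:
    positive_count: int
    negative_count: int
    positive_mean_ms: float       # mean folded time of positive-half spikes
    negative_mean_ms: float       # raw (not re-referenced)
    negative_mean_shifted_ms: float   # with half a period subtracted
    positive_sd_ms: float
    negative_sd_ms: float


def halfwave_stats(trains, f_t: float) -> HalfwaveStats:
    """Spike counts and mean timings per half-wave of the soma-phase field.

    Spikes are folded onto one period; the positive half-wave is [0, T/2)
    (where the soma V_e > 0), the negative [T/2, T).  The negative-half mean
    is also reported with T/2 subtracted for direct comparison.
    """
    if f_t <= 0:
        raise ValueError("f_t must be > 0")
    period = 1000.0 / f_t
    half = period / 2
    folded = np.concatenate([np.mod(np.asarray(t, dtype=float), period)
                             for t in _as_trains(trains)]) \
        if _as_trains(trains) else np.empty(0)
    pos = folded[folded < half]
    neg = folded[folded >= half]

    def _ms(x):
        return (float(np.mean(x)), float(np.std(x))) if x.size else (float("nan"),) * 2

    pmean, psd = _ms(pos)
    nmean, nsd = _ms(neg)
    return HalfwaveStats(
        positive_count=int(pos.size), negative_count=int(neg.size),
        positive_mean_ms=pmean, negative_mean_ms=nmean,
        negative_mean_shifted_ms=nmean - half if neg.size else float("nan"),
        positive_sd_ms=psd, negative_sd_ms=nsd)


def relative_rate_change(f_condition: float, f_baseline: float) -> float:
    """(F_condition - F_baseline) / F_baseline * 100 (%)."""
    if f_baseline == 0:
        return float("nan")
    return (f_condition - f_baseline) / f_baseline * 100.0


@dataclass
class PhaseStats:
    """Bundle of every per-condition statistic."""

    psth_bin_ms: float
    corr_bin_ms: float
    f_t: float
    duration_ms: float
    folded_difference: np.ndarray     # at psth_bin_ms resolution
    correlation_r: float              # at corr_bin_ms resolution
    halfwaves: HalfwaveStats
    firing_rate_hz: float
    baseline_rate_hz: float
    rate_change_pct: float


def compute_phase_stats(trains, baseline_trains, f_t: float, duration_ms: float,
                        psth_bin_ms: float = 10.0,
                        corr_bin_ms: float = 1.0) -> PhaseStats:
    """Full analysis pipeline for one condition against its baseline."""
    trains = _as_trains(trains)
    base = _as_trains(baseline_trains)
    h_c = psth(trains, psth_bin_ms, duration_ms)
    h_b = psth(base, psth_bin_ms, duration_ms)
    diff = baseline_difference(h_c, h_b)
    folded = phase_fold(diff, f_t, psth_bin_ms)
    fine = phase_fold(baseline_difference(psth(trains, corr_bin_ms, duration_ms),
                                          psth(base, corr_bin_ms, duration_ms)),
                      f_t, corr_bin_ms)
    r = phase_correlation(fine, f_t, corr_bin_ms)
    n_c = sum(len(t) for t in trains)
    n_b = sum(len(t) for t in base)
    dur_s = duration_ms * 1e-3 * max(len(trains), 1)
    f_c = n_c / dur_s
    f_b = n_b / dur_s
    return PhaseStats(
        psth_bin_ms=psth_bin_ms, corr_bin_ms=corr_bin_ms, f_t=f_t,
        duration_ms=duration_ms, folded_difference=folded, correlation_r=r,
        halfwaves=halfwave_stats(trains, f_t), firing_rate_hz=f_c,
        baseline_rate_hz=f_b, rate_change_pct=relative_rate_change(f_c, f_b))
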