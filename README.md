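# ephapsim

Single-neuron simulation of **ephaptic coupling**: how sinusoidal
extracellular potential oscillations — of the kind that local field
potentials, seizures, or transcranial/deep-brain stimulation impose on
hippocampal tissue — modulate the number and timing of action potentials in
multi-compartment CA1 and CA3 pyramidal-neuron models driven by spatially
distributed synaptic input.

It is aimed at computational neuroscientists who want a self-contained,
NEURON-free pipeline for this class of question: SWC morphologies in,
spike-phase statistics out, with every stage (discretization, channel
kinetics, integration, analysis) testable in isolation.

## The model

A neuron is a branched tree of cylindrical compartments (d_lambda
discretization of an SWC reconstruction). The extracellular potential is an
imposed separable sinusoid along the somatodendritic axis *x* (mm):

    V_e(x, t) = V_o sin(2π f_t t) · sin(2π f_s x + φ_s)

Standard cable theory treats the extracellular space as ground; here every
transmembrane element — capacitance, leak, active channels, synapses — sees
the *membrane* potential V_m = V_i − V_e instead, so the current through
ion channel *k* is

    I_k = g_k (V_i − V_e − V_k)

while axial currents still flow down gradients of the intracellular
potential V_i. Writing the cable equation in V_m, the field enters solely
through the axial drive Σ_j (V_e,j − V_e,i)/r_ij: a spatially uniform field
has no effect, and a field with structure along the tree polarizes it.

Active membranes follow the two hippocampal repertoires: CA1 (Na, K_DR,
K_A with a somatodendritic density gradient, I_h) and CA3 (Na, K_DR, K_M,
K_A, K_D, Ca_N/L/T, the Ca-dependent K_C and K_AHP, I_h, plus a submembrane
calcium pool). Synaptic drive is a homogeneous Poisson process over
synapses placed uniformly on dendritic compartments thinner than 0.35 µm,
each event an alpha conductance g(t) = g_max (t/τ) e^{−(t−τ)/τ} (τ = 0.1 ms,
g_max = 1 µS, E_syn = 0 mV). The fixed-step solver (25 µs; backward Euler
or midpoint Crank–Nicolson) solves the branched tree exactly per step with
a linear-time Hines elimination.

Analysis mirrors the study design: peristimulus histograms, baseline
(V_o = 0) differencing with PSP times held fixed across conditions, phase
folding onto one field period, Pearson correlation against the soma-phase
reference sin(2π f_t t), and per-half-wave spike counts and mean timings.

## Worked example

Tonic firing under somatic current injection, with and without a weak
field — the classic single-neuron ephaptic experiment:

```python
import numpy as np
from ephapsim import current_injection_protocol

res = current_injection_protocol(duration_ms=2000.0, amplitudes=(0.0, 0.25))
print(f"ISI {res.isi_mean_ms:.1f} ms, CV {res.isi_cv:.3f}")
print(f"median |shift| at 0.25 mV: {np.median(np.abs(res.shifts[0.25])):.2f} ms")
```

```
ISI 75.8 ms, CV 0.071
median |shift| at 0.25 mV: 0.62 ms
```

A 0.35 nA somatic DC injection makes the CA3 model fire tonically every
~76 ms; adding 0.25 mV, 10 Hz extracellular oscillations — the amplitude
scale of spontaneous LFPs — leaves the rate untouched but nudges each spike
by a fraction of a millisecond, the signature of weak ephaptic coupling.

The ensemble experiments run through the CLI:

```bash
ephapsim generate-morphologies            # ten synthetic SWC stand-ins
ephapsim -v run amplitude_sweep --scale 0.083 --region basal --out results/
ephapsim analyze results/amplitude_sweep_spikes.csv
```

which reports, per field amplitude, the phase correlation r (negative for
basal-targeted input: the positive soma half-wave suppresses spikes),
half-wave spike counts, and the firing-rate change versus baseline.

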