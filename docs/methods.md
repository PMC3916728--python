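# Methods

## Model overview

`ephapsim` simulates one pyramidal neuron at a time as a tree of
cylindrical compartments with Hodgkin–Huxley membranes, synaptic
conductances, and an *imposed* extracellular potential. The field is a
boundary condition, not a self-consistent computation: it does not react to
the neuron's own currents, which matches the single-neuron scope of the
study design (network-level ephaptic feedback is out of scope).

The central modeling assumption is that every transmembrane element is
driven by V_m = V_i − V_e while axial coupling acts on V_i. Solving the
cable equation in V_m makes the field appear as an axial drive term
Σ_j (V_e,j − V_e,i)/r_ij with V_e evaluated analytically from its closed
form at each compartment center and time step. Two consequences are exact
in this formulation and are enforced by tests: a spatially uniform field
(f_s = 0) leaves V_m — and therefore every spike time — bit-identical to
the no-field run, and an isolated compartment is completely insensitive to
any field.

## Morphology and discretization

SWC files are parsed as chains of typed cylinders (soma, axon, basal,
apical; codes 1–4), decomposed into unbranched sections, and split per the
d_lambda rule: each section becomes an odd number
n = ⌊(L/(0.1·λ₁₀₀) + 0.9)/2⌋·2 + 1 of equal-length compartments, where
λ₁₀₀ = 10⁵·√(d/(4π·100·Ra·Cm)) µm is the AC length constant at 100 Hz
computed from the section's length-weighted mean diameter. Compartment
areas are lateral cylinder surfaces (total membrane area is conserved
exactly); axial resistances sum the two half-compartment terms
4Ra(L/2)/(πd²).

The somatodendritic axis is the first principal component of the SWC point
cloud, oriented so the apical centroid is positive, with the origin at the
soma centroid; x is reported in mm because the field's spatial frequency is
in mm⁻¹. The soma is a cylinder chain, not a sphere, because the SWC format
describes every segment as a cylinder.

## Synthetic morphologies

The original CA3 (Samsonovich/Ascoli-style) and CA1 (Pyapali-style)
reconstructions are not redistributable, so `ephapsim.synthetic` generates
pyramidal-like stand-ins: a 35 µm soma, a 100 µm axon, five basal subtrees
(−x), and an apical trunk plus tuft (+x), with Rall-style diameter
tapering to sub-0.35 µm terminals so synapse placement never starves.
Defaults give ~380–410 compartments, 0.9–1.0 mm somatodendritic extent
(matching the 0.625 mm half-wavelength of the f_s = 0.8 mm⁻¹ field), and
~1.6·10⁻⁴ cm² of membrane. The membrane-area scale was chosen deliberately:
a smaller tree (the first design iteration had ~0.9·10⁻⁴ cm²) has an input
resistance near 270 MΩ and is so excitable that the 200–7000 Hz aggregate
PSP range cannot map onto the study's three firing bands, and 0.35 nA
drives far faster than the reported tonic period. Five seeds are designated
CA3-like and five CA1-like (the CA1 configuration has a longer trunk and
twice as many oblique branches — a more broadly branched apical tree).

What the generator does **not** emulate: realistic branch-length and
diameter distributions of real reconstructions, spines, 3D tortuosity
statistics. Tests passing on these stand-ins show the *pipeline and
physics* behave correctly at realistic scales; they do not certify
morphology-specific quantitative predictions for any real cell.

## Channel kinetics and densities

Kinetics use the standard functional families for these channels —
trap-style Na activation/inactivation, Borg-Graham (thermodynamic) forms
for K_DR/K_A/I_h, Boltzmann + bell-shaped time constants for K_M/K_D and
the Ca channels, a Moczydlowski–Latorre two-state BK gate (K_C), and a
calcium-pool-driven K_AHP gate. All parameters live in
`ephapsim.biophysics` and round-trip through YAML. Gating rates are
tabulated on a 0.05 mV grid over [−120, 60] mV and interpolated linearly in
the solver; the tables are dense enough that every gate is smooth at that
resolution (tested).

Passive properties are uniform: CA1 τ_m = 28 ms, R_m = 28 kΩcm², Ra =
150 Ωcm (hence Cm = 1 µF/cm² exactly); CA3 τ_m = 35 ms with R_m read as
25 kΩcm² (the plain Ωcm² print is treated as a typo — no plausible Cm
reaches τ_m = 35 ms otherwise), forcing Cm = 1.4 µF/cm². Reversals:
E_Na = +55, E_K = −90, E_h = −30, e_pas = −65 mV (the initial potential),
Ca treated ohmically with E_Ca = +120 mV — a deliberate simplification of
GHK that is adequate because the Ca currents' role here is spike-shape and
Ca-pool influx, not Ca reversal behavior near 0 mV.

Densities (S/cm²) are free parameters — no source at hand prints them for
exactly these cells — and were set in two steps, **before** the acceptance
runs were frozen:

1. *Structural choices*: axon carries Na and K_DR at somatic densities;
   CA1 K_A and I_h rise linearly with dendritic path distance (the
   hallmark CA1 gradients, capped at 6.5× and 9×); dendritic Na is 0.5× the
   somatic density in both sets. The last choice is load-bearing: at 1×,
   single distal PSPs (g_max = 1 µS is a strong event) relay into full
   somatic action potentials and the synthetic cells fire ~40 Hz at a
   200 Hz aggregate input rate, which contradicts the study's own band
   structure. At 0.5× dendrites still boost PSP propagation (the stated
   reason active dendrites are needed) without acting as a 1:1 relay.
2. *Protocol calibration*: the CA3 K_M (2·10⁻⁵) and K_AHP (5.65·10⁻⁵)
   densities and the Ca-pool decay (40 ms) were tuned so the model
   reproduces the study's stated current-injection behavior — tonic firing
   with a ~75 ms period under 0.35 nA somatic DC, and sub-millisecond spike
   shifts under 0.25 mV fields. A slower pool (~100 ms) produces a
   several-hundred-ms adaptation transient at injection onset that makes
   the 2-s interspike CV exceed 0.1 even though firing is asymptotically
   tonic; the K_AHP gate is linear in [Ca] for the same reason (a steeper
   power makes the rate control nearly bistable).

## Stimulation

Synapses are placed uniformly at random over dendritic compartments
thinner than 0.35 µm (optionally restricted to the basal or apical
subtree), with a uniform within-compartment position; 100 synapses share
the aggregate Poisson rate evenly. Event conductances follow the alpha
function peaking at g_max = 1 µS one τ = 0.1 ms after onset; overlapping
events sum. Inside the solver each compartment tracks the alpha kernel
with an exact two-state exponential recursion, with sub-step onset offsets
handled analytically, so event timing is not quantized to the grid.

The aggregate rate for a firing band (low ≤ 5 Hz < medium < 15 Hz ≤ high)
is found by bisection over [200, 7000] Hz with 1-s no-field probe
simulations; the probe's synapse geometry is held fixed across probes so
the search is deterministic per seed.

Within one (morphology, iteration) pair, placements and PSP times are
drawn once from the pair's seed and reused for every field condition — the
baseline pairing that all statistics rely on. Seeds derive from a master
seed via `SeedSequence(master, spawn_key=(morphology, iteration))`, so
enlarging an ensemble never perturbs existing members.

## Numerical integration

Fixed step dt = 25 µs. Gating states advance by the exponential
(exact-for-frozen-V) update using the voltage at the step start — the
staggered, half-step-offset interpretation — and the resulting conductances
enter a linear tree solve executed by Hines elimination (leaf-to-root,
then back-substitution; exact, linear time). Backward Euler is the default;
`crank_nicolson` solves for the midpoint voltage with midpoint sources and
extrapolates, which is second-order for the Ca-pool-free CA1 set (measured
spike-time drift < 0.25 ms over 1 s when dt is halved) and noticeably
tighter than backward Euler for CA3 (whose pool coupling is half-step
lagged). Spikes are upward 0 mV crossings of somatic V_m with a 2 ms
lockout, linearly interpolated between samples.

Each run simulates a 100 ms settle window with all stimuli active before
the reported window; reported time and the field phase share their origin
at the settle end, so folded-phase bins line up exactly with
sin(2π f_t t). Initial state: V_m = −65 mV everywhere, gates at their
steady state for −65 mV, Ca at its resting 50 nM.

A caveat established during development: *synaptically driven spike times
are chaotic*. Near-threshold dendritic events amplify any perturbation —
halving dt, or a 0.25 mV field — into spike-time shifts of tens of
milliseconds and occasional ±1 count changes later in a run. Step-size
robustness is therefore asserted pointwise (< 0.5 ms) on the tonic
injection protocol and statistically (spike counts) for PSP-driven runs;
likewise the ensemble statistics below are pooled counts, not
per-trajectory differences.

## Analysis conventions

Bins are half-open [a, b), time origin at the settle end. The baseline
difference is condition − baseline (positive = field added spikes). The
phase reference for correlations and half-waves is the field at the soma
(x = 0): with sin(φ_s) > 0 the positive half-wave is the first half of the
folded period (25 ms center at 10 Hz, 75 ms for the negative half; the
reported shifted negative mean subtracts the 50 ms half-period). The
correlation is the zero-lag Pearson coefficient between the 1 ms folded
difference histogram and sin(2π f_t t); a zero-variance histogram yields
NaN, never 0. Firing-rate change is (F_cond − F_base)/F_base·100; at the
ensemble level the package reports the *pooled* (overall) rate change,
because per-iteration 1-s counts (~10 spikes) quantize rate differences in
~10% steps of chaotic origin that say nothing about the field.

## Experiment scales

The full design is 5 + 5 morphologies × 48 iterations (480 pairs; 240
spike trains per cell class). Desk-scale runs shrink iterations, never the
condition grid. The shipped acceptance computations use: the 2-s,
single-model injection protocol; a 2-morphology (one CA3-like, one
CA1-like) × 8-iteration basal-stimulation ensemble at V_o ∈
{0, 0.25, 0.5, 4} mV for the rate-change bounds; and 10-iteration single-model ensembles per region for
the correlation-sign checks. These sizes keep a full reproduction around
ten minutes on one CPU while leaving the pooled estimators stable.

## Known limitations

- Channel kinetics are family-standard transcriptions, not trace-level
  copies of any published implementation; only behavior-level properties
  (spiking, tonic period, polarization signs, band structure) are
  validated.
- The ohmic Ca approximation overestimates Ca driving force at
  depolarized potentials.
- The field is purely sinusoidal and separable; no broadband or
  self-consistent fields.
- Single neuron only; no synaptic plasticity, inhibition, or NMDA voltage
  dependence.
- Synthetic morphologies are statistical stand-ins, not reconstructions;
  results specific to real dendritic geometry (e.g. exact correlation
  magnitudes per cell) should not be over-interpreted. In particular the
  CA1-like stand-in keeps more synaptic volleys within a fraction of a
  millivolt of threshold than a real reconstruction, so its firing rate
  responds measurably (a few percent) even to 0.25 mV fields — stronger
  weak-field sensitivity than the original cells exhibit.
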