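"""Synthetic pyramidal-like morphologies and canonical experiment bundles.

The study design calls for five CA3-style and five CA1-style reconstructed
pyramidal cells; the original reconstruction files are not redistributable,
so this module generates *synthetic stand-ins*: SWC trees with a cylindrical
soma chain, a 100 um axon, several basal subtrees extending in -x and an
apical trunk plus tuft extending in +x, with Rall-style diameter tapering so
that terminal branches fall below the 0.35 um synapse-hosting threshold.
Total somatodendritic extent is ~0.5-1 mm, matching the spatial scale of the
imposed extracellular field (half wavelength 0.625 mm at f_s = 0.8 /mm).

It also defines the canonical stimulation/field parameter grids used by the
experiments (amplitude, temporal-frequency and spatial sweeps, somatic
current injection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Structure

# --- canonical parameter grids -------------------------------------------------

AMPLITUDES_MV = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
TEMPORAL_FREQUENCIES_HZ = (1.0, 5.0, 10.0, 20.0, 50.0, 100.0)
DEFAULT_FS_PER_MM = 0.8
DEFAULT_PHIS_RAD = 3 * np.pi / 10
# (f_s, phi_s, amplitude multiplier): halving f_s doubles V_o so the peak
# field gradient 2*pi*f_s*V_o is unchanged
SPATIAL_SETTINGS = (
    (0.8, 3 * np.pi / 10, 1.0),
    (0.8, np.pi / 2, 1.0),
    (0.4, np.pi / 2, 2.0),
)
FIRING_BANDS = {"low": (0.0, 5.0), "medium": (5.0, 15.0), "high": (15.0, np.inf)}
INJECTION_NA = 0.35


@dataclass(frozen=True)
class MorphogenConfig:
    seed: int = 0
    n_basal_trees: int = 5
    basal_extent_um: float = 260.0
    basal_orders: int = 2            # binary branchings after the stem
    apical_trunk_um: float = 420.0
    apical_tuft_um: float = 300.0
    tuft_orders: int = 2
    n_oblique: int = 3
    soma_diam_um: float = 35.0
    soma_length_um: float = 35.0
    axon_length_um: float = 100.0    # short axon; longer makes no difference
    axon_diam_um: float = 1.0
    trunk_diam_um: float = 3.5
    basal_stem_diam_um: float = 1.6
    taper: float = 0.45              # child/parent diameter at a symmetric branch
    terminal_diam_um: float = 0.2    # floor; guarantees sub-0.35 um hosts
    oblique_diam_um: float = 0.3
    wiggle: float = 0.15             # rad, random direction jitter per step
    step_um: float = 25.0            # polyline sampling step

    def __post_init__(self):
        if self.terminal_diam_um >= 0.35:
            raise ValueError("terminal_diam_um must be < 0.35 um to host synapses")
        if self.terminal_diam_um >= self.trunk_diam_um:
            raise ValueError("terminal diameter must be smaller than the trunk diameter")
        if not (0 < self.taper < 1):
            raise ValueError("taper must be in (0, 1)")


# seeds designated as the two canonical five-cell cohorts
CA3_LIKE_SEEDS = (0, 1, 2, 3, 4)
CA1_LIKE_SEEDS = (100, 101, 102, 103, 104)


def ca3_like_config(index: int) -> MorphogenConfig:
    """Compact basal tree, moderately branched apical tree."""
    return MorphogenConfig(seed=CA3_LIKE_SEEDS[index])


def ca1_like_config(index: int) -> MorphogenConfig:
    """Longer and more branched apical tree (obliques along the whole trunk)."""
    return MorphogenConfig(
        seed=CA1_LIKE_SEEDS[index],
        apical_trunk_um=440.0,
        apical_tuft_um=300.0,
        n_oblique=6,
        basal_extent_um=230.0,
    )


class _SwcBuilder:
    def __init__(self):
        self.lines = []
        self.next_id = 1

    def add(self, structure: Structure, pos, radius: float, parent: int) -> int:
        pid = self.next_id
        self.next_id += 1
        x, y, z = pos
        self.lines.append(
            f"{pid} {int(structure)} {x:.4f} {y:.4f} {z:.4f} {radius:.4f} {parent}"
        )
        return pid

    def text(self) -> str:
        return "# synthetic pyramidal-like morphology (ephapsim)\n" + "\n".join(self.lines) + "\n"


def _unit(v):
    return v / np.linalg.norm(v)


def _jitter(direction, rng, sigma):
    d = direction + rng.normal(0.0, sigma, 3)
    return _unit(d)


def _grow_segment(b, rng, cfg, structure, start_pos, start_parent, direction,
                  length, diam):
    """Grow a polyline of ~cfg.step_um steps; returns (end_id, end_pos, end_dir)."""
    n_steps = max(1, int(round(length / cfg.step_um)))
    step = length / n_steps
    pos = np.array(start_pos, dtype=float)
    parent = start_parent
    d = np.array(direction, dtype=float)
    for _ in range(n_steps):
        d = _jitter(d, rng, cfg.wiggle)
        pos = pos + d * step
        parent = b.add(structure, pos, diam / 2, parent)
    return parent, pos, d


def _grow_subtree(b, rng, cfg, structure, pos, parent, direction, length, diam,
                  orders):
    """Recursive symmetric binary tree with Rall-like diameter taper."""
    end_id, end_pos, end_dir = _grow_segment(
        b, rng, cfg, structure, pos, parent, direction, length, diam)
    if orders <= 0:
        return
    child_d = max(diam * cfg.taper * rng.uniform(0.9, 1.1), cfg.terminal_diam_um)
    for sign in (+1, -1):
        perp = np.cross(end_dir, rng.normal(size=3))
        perp = _unit(perp)
        new_dir = _unit(end_dir + sign * 0.6 * perp)
        _grow_subtree(b, rng, cfg, structure, end_pos, end_id, new_dir,
                      length * rng.uniform(0.85, 1.15), child_d, orders - 1)


def generate_morphology(cfg: MorphogenConfig | None = None) -> str:
    """Return SWC text for one synthetic pyramidal-like cell (deterministic per seed)."""
    cfg = cfg or MorphogenConfig()
    rng = np.random.default_rng(cfg.seed)
    b = _SwcBuilder()

    # soma: 3-point cylinder chain along x, centered at the origin
    r = cfg.soma_diam_um / 2
    half = cfg.soma_length_um / 2
    root = b.add(Structure.SOMA, (-half, 0, 0), r, -1)
    mid = b.add(Structure.SOMA, (0, 0, 0), r, root)
    top = b.add(Structure.SOMA, (half, 0, 0), r, mid)

    # axon: straight, off the basal pole, slightly off-axis
    ax_dir = _unit(np.array([-1.0, 0.35, 0.0]))
    _grow_segment(b, rng, cfg, Structure.AXON, (-half, 0, 0), root, ax_dir,
                  cfg.axon_length_um, cfg.axon_diam_um)

    # basal trees: stems fan out in a cone around -x
    n_levels = 1 + cfg.basal_orders
    seg_len = cfg.basal_extent_um / n_levels
    for k in range(cfg.n_basal_trees):
        ang = 2 * np.pi * k / cfg.n_basal_trees
        d0 = _unit(np.array([-1.0, 0.5 * np.cos(ang), 0.5 * np.sin(ang)]))
        _grow_subtree(b, rng, cfg, Structure.BASAL, (-half, 0, 0), root, d0,
                      seg_len, cfg.basal_stem_diam_um, cfg.basal_orders)

    # apical trunk: straight up +x with taper, obliques branching off
    trunk_dir = np.array([1.0, 0.0, 0.0])
    n_steps = max(2, int(round(cfg.apical_trunk_um / cfg.step_um)))
    step = cfg.apical_trunk_um / n_steps
    pos = np.array([half, 0.0, 0.0])
    parent = top
    trunk_ids = []
    d = trunk_dir.copy()
    for i in range(n_steps):
        d = _jitter(d, rng, cfg.wiggle / 2)
        d = _unit(d + np.array([0.3, 0, 0]))  # keep the trunk heading apical
        pos = pos + d * step
        diam = cfg.trunk_diam_um * (1 - 0.4 * (i + 1) / n_steps)
        parent = b.add(Structure.APICAL, pos, diam / 2, parent)
        trunk_ids.append((parent, pos.copy(), d.copy()))
    # obliques: thin side branches along the trunk
    for _ in range(cfg.n_oblique):
        host, hpos, hdir = trunk_ids[rng.integers(0, len(trunk_ids) - 1)]
        perp = _unit(np.cross(hdir, rng.normal(size=3)))
        ob_dir = _unit(perp + 0.4 * hdir)
        _grow_segment(b, rng, cfg, Structure.APICAL, hpos, host, ob_dir,
                      rng.uniform(80, 120), cfg.oblique_diam_um)
    # tuft: binary tree in a cone around +x from the trunk end
    end_id, end_pos, _ = trunk_ids[-1]
    tuft_levels = 1 + cfg.tuft_orders
    tuft_seg = cfg.apical_tuft_um / tuft_levels
    tuft_d0 = max(cfg.trunk_diam_um * 0.6 * cfg.taper, cfg.terminal_diam_um)
    for sign in (+1, -1):
        d0 = _unit(np.array([1.0, 0.35 * sign, 0.1 * rng.standard_normal()]))
        _grow_subtree(b, rng, cfg, Structure.APICAL, end_pos, end_id, d0,
                      tuft_seg, tuft_d0, cfg.tuft_orders)
    return b.text()


def canonical_experiment(name: str) -> dict:
    """Full parameter bundle for a named experiment of the study.

    Names: ``amplitude_sweep``, ``frequency_sweep``, ``spatial_sweep``,
    ``current_injection``.  Conditions are (V_o mV, f_t Hz, f_s /mm,
    phi_s rad) tuples; every grid includes the V_o = 0 baseline.
    """
    base = dict(duration_ms=1000.0, settle_ms=100.0, iterations=48,
                n_morphologies=10, firing_band="medium")
    if name == "amplitude_sweep":
        conds = [(v, 10.0, DEFAULT_FS_PER_MM, DEFAULT_PHIS_RAD) for v in AMPLITUDES_MV]
        return {**base, "name": name, "conditions": conds}
    if name == "frequency_sweep":
        conds = [(0.0, 10.0, DEFAULT_FS_PER_MM, DEFAULT_PHIS_RAD)]
        conds += [(4.0, ft, DEFAULT_FS_PER_MM, DEFAULT_PHIS_RAD)
                  for ft in TEMPORAL_FREQUENCIES_HZ]
        return {**base, "name": name, "conditions": conds}
    if name == "spatial_sweep":
        conds = []
        for fs, phis, mult in SPATIAL_SETTINGS:
            for v in AMPLITUDES_MV:
                conds.append((v * mult, 10.0, fs, phis))
        # dedupe baselines
        seen, uniq = set(), []
        for c in conds:
            key = c if c[0] > 0 else (0.0,)
            if key not in seen:
                seen.add(key)
                uniq.append(c if c[0] > 0 else (0.0, 10.0, DEFAULT_FS_PER_MM, DEFAULT_PHIS_RAD))
        return {**base, "name": name, "conditions": uniq}
    if name == "current_injection":
        conds = [(v, 10.0, DEFAULT_FS_PER_MM, DEFAULT_PHIS_RAD) for v in AMPLITUDES_MV]
        return {**base, "name": name, "conditions": conds,
                "injection_nA": INJECTION_NA, "duration_ms": 2000.0, "iterations": 1}
    raise ValueError(f"unknown experiment name: {name!r}")
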