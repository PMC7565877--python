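"""Synthetic structures and trajectories with known ground truth.

Three generators back the test strategy of the whole package:

* channel phantoms — rings of pseudo-atoms around a parametric centerline
  with an analytic clearance profile (``wall radius - atom radius``);
* multi-ligand diffusion — independent continuous-time jump processes on a
  region graph, observed at frame times, with coordinates constructed so a
  distance-cutoff contact criterion recovers the state sequence exactly;
* base-pair distance series — per-frame hydrogen-bond distances realising a
  planted associated/partial/melted schedule, optionally stratified.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, SpecError
from .regions import SOLVENT, MacroRegion, RegionGraph
from .states import LigandStateTimeline
from .structures import MolecularStructure, ResidueSelection, TrajectoryWindow

__all__ = [
    "StraightCenterline",
    "BentCenterline",
    "ChannelPhantomSpec",
    "ChannelPhantom",
    "make_channel_phantom",
    "gaussian_constriction",
    "DiffusionModelSpec",
    "DiffusionResult",
    "make_diffusion_trajectory",
    "ligand_count_from_concentration",
    "MeltSeriesSpec",
    "MeltSeriesResult",
    "make_basepair_series",
]

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# channel phantoms

class StraightCenterline:
    """Straight segment of given length along ``direction`` from ``origin``."""

    def __init__(self, length: float, origin=(0.0, 0.0, 0.0),
                 direction=(0.0, 0.0, 1.0)):
        self.length = float(length)
        self.origin = np.asarray(origin, dtype=np.float64)
        d = np.asarray(direction, dtype=np.float64)
        self.direction = d / np.linalg.norm(d)

    def point(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction

    def tangent(self, s: float) -> np.ndarray:
        return self.direction.copy()


class BentCenterline:
    """Two straight legs joined by a 90-degree circular arc (in the xz plane).

    Leg 1 runs along +z, the arc turns toward +x, leg 2 runs along +x.
    """

    def __init__(self, leg: float, bend_radius: float = 6.0,
                 origin=(0.0, 0.0, 0.0)):
        self.leg = float(leg)
        self.r = float(bend_radius)
        self.origin = np.asarray(origin, dtype=np.float64)
        self.arc_len = 0.5 * np.pi * self.r
        self.length = 2.0 * self.leg + self.arc_len

    def point(self, s: float) -> np.ndarray:
        if s <= self.leg:
            return self.origin + np.array([0.0, 0.0, s])
        if s <= self.leg + self.arc_len:
            theta = (s - self.leg) / self.r
            centre = self.origin + np.array([self.r, 0.0, self.leg])
            return centre + np.array([-self.r * np.cos(theta), 0.0,
                                      self.r * np.sin(theta)])
        t = s - self.leg - self.arc_len
        corner = self.origin + np.array([self.r, 0.0, self.leg + self.r])
        return corner + np.array([t, 0.0, 0.0])

    def tangent(self, s: float) -> np.ndarray:
        if s <= self.leg:
            return np.array([0.0, 0.0, 1.0])
        if s <= self.leg + self.arc_len:
            theta = (s - self.leg) / self.r
            return np.array([np.sin(theta), 0.0, np.cos(theta)])
        return np.array([1.0, 0.0, 0.0])


def gaussian_constriction(base_radius: float, min_radius: float,
                          center: float, width: float) -> Callable[[float], float]:
    """Wall-radius profile dipping from ``base_radius`` to ``min_radius``."""
    def profile(s: float) -> float:
        return base_radius - (base_radius - min_radius) * np.exp(
            -0.5 * ((s - center) / width) ** 2)
    return profile


@dataclass
class ChannelPhantomSpec:
    centerline: object                       # StraightCenterline / BentCenterline
    wall_radius: float | Callable[[float], float] = 4.0
    atom_radius: float = 1.5
    atoms_per_ring: int = 24
    ring_spacing: float = 1.0
    seed: int = 0

    def wall_radius_at(self, s: float) -> float:
        if callable(self.wall_radius):
            return float(self.wall_radius(s))
        return float(self.wall_radius)

    def __post_init__(self) -> None:
        if self.atoms_per_ring < 3:
            raise SpecError("atoms_per_ring must be >= 3")
        if self.ring_spacing > 2.0 * self.atom_radius:
            raise SpecError(
                "ring_spacing must be <= 2*atom_radius (no escape gaps)")


@dataclass
class ChannelPhantom:
    structure: MolecularStructure
    arclengths: np.ndarray          # (K,) ring positions along the centerline
    true_clearance: np.ndarray      # (K,) wall radius - atom radius
    spec: ChannelPhantomSpec

    def centerline_point(self, s: float) -> np.ndarray:
        return self.spec.centerline.point(s)


def make_channel_phantom(spec: ChannelPhantomSpec) -> ChannelPhantom:
    """Build a tube of pseudo-atom rings with an analytic clearance profile.

    Ring frames are transported along the centerline to avoid twist at
    bends.  A wall radius at or below the atom radius seals the channel; a
    warning with the plug location is emitted in that case.
    """
    cl = spec.centerline
    s_values = np.arange(0.0, cl.length + 1e-9, spec.ring_spacing)
    n_rings = len(s_values)
    walls = np.array([spec.wall_radius_at(s) for s in s_values])
    max_wall = float(walls.max())
    coords_list: list[np.ndarray] = []
    ring_of_atom: list[int] = []
    clearances = np.empty(n_rings)

    # rotation-minimising frame transport
    t_prev = cl.tangent(0.0)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t_prev[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t_prev, helper)
    u /= np.linalg.norm(u)

    phis = 2.0 * np.pi * np.arange(spec.atoms_per_ring) / spec.atoms_per_ring
    plugged_at: float | None = None
    for k, s in enumerate(s_values):
        t = cl.tangent(s)
        axis = np.cross(t_prev, t)
        sin_a = np.linalg.norm(axis)
        if sin_a > 1e-12:
            axis /= sin_a
            cos_a = float(np.clip(np.dot(t_prev, t), -1.0, 1.0))
            u = (u * cos_a + np.cross(axis, u) * sin_a
                 + axis * np.dot(axis, u) * (1.0 - cos_a))
            u /= np.linalg.norm(u)
        t_prev = t
        v = np.cross(t, u)
        wall = float(walls[k])
        clearances[k] = wall - spec.atom_radius
        if clearances[k] <= 0 and plugged_at is None:
            plugged_at = float(s)
        centre = cl.point(s)
        ring = (centre[None, :]
                + wall * np.outer(np.cos(phis), u)
                + wall * np.outer(np.sin(phis), v))
        coords_list.append(ring)
        ring_of_atom.extend([k] * len(ring))
        if clearances[k] <= 0:
            # sealed section: fill the cross-section out to the widest wall so
            # the plug occludes the whole channel, not just its centre
            r = wall + spec.atom_radius
            while r < max_wall:
                n_fill = max(3, int(np.ceil(2.0 * np.pi * r / spec.atom_radius)))
                fill_phis = 2.0 * np.pi * np.arange(n_fill) / n_fill
                coords_list.append(
                    centre[None, :]
                    + r * np.outer(np.cos(fill_phis), u)
                    + r * np.outer(np.sin(fill_phis), v))
                ring_of_atom.extend([k] * n_fill)
                r += spec.atom_radius

    coords = np.concatenate(coords_list)
    if plugged_at is not None:
        warnings.warn(
            f"channel sealed: wall radius <= atom radius at arclength "
            f"{plugged_at:.1f} A", stacklevel=2)

    n = len(coords)
    structure = MolecularStructure(
        atom_ids=np.arange(n, dtype=np.int64),
        atom_names=["X"] * n,
        elements=["X"] * n,
        residue_numbers=np.asarray(ring_of_atom, dtype=np.int64) + 1,
        residue_names=["PHT"] * n,
        subunit_ids=["W"] * n,
        coordinates=coords,
        vdw_radii=np.full(n, spec.atom_radius),
    )
    return ChannelPhantom(
        structure=structure,
        arclengths=s_values,
        true_clearance=clearances,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# multi-ligand diffusion on a region graph

def ligand_count_from_concentration(concentration_mM: float = 15.0,
                                    box_edge: float = 180.0) -> int:
    """Ligand count for a concentration in a cubic box of edge ``box_edge`` A.

    The defaults encode the study-style setup of 15 mM ligand in a box
    extending ~15 A beyond a large polymerase complex.
    """
    per_litre = concentration_mM * 1e-3 * AVOGADRO
    per_cubic_angstrom = per_litre / 1e27
    return max(1, round(per_cubic_angstrom * box_edge ** 3))


@dataclass
class DiffusionModelSpec:
    """Continuous-time jump model of ligands hopping among region anchors."""

    region_names: Sequence[str]
    anchors: dict                       # region -> (3,) coordinates, A
    rates: dict = field(default_factory=dict)   # (from, to) -> ns^-1
    region_classes: dict = field(default_factory=dict)  # region -> class
    n_ligands: int | None = None        # default from 15 mM in a nominal box
    frame_interval: float = 1.0         # ns
    n_frames: int = 1000
    jitter: float = 0.5                 # A, Gaussian, clipped for separability
    contact_cutoff: float = 4.0         # A, criterion the fixture guarantees
    solvent_anchor: np.ndarray = field(
        default_factory=lambda: np.array([500.0, 500.0, 500.0]))
    initial_state: str = SOLVENT
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_names = list(self.region_names)
        if self.n_ligands is None:
            self.n_ligands = ligand_count_from_concentration()
        if self.n_ligands < 1:
            raise SpecError("n_ligands must be >= 1")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if any(r < 0 for r in self.rates.values()):
            raise SpecError("jump rates must be non-negative")
        missing = set(self.region_names) - set(self.anchors)
        if missing:
            raise ConfigError(f"anchors missing for regions: {sorted(missing)}")
        self.solvent_anchor = np.asarray(self.solvent_anchor, dtype=np.float64)
        states = set(self.region_names) | {SOLVENT}
        for a, b in self.rates:
            if a not in states or b not in states or a == b:
                raise ConfigError(f"invalid rate pair ({a}, {b})")
        # regions must be separable under the contact criterion
        names = self.region_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = np.linalg.norm(np.asarray(self.anchors[names[i]], float)
                                   - np.asarray(self.anchors[names[j]], float))
                if d < 2.0 * self.contact_cutoff:
                    raise ConfigError(
                        f"anchors of {names[i]} and {names[j]} are {d:.1f} A "
                        f"apart (< 2 x cutoff): regions would overlap")

    @property
    def states(self) -> list[str]:
        return [SOLVENT] + list(self.region_names)

    def generator_matrix(self) -> np.ndarray:
        states = self.states
        pos = {s: i for i, s in enumerate(states)}
        q = np.zeros((len(states), len(states)))
        for (a, b), rate in self.rates.items():
            q[pos[a], pos[b]] = rate
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> dict[str, float]:
        """Stationary law of the jump process (null space of the generator)."""
        q = self.generator_matrix()
        if np.allclose(q, 0.0):
            # degenerate: no jumps ever happen; mass stays at the initial state
            pi = {s: 0.0 for s in self.states}
            pi[self.initial_state] = 1.0
            return pi
        n = q.shape[0]
        a = np.vstack([q.T, np.ones((1, n))])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        return dict(zip(self.states, pi))


@dataclass
class DiffusionResult:
    trajectory: TrajectoryWindow
    timeline: LigandStateTimeline      # ground truth
    structure: MolecularStructure
    graph: RegionGraph
    spec: DiffusionModelSpec


# small tetrahedral offsets for the pseudo-atoms marking a region anchor
_ANCHOR_OFFSETS = 0.5 / np.sqrt(3.0) * np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
])
_ANCHOR_SPREAD = 0.5  # max |offset|


def _simulate_ctmc(spec: DiffusionModelSpec, ligand: int) -> list[str]:
    """State at each frame time for one ligand (exact jump-process sampling)."""
    rng = np.random.default_rng([spec.seed, ligand])
    states = spec.states
    out_rates = {
        s: [(b, r) for (a, b), r in sorted(spec.rates.items()) if a == s and r > 0]
        for s in states
    }
    t_end = (spec.n_frames - 1) * spec.frame_interval
    observed: list[str] = []
    state = spec.initial_state
    t = 0.0
    next_frame = 0
    frame_times = np.arange(spec.n_frames) * spec.frame_interval
    while next_frame < spec.n_frames:
        total = sum(r for _, r in out_rates[state])
        dwell = np.inf if total == 0 else rng.exponential(1.0 / total)
        t_jump = t + dwell
        while next_frame < spec.n_frames and frame_times[next_frame] < t_jump:
            observed.append(state)
            next_frame += 1
        if t_jump > t_end or total == 0:
            break
        targets, rates = zip(*out_rates[state])
        probs = np.asarray(rates) / total
        state = targets[rng.choice(len(targets), p=probs)]
        t = t_jump
    while len(observed) < spec.n_frames:
        observed.append(state)
    return observed


def make_diffusion_trajectory(spec: DiffusionModelSpec) -> DiffusionResult:
    """Simulate independent ligand jump processes and realise coordinates.

    Each ligand is one heavy pseudo-atom placed at its current region's
    anchor plus clipped Gaussian jitter — guaranteed within the contact
    cutoff of that region's marker atoms and strictly outside every other
    region's.  The exact state sequence is returned as the ground-truth
    timeline.
    """
    names = list(spec.region_names)
    n_region_atoms = len(names) * len(_ANCHOR_OFFSETS)
    n_lig = spec.n_ligands
    n_atoms = n_region_atoms + n_lig

    region_coords = np.concatenate([
        np.asarray(spec.anchors[name], dtype=np.float64) + _ANCHOR_OFFSETS
        for name in names
    ])

    atom_ids = np.arange(n_atoms, dtype=np.int64)
    atom_names = (["C"] * n_region_atoms) + ["P"] * n_lig
    elements = (["C"] * n_region_atoms) + ["P"] * n_lig
    residue_numbers = np.concatenate([
        np.repeat(np.arange(len(names)) + 1, len(_ANCHOR_OFFSETS)),
        np.arange(n_lig) + 1001,
    ])
    residue_names = (["MRK"] * n_region_atoms) + ["CTP"] * n_lig
    subunit_ids = (["R"] * n_region_atoms) + ["L"] * n_lig

    # ligand placeholder coordinates (frame 0 overwrites them)
    base_coords = np.vstack([region_coords,
                             np.tile(spec.solvent_anchor, (n_lig, 1))])
    structure = MolecularStructure(
        atom_ids=atom_ids,
        atom_names=atom_names,
        elements=elements,
        residue_numbers=residue_numbers,
        residue_names=residue_names,
        subunit_ids=subunit_ids,
        coordinates=base_coords,
        vdw_radii=np.full(n_atoms, 1.7),
    )

    sequences = [_simulate_ctmc(spec, li) for li in range(n_lig)]

    max_disp = spec.contact_cutoff - _ANCHOR_SPREAD - 0.1
    rng = np.random.default_rng([spec.seed, 10**6])
    frames = np.empty((spec.n_frames, n_atoms, 3))
    frames[:, :n_region_atoms, :] = region_coords[None, :, :]
    anchor_of = {name: np.asarray(spec.anchors[name], dtype=np.float64)
                 for name in names}
    anchor_of[SOLVENT] = spec.solvent_anchor
    for f in range(spec.n_frames):
        for li in range(n_lig):
            disp = rng.normal(scale=spec.jitter, size=3)
            norm = np.linalg.norm(disp)
            if norm > max_disp:
                disp *= max_disp / norm
            frames[f, n_region_atoms + li] = anchor_of[sequences[li][f]] + disp

    frame_times = np.arange(spec.n_frames) * spec.frame_interval
    if spec.frame_interval <= 0:
        raise SpecError("frame_interval must be positive")
    traj = TrajectoryWindow(
        coordinates=frames,
        frame_times=frame_times,
        ligand_atom_groups=[np.array([n_region_atoms + li]) for li in range(n_lig)],
        topology=structure,
    )

    occupied = [[frozenset() if sequences[li][f] == SOLVENT
                 else frozenset([sequences[li][f]]) for li in range(n_lig)]
                for f in range(spec.n_frames)]
    primary = [[sequences[li][f] for li in range(n_lig)]
               for f in range(spec.n_frames)]
    timeline = LigandStateTimeline(
        occupied=occupied, primary=primary, frame_times=frame_times)

    regions = [
        MacroRegion(
            name=name,
            region_class=spec.region_classes.get(name, "entry"),
            selection=ResidueSelection.from_dict({"R": {i + 1}}),
        )
        for i, name in enumerate(names)
    ]
    adjacency = {frozenset((a, b)) for (a, b) in spec.rates if SOLVENT not in (a, b)}
    graph = RegionGraph(regions=regions, adjacency=adjacency)

    return DiffusionResult(trajectory=traj, timeline=timeline,
                           structure=structure, graph=graph, spec=spec)


# ---------------------------------------------------------------------------
# base-pair melting series

@dataclass
class MeltSeriesSpec:
    """Planted per-register (melted, partial) fractions, optionally stratified.

    ``strata`` maps a stratum label to ``(frame_fraction, melted_multiplier,
    partial_multiplier)``; multipliers scale the base fractions within that
    stratum.  ``mode`` 'exact' realises fractions as exact frame counts,
    'bernoulli' draws each frame independently.
    """

    registers: dict                     # label -> (melted_frac, partial_frac)
    n_frames: int = 1000
    strata: dict | None = None
    mode: str = "exact"
    n_bonds: int = 3                    # G.C pairs downstream
    intact_distance: float = 2.9        # A +- 0.1
    broken_distance: float = 8.0        # A +- 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.mode not in ("exact", "bernoulli"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.n_bonds not in (2, 3):
            raise SpecError("n_bonds must be 2 or 3")
        for reg, (m, p) in self.registers.items():
            for mult_m, mult_p in self._multipliers().values():
                if m * mult_m + p * mult_p > 1.0 + 1e-12:
                    raise SpecError(
                        f"register {reg}: melted+partial fractions exceed 1")
        if self.strata is not None:
            total = sum(v[0] for v in self.strata.values())
            if not np.isclose(total, 1.0):
                raise SpecError("stratum frame fractions must sum to 1")

    def _multipliers(self) -> dict:
        if self.strata is None:
            return {None: (1.0, 1.0)}
        return {k: (v[1], v[2]) for k, v in self.strata.items()}


_WC_ATOMS = {
    3: (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),   # G.C
    2: (("N1", "N3"), ("N6", "O4")),                  # A.T
}


@dataclass
class MeltSeriesResult:
    trajectory: TrajectoryWindow
    structure: MolecularStructure
    pairs: list                          # BasePairDefinition per register
    true_states: object                  # DataFrame frames x registers
    strata: list[str] | None


def _allocate_states(n: int, melted_frac: float, partial_frac: float,
                     mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "exact":
        n_melt = round(melted_frac * n)
        n_part = round(partial_frac * n)
        states = np.array(
            ["melted"] * n_melt + ["partial"] * n_part
            + ["associated"] * (n - n_melt - n_part), dtype=object)
        return states[rng.permutation(n)]
    draws = rng.random(n)
    states = np.where(draws < melted_frac, "melted",
                      np.where(draws < melted_frac + partial_frac,
                               "partial", "associated"))
    return states.astype(object)


def make_basepair_series(spec: MeltSeriesSpec) -> MeltSeriesResult:
    """Realise a planted melting schedule as hydrogen-bond distance series.

    Intact bonds are drawn at 2.9 +- 0.1 A and broken bonds at 8 +- 1 A, so
    any cutoff in (3.0, 7.0) recovers the planted states exactly.
    """
    import pandas as pd

    from .bubble import BasePairDefinition

    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    registers = list(spec.registers)

    # stratum label per frame (contiguous blocks sized by frame fraction)
    if spec.strata is None:
        strata_labels = None
        frame_strata = [None] * n
    else:
        labels = list(spec.strata)
        counts = [round(spec.strata[k][0] * n) for k in labels]
        counts[-1] = n - sum(counts[:-1])
        if min(counts) < 0:
            raise SpecError("stratum fractions produce a negative frame count")
        frame_strata = [lab for lab, c in zip(labels, counts) for _ in range(c)]
        strata_labels = [str(s) for s in frame_strata]

    mults = spec._multipliers()
    states = pd.DataFrame(index=range(n), columns=registers, dtype=object)
    for reg in registers:
        m0, p0 = spec.registers[reg]
        for stratum, (mm, pm) in mults.items():
            idx = [f for f in range(n) if frame_strata[f] == stratum]
            if not idx:
                continue
            states.loc[idx, reg] = _allocate_states(
                len(idx), m0 * mm, p0 * pm, spec.mode, rng)

    # geometry: template atoms fixed, partner atom distance encodes the bond
    atom_ids, atom_names, elements = [], [], []
    residue_numbers, residue_names, subunit_ids = [], [], []
    base_positions = []
    pairs = []
    wc = _WC_ATOMS[spec.n_bonds]
    counter = 0
    for ri, reg in enumerate(registers):
        origin = np.array([0.0, 0.0, 20.0 * ri])
        pair_refs = []
        for bi, (t_name, n_name) in enumerate(wc):
            t_pos = origin + np.array([0.0, 3.0 * bi, 0.0])
            for sub, name in (("T", t_name), ("N", n_name)):
                atom_ids.append(counter)
                counter += 1
                atom_names.append(name)
                elements.append(name[0])
                residue_numbers.append(ri + 1)
                residue_names.append("DG" if sub == "T" else "DC")
                subunit_ids.append(sub)
                base_positions.append(t_pos.copy())
            pair_refs.append((("T", ri + 1, t_name), ("N", ri + 1, n_name)))
        pairs.append(BasePairDefinition(register=reg,
                                        atom_pairs=tuple(pair_refs)))

    base_positions = np.asarray(base_positions)
    n_atoms = len(base_positions)
    structure = MolecularStructure(
        atom_ids=np.asarray(atom_ids),
        atom_names=atom_names,
        elements=elements,
        residue_numbers=np.asarray(residue_numbers),
        residue_names=residue_names,
        subunit_ids=subunit_ids,
        coordinates=base_positions,
        vdw_radii=np.full(n_atoms, 1.5),
    )

    frames = np.tile(base_positions[None, :, :], (n, 1, 1))
    for ri, reg in enumerate(registers):
        for f in range(n):
            state = states.at[f, reg]
            if state == "associated":
                broken = np.zeros(spec.n_bonds, dtype=bool)
            elif state == "melted":
                broken = np.ones(spec.n_bonds, dtype=bool)
            else:
                k = int(rng.integers(1, spec.n_bonds))
                broken = np.zeros(spec.n_bonds, dtype=bool)
                broken[rng.choice(spec.n_bonds, size=k, replace=False)] = True
            for bi in range(spec.n_bonds):
                if broken[bi]:
                    d = spec.broken_distance + rng.uniform(-1.0, 1.0)
                else:
                    d = spec.intact_distance + 0.1 * rng.uniform(-1.0, 1.0)
                partner_atom = (ri * spec.n_bonds + bi) * 2 + 1
                template_atom = partner_atom - 1
                frames[f, partner_atom] = (frames[f, template_atom]
                                           + np.array([d, 0.0, 0.0]))

    traj = TrajectoryWindow(
        coordinates=frames,
        frame_times=np.arange(n, dtype=np.float64),
        ligand_atom_groups=[],
        topology=structure,
    )
    return MeltSeriesResult(
        trajectory=traj,
        structure=structure,
        pairs=pairs,
        true_states=states,
        strata=strata_labels,
    )
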