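"""Per-frame ligand region occupancy, binding propensities, transitions.

A ligand occupies a macro-region in a frame iff any of its heavy atoms lies
within a contact cutoff (default 4.0 A) of any heavy atom of the region
selection.  From the resulting timeline the module derives time-average
simultaneous occupant counts per region and per channel, a directed
transition graph over primary regions, and loading/exit events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, SelectionError
from .pathway import PathwayAxis
from .regions import SOLVENT, TERMINAL_REGIONS, RegionGraph
from .structures import MolecularStructure, TrajectoryWindow, resolve_selection

__all__ = [
    "LigandStateTimeline",
    "PropensityTable",
    "TransitionGraph",
    "TransitionEvent",
    "assign_states",
    "binding_propensity",
    "transition_graph",
    "farthest_reach",
    "occupancy_recovery_check",
]

DEFAULT_CONTACT_CUTOFF = 4.0  # A, heavy-atom


@dataclass
class LigandStateTimeline:
    """Per-frame, per-ligand occupied region sets and primary region."""

    occupied: list[list[frozenset]]   # [frame][ligand] -> region names
    primary: list[list[str]]          # [frame][ligand] -> region name or solvent
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if len(self.occupied) != len(self.primary):
            raise ValueError("occupied/primary frame counts disagree")
        for occ, prim in zip(self.occupied, self.primary):
            for regions, p in zip(occ, prim):
                if p != SOLVENT and p not in regions:
                    raise ValueError(f"primary {p!r} not among occupied {set(regions)}")

    @property
    def n_frames(self) -> int:
        return len(self.occupied)

    @property
    def n_ligands(self) -> int:
        return len(self.occupied[0]) if self.occupied else 0

    @classmethod
    def from_primary(cls, sequences: list[list[str]],
                     frame_times: np.ndarray | None = None) -> "LigandStateTimeline":
        """Build a timeline from per-ligand primary-region sequences.

        Occupied sets are the singletons of the primary region; useful for
        authored event-bookkeeping fixtures.
        """
        n_frames = len(sequences[0])
        if any(len(s) != n_frames for s in sequences):
            raise ValueError("all sequences must share the frame count")
        occupied = [[frozenset() if s[f] == SOLVENT else frozenset([s[f]])
                     for s in sequences] for f in range(n_frames)]
        primary = [[s[f] for s in sequences] for f in range(n_frames)]
        if frame_times is None:
            frame_times = np.arange(n_frames, dtype=np.float64)
        return cls(occupied=occupied, primary=primary, frame_times=frame_times)

    def primary_sequence(self, ligand: int) -> list[str]:
        return [self.primary[f][ligand] for f in range(self.n_frames)]


def _resolve_regions(structure: MolecularStructure,
                     graph: RegionGraph,
                     heavy_only: bool = True) -> dict[str, np.ndarray]:
    heavy = structure.heavy_mask()
    resolved: dict[str, np.ndarray] = {}
    for region in graph.regions:
        if region.selection is None:
            raise SelectionError(
                f"region {region.name} has no residue selection")
        idx = resolve_selection(structure, region.selection)
        if heavy_only:
            idx = idx[heavy[idx]]
        if len(idx) == 0:
            raise SelectionError(
                f"region {region.name} resolved to zero (heavy) atoms")
        resolved[region.name] = idx
    return resolved


def assign_states(traj: TrajectoryWindow, graph: RegionGraph,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  structure: MolecularStructure | None = None) -> LigandStateTimeline:
    """Contact-based per-frame region occupancy for every ligand.

    The primary region is the occupied region of greatest depth rank
    (terminus > infiltration > entry > external); rank ties go to the most
    recently entered region, then to name order for determinism.
    """
    structure = structure if structure is not None else traj.topology
    if structure is None:
        raise SelectionError("a topology structure is required to resolve regions")
    region_atoms = _resolve_regions(structure, graph)
    region_names = list(region_atoms)
    heavy = structure.heavy_mask()
    ligand_heavy = [g[heavy[g]] for g in traj.ligand_atom_groups]
    if any(len(g) == 0 for g in ligand_heavy):
        raise SelectionError("a ligand group has no heavy atoms")

    all_region_idx = np.concatenate([region_atoms[n] for n in region_names])
    owner = np.concatenate([
        np.full(len(region_atoms[n]), k, dtype=np.int64)
        for k, n in enumerate(region_names)
    ])

    n_lig = len(ligand_heavy)
    occupied: list[list[frozenset]] = []
    primary: list[list[str]] = []
    entered_at = [dict() for _ in range(n_lig)]  # region -> frame of last entry
    prev_occ = [frozenset() for _ in range(n_lig)]

    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        tree = cKDTree(coords[all_region_idx])
        frame_occ: list[frozenset] = []
        frame_prim: list[str] = []
        for li, lig_idx in enumerate(ligand_heavy):
            hits = tree.query_ball_point(coords[lig_idx], r=cutoff)
            region_ids = {int(owner[j]) for sub in hits for j in sub}
            occ = frozenset(region_names[k] for k in region_ids)
            for name in occ - prev_occ[li]:
                entered_at[li][name] = f
            prev_occ[li] = occ
            if occ:
                prim = max(occ, key=lambda n: (
                    graph.depth_rank(n), entered_at[li].get(n, -1), n))
            else:
                prim = SOLVENT
            frame_occ.append(occ)
            frame_prim.append(prim)
        occupied.append(frame_occ)
        primary.append(frame_prim)

    return LigandStateTimeline(
        occupied=occupied, primary=primary, frame_times=traj.frame_times.copy())


@dataclass
class PropensityTable:
    """Mean/max simultaneous bound-ligand statistics per region and channel."""

    regions: pd.DataFrame    # index region, columns mean_bound / max_bound
    channels: pd.DataFrame   # index channel, columns mean_bound / max_bound


def binding_propensity(timeline: LigandStateTimeline, graph: RegionGraph,
                       dedupe_channels: bool = True) -> PropensityTable:
    """Time-average and maximum simultaneous occupant counts.

    Channel aggregates count distinct ligands per frame when
    ``dedupe_channels`` is true (a ligand touching two member regions counts
    once); otherwise they sum the per-region occupant counts.
    """
    if timeline.n_frames == 0:
        raise ValueError("empty timeline")
    names = graph.names
    n_frames = timeline.n_frames
    counts = np.zeros((n_frames, len(names)), dtype=np.int64)
    name_pos = {n: j for j, n in enumerate(names)}
    for f in range(n_frames):
        for occ in timeline.occupied[f]:
            for region in occ:
                counts[f, name_pos[region]] += 1
    regions = pd.DataFrame({
        "mean_bound": counts.mean(axis=0),
        "max_bound": counts.max(axis=0),
    }, index=pd.Index(names, name="region"))

    rows = {}
    for channel in graph.channels():
        members = set(graph.channel_members(channel))
        if dedupe_channels:
            per_frame = np.array([
                sum(1 for occ in timeline.occupied[f] if occ & members)
                for f in range(n_frames)
            ])
        else:
            member_cols = [name_pos[m] for m in members]
            per_frame = counts[:, member_cols].sum(axis=1)
        rows[channel] = {"mean_bound": per_frame.mean(),
                         "max_bound": per_frame.max()}
    channels = pd.DataFrame.from_dict(rows, orient="index")
    if channels.empty:
        channels = pd.DataFrame(columns=["mean_bound", "max_bound"])
    channels.index.name = "channel"
    return PropensityTable(regions=regions, channels=channels)


@dataclass(frozen=True)
class TransitionEvent:
    ligand: int
    kind: str            # entry | partial_loading | complete_loading | exit
    deepest_region: str
    frame_span: tuple[int, int]


@dataclass
class TransitionGraph:
    """Directed primary-region transition counts plus detected events."""

    edges: dict[tuple[str, str], int]
    events: list[TransitionEvent]
    non_adjacent: list[tuple[str, str]] = field(default_factory=list)

    def out_edge_total(self, sequences_changes: int | None = None) -> int:
        return sum(self.edges.values())


def transition_graph(timeline: LigandStateTimeline,
                     graph: RegionGraph) -> TransitionGraph:
    """Count directed primary-region changes and detect loading/exit events.

    Transitions between regions not adjacent in the graph are counted but
    flagged (cutoff-based occupancy can skip a frame).  Events per excursion
    from solvent: ``entry`` (solvent to a region), ``complete_loading``
    (terminus reached), ``partial_loading`` (infiltration reached but no
    terminus before returning to solvent or the timeline ends), ``exit``
    (return to solvent after visiting an infiltration region).
    """
    edges: dict[tuple[str, str], int] = {}
    events: list[TransitionEvent] = []
    non_adjacent: list[tuple[str, str]] = []

    for li in range(timeline.n_ligands):
        seq = timeline.primary_sequence(li)
        # excursion bookkeeping
        exc_start: int | None = None if seq[0] == SOLVENT else 0
        visited: list[str] = [] if seq[0] == SOLVENT else [seq[0]]
        completed = False

        def _deepest() -> str:
            return max(visited, key=lambda n: (graph.depth_rank(n),
                                               visited.index(n), n))

        def _close_excursion(end_frame: int, returned: bool) -> None:
            nonlocal exc_start, visited, completed
            if exc_start is None:
                return
            reached_infiltration = any(
                graph.depth_rank(n) >= 2 for n in visited)
            if returned and reached_infiltration:
                events.append(TransitionEvent(
                    ligand=li, kind="exit", deepest_region=_deepest(),
                    frame_span=(exc_start, end_frame)))
            if reached_infiltration and not completed:
                events.append(TransitionEvent(
                    ligand=li, kind="partial_loading", deepest_region=_deepest(),
                    frame_span=(exc_start, end_frame)))
            exc_start = None
            visited = []
            completed = False

        for f in range(1, len(seq)):
            a, b = seq[f - 1], seq[f]
            if a == b:
                continue
            edges[(a, b)] = edges.get((a, b), 0) + 1
            if a != SOLVENT and b != SOLVENT and not graph.adjacent(a, b):
                non_adjacent.append((a, b))
                warnings.warn(
                    f"ligand {li}: transition {a} -> {b} between non-adjacent "
                    f"regions at frame {f}", stacklevel=2)
            if a == SOLVENT:
                exc_start = f
                visited = [b]
                completed = False
                events.append(TransitionEvent(
                    ligand=li, kind="entry", deepest_region=b,
                    frame_span=(f, f)))
                continue
            if b == SOLVENT:
                _close_excursion(f, returned=True)
                continue
            if b not in visited:
                visited.append(b)
            if b in TERMINAL_REGIONS and not completed:
                completed = True
                events.append(TransitionEvent(
                    ligand=li, kind="complete_loading", deepest_region=b,
                    frame_span=(exc_start if exc_start is not None else 0, f)))
        _close_excursion(len(seq) - 1, returned=False)

    return TransitionGraph(edges=edges, events=events, non_adjacent=non_adjacent)


def farthest_reach(timeline: LigandStateTimeline, axis: PathwayAxis,
                   traj: TrajectoryWindow, graph: RegionGraph,
                   channel: str) -> dict[int, tuple[int, np.ndarray, float]]:
    """Deepest advance of each ligand along a channel axis.

    Per ligand, over the frames where it occupies a member region of
    ``channel``, the frame minimising the arclength-to-terminus of the
    ligand-centroid projection onto the axis.  Ligands never occupying the
    channel are absent from the result.
    """
    members = set(graph.channel_members(channel))
    structure = traj.topology
    heavy = structure.heavy_mask() if structure is not None else None
    result: dict[int, tuple[int, np.ndarray, float]] = {}
    for li in range(timeline.n_ligands):
        lig_idx = traj.ligand_atom_groups[li]
        if heavy is not None:
            hidx = lig_idx[heavy[lig_idx]]
            if len(hidx):
                lig_idx = hidx
        best: tuple[float, int, np.ndarray] | None = None
        for f in range(timeline.n_frames):
            if not (timeline.occupied[f][li] & members):
                continue
            centroid = traj.coordinates[f][lig_idx].mean(axis=0)
            d = np.linalg.norm(axis.points - centroid, axis=1)
            j = int(np.argmin(d))
            arc = float(axis.arclength_from_end[j])
            if best is None or arc < best[0]:
                best = (arc, f, axis.points[j].copy())
        if best is not None:
            result[li] = (best[1], best[2], best[0])
    return result


def occupancy_recovery_check(model, timeline: LigandStateTimeline,
                             n_batches: int = 32) -> pd.DataFrame:
    """Compare estimated per-region mean occupancy with the jump model's
    stationary expectation.

    ``model`` is a :class:`ntpflow.synthetic.DiffusionModelSpec` (duck-typed:
    needs ``region_names``, ``n_ligands`` and ``stationary_distribution()``).
    Standard errors come from batch means on the per-frame occupant-count
    series, which absorbs the autocorrelation of the jump process.
    """
    pi = model.stationary_distribution()
    regions = list(model.region_names)
    timeline_regions = {r for frame in timeline.occupied for occ in frame for r in occ}
    unknown = timeline_regions - set(regions)
    if unknown:
        raise ConfigError(f"timeline contains regions not in the model: {unknown}")

    n_frames = timeline.n_frames
    n_batches = max(2, min(n_batches, n_frames // 2))
    rows = {}
    for region in regions:
        series = np.array([
            sum(1 for occ in timeline.occupied[f] if region in occ)
            for f in range(n_frames)
        ], dtype=np.float64)
        estimate = series.mean()
        expected = model.n_ligands * pi[region]
        batches = np.array_split(series, n_batches)
        bmeans = np.array([b.mean() for b in batches])
        se = float(bmeans.std(ddof=1) / np.sqrt(n_batches))
        z = (estimate - expected) / se if se > 0 else (
            0.0 if np.isclose(estimate, expected) else np.inf)
        rows[region] = {"estimate": estimate, "expected": expected,
                        "se": se, "z": z}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out
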