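import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntpflow import (
    LigandStateTimeline,
    MacroRegion,
    RegionGraph,
    ResidueSelection,
    TrajectoryWindow,
    assign_states,
    binding_propensity,
    default_region_graph,
    farthest_reach,
    occupancy_recovery_check,
    transition_graph,
)
from ntpflow.errors import ConfigError
from ntpflow.regions import SOLVENT
from ntpflow.structures import MolecularStructure
from ntpflow.synthetic import DiffusionModelSpec, make_diffusion_trajectory


def two_region_spec(**overrides):
    kwargs = dict(
        region_names=["A", "B"],
        anchors={"A": (0.0, 0.0, 0.0), "B": (20.0, 0.0, 0.0)},
        rates={("solvent", "A"): 0.2, ("A", "solvent"): 0.4,
               ("solvent", "B"): 0.2, ("B", "solvent"): 0.4},
        n_ligands=8, n_frames=2000, frame_interval=1.0, seed=11)
    kwargs.update(overrides)
    return DiffusionModelSpec(**kwargs)


def brute_occupancy(traj, structure, graph, cutoff):
    """Independent oracle: all-pairs distance scan, plain loops."""
    from ntpflow.structures import resolve_selection
    heavy = structure.heavy_mask()
    region_idx = {}
    for region in graph.regions:
        idx = resolve_selection(structure, region.selection)
        region_idx[region.name] = [i for i in idx if heavy[i]]
    counts = []
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        frame_counts = {name: 0 for name in region_idx}
        for group in traj.ligand_atom_groups:
            lig = [i for i in group if heavy[i]]
            for name, ridx in region_idx.items():
                touching = False
                for i in lig:
                    for j in ridx:
                        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                            touching = True
                            break
                    if touching:
                        break
                if touching:
                    frame_counts[name] += 1
        counts.append(frame_counts)
    return counts


class TestAssignStates:
    def _toy_structure_and_traj(self, lig_positions):
        """One-atom regions A at origin and B at x=20; ligands are single atoms
        at explicit positions per frame."""
        n_frames = len(lig_positions)
        n_lig = len(lig_positions[0])
        n_atoms = 2 + n_lig
        coords0 = np.zeros((n_atoms, 3))
        coords0[1] = [20.0, 0.0, 0.0]
        structure = MolecularStructure(
            atom_ids=np.arange(n_atoms),
            atom_names=["C"] * 2 + ["P"] * n_lig,
            elements=["C"] * 2 + ["P"] * n_lig,
            residue_numbers=np.array([1, 2] + list(range(101, 101 + n_lig))),
            residue_names=["MRK"] * 2 + ["CTP"] * n_lig,
            subunit_ids=["R"] * 2 + ["L"] * n_lig,
            coordinates=coords0, vdw_radii=np.full(n_atoms, 1.7))
        frames = np.tile(coords0[None], (n_frames, 1, 1))
        for f in range(n_frames):
            for li in range(n_lig):
                frames[f, 2 + li] = lig_positions[f][li]
        traj = TrajectoryWindow(
            coordinates=frames,
            frame_times=np.arange(n_frames, dtype=float),
            ligand_atom_groups=[np.array([2 + li]) for li in range(n_lig)],
            topology=structure)
        graph = RegionGraph(regions=[
            MacroRegion("MR2", "entry",
                        selection=ResidueSelection.from_dict({"R": {1}})),
            MacroRegion("MR3", "entry",
                        selection=ResidueSelection.from_dict({"R": {2}})),
        ], adjacency={frozenset(("MR2", "MR3"))})
        return structure, traj, graph

    def test_below_cutoff_occupied(self):
        _, traj, graph = self._toy_structure_and_traj([[(3.0, 0.0, 0.0)]])
        tl = assign_states(traj, graph, cutoff=4.0)
        assert tl.occupied[0][0] == frozenset({"MR2"})
        assert tl.primary[0][0] == "MR2"

    def test_above_cutoff_solvent(self):
        _, traj, graph = self._toy_structure_and_traj([[(10.0, 10.0, 10.0)]])
        tl = assign_states(traj, graph, cutoff=4.0)
        assert tl.occupied[0][0] == frozenset()
        assert tl.primary[0][0] == SOLVENT

    def test_equidistant_primary_is_most_recent(self):
        # regions 6 A apart: frame 0 touches only MR2, frame 1 touches both;
        # MR3 entered more recently, so it becomes the primary region
        structure, traj, graph = self._toy_structure_and_traj(
            [[(0.5, 0.0, 0.0)], [(3.0, 0.0, 0.0)]])
        structure.coordinates[1] = [6.0, 0.0, 0.0]
        traj.coordinates[:, 1] = [6.0, 0.0, 0.0]
        tl = assign_states(traj, graph, structure=structure, cutoff=4.0)
        assert tl.occupied[0][0] == frozenset({"MR2"})
        assert tl.occupied[1][0] == frozenset({"MR2", "MR3"})
        assert tl.primary[1][0] == "MR3"  # entered more recently

    def test_infiltration_outranks_entry(self):
        structure, traj, _ = self._toy_structure_and_traj([[(10.0, 0.0, 0.0)]])
        structure.coordinates[1] = [13.0, 0.0, 0.0]
        traj.coordinates[:, 1] = [13.0, 0.0, 0.0]
        graph = RegionGraph(regions=[
            MacroRegion("MR2", "entry",
                        selection=ResidueSelection.from_dict({"R": {1}})),
            MacroRegion("MR17", "infiltration",
                        selection=ResidueSelection.from_dict({"R": {2}})),
        ], adjacency={frozenset(("MR2", "MR17"))})
        tl = assign_states(traj, graph, structure=structure, cutoff=11.0)
        assert tl.occupied[0][0] == frozenset({"MR2", "MR17"})
        assert tl.primary[0][0] == "MR17"

    def test_conservation_against_brute_force(self):
        spec = two_region_spec(n_ligands=20, n_frames=40)
        result = make_diffusion_trajectory(spec)
        tl = assign_states(result.trajectory, result.graph, cutoff=4.0)
        oracle = brute_occupancy(result.trajectory, result.structure,
                                 result.graph, cutoff=4.0)
        for f in range(result.trajectory.n_frames):
            for name in ("A", "B"):
                got = sum(1 for occ in tl.occupied[f] if name in occ)
                assert got == oracle[f][name]


class TestBindingPropensity:
    def test_hand_counted_toy(self):
        # ligand A in MR2 frames 0-2, ligand B in MR2 frame 2 only
        seq_a = ["MR2", "MR2", "MR2", SOLVENT]
        seq_b = [SOLVENT, SOLVENT, "MR2", SOLVENT]
        tl = LigandStateTimeline.from_primary([seq_a, seq_b])
        graph = RegionGraph(regions=[MacroRegion("MR2", "entry")])
        table = binding_propensity(tl, graph)
        assert table.regions.loc["MR2", "mean_bound"] == pytest.approx(1.0)
        assert table.regions.loc["MR2", "max_bound"] == 2

    def test_no_occupancy_all_zero(self):
        tl = LigandStateTimeline.from_primary([[SOLVENT] * 5, [SOLVENT] * 5])
        graph = RegionGraph(regions=[MacroRegion("MR2", "entry")])
        table = binding_propensity(tl, graph)
        assert (table.regions["mean_bound"] == 0).all()
        assert (table.regions["max_bound"] == 0).all()

    def test_ch2_aggregate_from_published_membership(self):
        # MR1 holds 2 ligands, MR2 one, every frame -> CH2 aggregate mean 3.0
        graph = default_region_graph()
        sequences = [["MR1"] * 4, ["MR1"] * 4, ["MR2"] * 4]
        tl = LigandStateTimeline.from_primary(sequences)
        table = binding_propensity(tl, graph)
        assert table.channels.loc["CH2", "mean_bound"] == pytest.approx(3.0)
        assert table.channels.loc["CH2", "max_bound"] == 3

    def test_channel_dedupe_counts_molecules_once(self):
        graph = default_region_graph()
        # one ligand touching MR2 and MR3 simultaneously
        occupied = [[frozenset({"MR2", "MR3"})]]
        tl = LigandStateTimeline(occupied=occupied, primary=[["MR3"]],
                                 frame_times=np.array([0.0]))
        deduped = binding_propensity(tl, graph, dedupe_channels=True)
        summed = binding_propensity(tl, graph, dedupe_channels=False)
        assert deduped.channels.loc["CH2", "mean_bound"] == 1.0
        assert summed.channels.loc["CH2", "mean_bound"] == 2.0

    def test_propensity_bounds(self):
        spec = two_region_spec(n_frames=500)
        result = make_diffusion_trajectory(spec)
        graph = result.graph
        table = binding_propensity(result.timeline, graph)
        assert (table.regions["mean_bound"] <= table.regions["max_bound"]).all()
        assert (table.channels["max_bound"] <= spec.n_ligands).all()


class TestTransitionGraph:
    def test_complete_loading_sequence(self):
        g = default_region_graph()
        tl = LigandStateTimeline.from_primary(
            [[SOLVENT, "MR8", "MR17", "MR19"]])
        tg = transition_graph(tl, g)
        assert tg.edges == {(SOLVENT, "MR8"): 1, ("MR8", "MR17"): 1,
                            ("MR17", "MR19"): 1}
        kinds = [e.kind for e in tg.events]
        assert kinds.count("complete_loading") == 1
        assert kinds.count("partial_loading") == 0
        assert kinds.count("exit") == 0
        complete = next(e for e in tg.events if e.kind == "complete_loading")
        assert complete.deepest_region == "MR19"

    def test_constant_timeline_no_edges(self):
        g = default_region_graph()
        tl = LigandStateTimeline.from_primary([["MR2"] * 6])
        tg = transition_graph(tl, g)
        assert tg.edges == {}
        assert tg.events == []

    def test_partial_loading_and_exit(self):
        g = default_region_graph()
        tl = LigandStateTimeline.from_primary(
            [["MR8", "MR17", "MR8", SOLVENT]])
        tg = transition_graph(tl, g)
        kinds = sorted(e.kind for e in tg.events)
        assert kinds == ["exit", "partial_loading"]
        partial = next(e for e in tg.events if e.kind == "partial_loading")
        assert partial.deepest_region == "MR17"

    def test_non_adjacent_transition_flagged_not_dropped(self):
        g = default_region_graph()
        tl = LigandStateTimeline.from_primary([["MR2", "MR19"]])
        with pytest.warns(UserWarning, match="non-adjacent"):
            tg = transition_graph(tl, g)
        assert tg.edges == {("MR2", "MR19"): 1}
        assert ("MR2", "MR19") in tg.non_adjacent

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_edge_conservation_property(self, seed):
        g = default_region_graph()
        rng = np.random.default_rng(seed)
        states = [SOLVENT] + g.names
        seq = [states[i] for i in rng.integers(0, len(states), size=30)]
        tl = LigandStateTimeline.from_primary([seq])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tg = transition_graph(tl, g)
        changes = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
        assert sum(tg.edges.values()) == changes


class TestFarthestReach:
    def _setup(self):
        from ntpflow import PathwaySpec, find_path
        from ntpflow.synthetic import (
            ChannelPhantomSpec, StraightCenterline, make_channel_phantom)
        phantom = make_channel_phantom(ChannelPhantomSpec(
            centerline=StraightCenterline(30.0), wall_radius=4.0,
            atom_radius=1.5))
        axis = find_path(phantom.structure, PathwaySpec(
            start_point=[0, 0, 0.0], target_point=[0, 0, 30.0],
            step_length=1.0, search_radius=2.0, max_points=100))
        return phantom, axis

    def _traj_for_zs(self, phantom, zs):
        base = phantom.structure
        n = base.n_atoms
        coords0 = np.vstack([base.coordinates, [[0.0, 0.0, 0.0]]])
        structure = MolecularStructure(
            atom_ids=np.arange(n + 1),
            atom_names=base.atom_names + ["P"],
            elements=base.elements + ["P"],
            residue_numbers=np.concatenate([base.residue_numbers, [999]]),
            residue_names=base.residue_names + ["CTP"],
            subunit_ids=base.subunit_ids + ["L"],
            coordinates=coords0, vdw_radii=np.append(base.vdw_radii, 1.7))
        frames = np.tile(coords0[None], (len(zs), 1, 1))
        for f, z in enumerate(zs):
            frames[f, n] = [0.0, 0.0, z]
        return structure, TrajectoryWindow(
            coordinates=frames, frame_times=np.arange(len(zs), dtype=float),
            ligand_atom_groups=[np.array([n])], topology=structure)

    def _graph(self):
        return RegionGraph(regions=[MacroRegion(
            "MR8", "entry", channel_memberships=frozenset({"CH3C"}))])

    def _timeline(self, occupied_flags):
        occ = [[frozenset({"MR8"}) if o else frozenset()]
               for o in occupied_flags]
        prim = [["MR8" if o else SOLVENT] for o in occupied_flags]
        return LigandStateTimeline(occupied=occ, primary=prim,
                                   frame_times=np.arange(len(occ), dtype=float))

    def test_monotone_advance_last_frame(self):
        phantom, axis = self._setup()
        _, traj = self._traj_for_zs(phantom, [5.0, 10.0, 15.0])
        tl = self._timeline([True, True, True])
        out = farthest_reach(tl, axis, traj, self._graph(), "CH3C")
        assert out[0][0] == 2  # deepest at the last frame

    def test_advance_then_retreat_apex(self):
        phantom, axis = self._setup()
        _, traj = self._traj_for_zs(phantom, [5.0, 20.0, 10.0])
        tl = self._timeline([True, True, True])
        out = farthest_reach(tl, axis, traj, self._graph(), "CH3C")
        assert out[0][0] == 1  # apex frame, not the last

    def test_never_in_channel_absent(self):
        phantom, axis = self._setup()
        _, traj = self._traj_for_zs(phantom, [5.0, 10.0])
        tl = self._timeline([False, False])
        out = farthest_reach(tl, axis, traj, self._graph(), "CH3C")
        assert out == {}


class TestOccupancyRecovery:
    def test_two_region_within_three_se(self):
        spec = two_region_spec(n_frames=4000)
        result = make_diffusion_trajectory(spec)
        tl = assign_states(result.trajectory, result.graph, cutoff=4.0)
        report = occupancy_recovery_check(spec, tl)
        assert report.loc["A", "expected"] == pytest.approx(2.0)
        assert abs(report.loc["A", "z"]) <= 3.0
        assert abs(report.loc["B", "z"]) <= 3.0

    def test_symmetric_rates_equal_means(self):
        spec = two_region_spec(n_frames=4000)
        pi = spec.stationary_distribution()
        assert pi["A"] == pytest.approx(pi["B"])

    def test_zero_rates_all_zero(self):
        spec = two_region_spec(
            rates={("solvent", "A"): 0.0, ("A", "solvent"): 0.0,
                   ("solvent", "B"): 0.0, ("B", "solvent"): 0.0},
            n_frames=50)
        result = make_diffusion_trajectory(spec)
        report = occupancy_recovery_check(spec, result.timeline)
        assert (report["estimate"] == 0.0).all()
        assert (report["expected"] == 0.0).all()

    def test_region_mismatch_raises(self):
        spec = two_region_spec(n_frames=10)
        tl = LigandStateTimeline.from_primary([["C"] * 10])
        with pytest.raises(ConfigError):
            occupancy_recovery_check(spec, tl)

    def test_coverage_at_three_frame_counts(self):
        for n_frames in (500, 2000, 8000):
            spec = two_region_spec(n_frames=n_frames, seed=23)
            result = make_diffusion_trajectory(spec)
            report = occupancy_recovery_check(spec, result.timeline)
            assert (report["z"].abs() <= 3.0).all(), n_frames
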