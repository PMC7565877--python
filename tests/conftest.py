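import numpy as np
import pytest

from ntpflow import (
    ChannelPhantomSpec,
    PathwaySpec,
    StraightCenterline,
    TrajectoryWindow,
    find_path,
    make_channel_phantom,
)
from ntpflow.synthetic import BentCenterline, gaussian_constriction

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500  -1.250   0.750  1.00  0.00           C
ATOM      3  O   HOH A   2      -3.125   4.000   9.875  1.00  0.00           O
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


def _multimodel_pdb_text(n_models=5, shift=1.0):
    """Three CTP ligand residues plus one protein atom, coordinates
    translating by `shift` A in x per model."""
    lines = []
    for m in range(n_models):
        lines.append(f"MODEL     {m + 1:>4d}")
        serial = 1
        dx = m * shift
        # one protein atom
        lines.append(
            f"ATOM  {serial:>5d}  CA  ALA A   1    "
            f"{0.0 + dx:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        serial += 1
        for li in range(3):
            for ai, name in enumerate(("PA", "O1A")):
                x = 10.0 * (li + 1) + dx
                elem = name[0]
                lines.append(
                    f"HETATM{serial:>5d}  {name:<3s} CTP B{100 + li:>4d}    "
                    f"{x:8.3f}{float(ai):8.3f}{0.0:8.3f}  1.00  0.00"
                    f"           {elem}")
                serial += 1
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


@pytest.fixture
def multimodel_pdb(tmp_path):
    p = tmp_path / "traj.pdb"
    p.write_text(_multimodel_pdb_text())
    return p


@pytest.fixture(scope="session")
def straight_phantom():
    """Open cylinder along z: length 30, wall 4.0, atoms 1.5 -> clearance 2.5."""
    spec = ChannelPhantomSpec(
        centerline=StraightCenterline(30.0), wall_radius=4.0,
        atom_radius=1.5, atoms_per_ring=24, ring_spacing=1.0, seed=0)
    return make_channel_phantom(spec)


@pytest.fixture(scope="session")
def bent_phantom():
    """90-degree bent tube, legs 12 A, bend radius 6 A."""
    spec = ChannelPhantomSpec(
        centerline=BentCenterline(leg=12.0, bend_radius=6.0), wall_radius=4.0,
        atom_radius=1.5, atoms_per_ring=24, ring_spacing=1.0, seed=0)
    return make_channel_phantom(spec)


@pytest.fixture(scope="session")
def constricted_phantom():
    """Cylinder with a Gaussian constriction to 1.0 A clearance at s = 15."""
    wall = gaussian_constriction(base_radius=4.0, min_radius=2.5,
                                 center=15.0, width=1.5)
    spec = ChannelPhantomSpec(
        centerline=StraightCenterline(30.0), wall_radius=wall,
        atom_radius=1.5, atoms_per_ring=24, ring_spacing=1.0, seed=0)
    return make_channel_phantom(spec)


@pytest.fixture(scope="session")
def straight_axis(straight_phantom):
    spec = PathwaySpec(start_point=[0.0, 0.0, 0.0],
                       target_point=[0.0, 0.0, 30.0],
                       step_length=1.0, search_radius=2.0, max_points=100)
    return find_path(straight_phantom.structure, spec, seed=0)


def single_frame_window(structure):
    return TrajectoryWindow(
        coordinates=structure.coordinates[None, :, :],
        frame_times=np.array([0.0]),
        ligand_atom_groups=[],
        topology=structure,
    )
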