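"""Structure and trajectory input, vdW radius assignment, residue selections.

Reading goes through MDAnalysis so that PDB (single- and multi-model), DCD
and XTC inputs are handled by standard readers.  The in-memory model is a
plain array-of-columns :class:`MolecularStructure`, which is what the
geometry code (clearance scans, contact detection) operates on.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyStructureError, InputError, SelectionError, TopologyError
from .radii import BONDI, DEFAULT_RADIUS, lookup_radius

__all__ = [
    "MolecularStructure",
    "TrajectoryWindow",
    "ResidueSelection",
    "read_structure",
    "load_trajectory",
    "resolve_selection",
    "write_pdb",
]

# Two-letter element symbols that occur in biomolecular PDB files and can be
# confused with a one-letter symbol plus remoteness indicator.
_TWO_LETTER = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "CU", "SE", "NI", "CD",
    "HG", "PB", "PT", "AU", "AG", "SI", "AL", "LI", "RB", "CS", "SR", "BA",
}


def _guess_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB atom name.

    Digits and whitespace are stripped; names matching a known two-letter
    symbol are taken whole, otherwise the first letter wins (so ``CA`` in a
    protein residue is read as carbon only when the caller supplies real
    element columns — this fallback treats bare ``CA`` as calcium, which is
    why files without element columns should be avoided for proteins).
    """
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        return "X"
    if stripped[:2] in _TWO_LETTER and len(stripped) <= 2:
        return stripped[:2]
    return stripped[0]


@dataclass
class MolecularStructure:
    """Atoms with coordinates, residue/subunit identity and vdW radii."""

    atom_ids: np.ndarray            # (N,) int
    atom_names: list[str]
    elements: list[str]
    residue_numbers: np.ndarray     # (N,) int, author numbering kept verbatim
    residue_names: list[str]
    subunit_ids: list[str]
    coordinates: np.ndarray         # (N, 3) float64, Angstrom
    vdw_radii: np.ndarray           # (N,) float64, Angstrom
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.int64)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        n = len(self.coordinates)
        if not (len(self.atom_ids) == len(self.atom_names) == len(self.elements)
                == len(self.residue_numbers) == len(self.residue_names)
                == len(self.subunit_ids) == len(self.vdw_radii) == n):
            raise ValueError("field lengths disagree")
        if n and not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if n and not np.all(self.vdw_radii > 0):
            raise ValueError("vdw radii must be positive")
        if n and len(np.unique(self.atom_ids)) != n:
            raise ValueError("atom ids must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def subset(self, indices: np.ndarray) -> "MolecularStructure":
        idx = np.asarray(indices, dtype=np.int64)
        return MolecularStructure(
            atom_ids=self.atom_ids[idx],
            atom_names=[self.atom_names[i] for i in idx],
            elements=[self.elements[i] for i in idx],
            residue_numbers=self.residue_numbers[idx],
            residue_names=[self.residue_names[i] for i in idx],
            subunit_ids=[self.subunit_ids[i] for i in idx],
            coordinates=self.coordinates[idx],
            vdw_radii=self.vdw_radii[idx],
        )


@dataclass
class TrajectoryWindow:
    """Ordered coordinate frames congruent with a :class:`MolecularStructure`."""

    coordinates: np.ndarray         # (F, N, 3) float64
    frame_times: np.ndarray         # (F,) ns, strictly increasing
    ligand_atom_groups: list[np.ndarray] = field(default_factory=list)
    topology: MolecularStructure | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, N, 3)")
        if len(self.frame_times) != len(self.coordinates):
            raise ValueError("frame_times length must equal frame count")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        groups = [np.asarray(g, dtype=np.int64) for g in self.ligand_atom_groups]
        seen: set[int] = set()
        for g in groups:
            gs = set(g.tolist())
            if gs & seen:
                raise ValueError("ligand atom groups must be disjoint")
            seen |= gs
        self.ligand_atom_groups = groups

    @property
    def n_frames(self) -> int:
        return len(self.coordinates)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_atom_groups)


@dataclass(frozen=True)
class ResidueSelection:
    """Residue ranges per subunit, e.g. the RPB1 1100-1110 convention."""

    entries: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        for subunit, residues in self.entries:
            if not residues:
                raise ValueError(f"empty residue set for subunit {subunit!r}")

    @classmethod
    def from_dict(cls, mapping: dict[str, Iterable[int]]) -> "ResidueSelection":
        return cls(tuple(
            (str(sub), frozenset(int(r) for r in residues))
            for sub, residues in mapping.items()
        ))

    def union(self, other: "ResidueSelection") -> "ResidueSelection":
        merged: dict[str, set[int]] = {}
        for sub, residues in self.entries + other.entries:
            merged.setdefault(sub, set()).update(residues)
        return ResidueSelection.from_dict(merged)

    def pairs(self) -> set[tuple[str, int]]:
        return {(sub, r) for sub, residues in self.entries for r in residues}


def _subunit_labels(universe) -> list[str]:
    """Prefer segid over chainID so multi-character subunit names survive."""
    atoms = universe.atoms
    segids = getattr(atoms, "segids", None)
    chains = getattr(atoms, "chainIDs", None)
    labels = []
    for i in range(len(atoms)):
        seg = str(segids[i]).strip() if segids is not None else ""
        if seg in ("", "SYSTEM"):
            seg = str(chains[i]).strip() if chains is not None else ""
        labels.append(seg or "A")
    return labels


def read_structure(path: str | os.PathLike,
                   radius_table: dict[str, float] | None = None,
                   default_radius: float = DEFAULT_RADIUS) -> MolecularStructure:
    """Read a PDB-dialect file into a :class:`MolecularStructure`.

    Radii come from ``radius_table`` (default: Bondi by element); unknown
    elements receive ``default_radius`` and trigger a warning.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001
        # MDAnalysis raises a mix of ValueError/IndexError/EOFError on
        # degenerate files; fold them into the package's input errors.
        raise EmptyStructureError(f"could not parse any atoms from {path}: {exc}") from exc
    n = len(universe.atoms)
    if n == 0:
        raise EmptyStructureError(f"no atoms parsed from {path}")

    names = [str(a) for a in universe.atoms.names]
    if hasattr(universe.atoms, "elements"):
        elements = [str(e).strip() or _guess_element(names[i])
                    for i, e in enumerate(universe.atoms.elements)]
    else:
        elements = [_guess_element(nm) for nm in names]

    radii = np.empty(n, dtype=np.float64)
    unknown: set[str] = set()
    for i, elem in enumerate(elements):
        r = lookup_radius(elem, radius_table)
        if r is None:
            unknown.add(elem)
            r = default_radius
        radii[i] = r
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)} assigned default radius "
            f"{default_radius} A", stacklevel=2)

    return MolecularStructure(
        atom_ids=np.arange(n, dtype=np.int64),
        atom_names=names,
        elements=elements,
        residue_numbers=np.asarray(universe.atoms.resids, dtype=np.int64),
        residue_names=[str(r) for r in universe.atoms.resnames],
        subunit_ids=_subunit_labels(universe),
        coordinates=np.asarray(universe.atoms.positions, dtype=np.float64),
        vdw_radii=radii,
        source_path=str(path),
    )


def _ligand_groups(structure: MolecularStructure,
                   ligand_spec: "ResidueSelection | str") -> list[np.ndarray]:
    """One atom-index group per matched residue instance, in structure order."""
    groups: dict[tuple[str, int], list[int]] = {}
    if isinstance(ligand_spec, str):
        resname = ligand_spec.strip().upper()
        for i in range(structure.n_atoms):
            if structure.residue_names[i].strip().upper() == resname:
                key = (structure.subunit_ids[i], int(structure.residue_numbers[i]))
                groups.setdefault(key, []).append(i)
    else:
        wanted = ligand_spec.pairs()
        for i in range(structure.n_atoms):
            key = (structure.subunit_ids[i], int(structure.residue_numbers[i]))
            if key in wanted:
                groups.setdefault(key, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: min(kv[1]))
    return [np.asarray(idx, dtype=np.int64) for _, idx in ordered]


def load_trajectory(paths: Sequence[str | os.PathLike] | str | os.PathLike,
                    topology: MolecularStructure,
                    ligand_spec: "ResidueSelection | str" = "CTP") -> TrajectoryWindow:
    """Load trajectory frames congruent with ``topology``.

    ``paths`` may be a multi-model PDB or DCD/XTC files (the latter require
    ``topology.source_path`` to point at a readable topology file).  Frames
    are returned in file order with strictly increasing times (ns); times
    fall back to the frame index when the reader provides none.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    paths = [str(p) for p in paths]

    frames: list[np.ndarray] = []
    times: list[float] = []
    for p in paths:
        if not Path(p).exists():
            raise InputError(f"no such file: {p}")
        suffix = Path(p).suffix.lower()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if suffix in (".dcd", ".xtc", ".trr"):
                if topology.source_path is None:
                    raise TopologyError(
                        "binary trajectories need a topology with a source_path")
                universe = mda.Universe(topology.source_path, p)
            else:
                universe = mda.Universe(p)
        if len(universe.atoms) != topology.n_atoms:
            raise TopologyError(
                f"{p}: {len(universe.atoms)} atoms, topology has {topology.n_atoms}")
        for ts in universe.trajectory:
            frames.append(np.asarray(ts.positions, dtype=np.float64).copy())
            times.append(float(getattr(ts, "time", 0.0)) / 1000.0)  # ps -> ns

    if not frames:
        raise InputError("no frames read")
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=np.float64)

    groups = _ligand_groups(topology, ligand_spec)
    if not groups:
        raise SelectionError(f"ligand selection {ligand_spec!r} matched no residues")

    return TrajectoryWindow(
        coordinates=np.stack(frames),
        frame_times=times_arr,
        ligand_atom_groups=groups,
        topology=topology,
    )


def resolve_selection(structure: MolecularStructure,
                      sel: ResidueSelection) -> np.ndarray:
    """Resolve a residue selection to sorted atom indices.

    An empty result is allowed but flagged with a warning so that typos in
    region definitions surface early.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("cannot resolve a selection on an empty structure")
    wanted = sel.pairs()
    idx = [i for i in range(structure.n_atoms)
           if (structure.subunit_ids[i], int(structure.residue_numbers[i])) in wanted]
    if not idx:
        warnings.warn(f"selection {sel.entries!r} matched no atoms", stacklevel=2)
    return np.asarray(sorted(idx), dtype=np.int64)


def _format_pdb_line(serial: int, name: str, resname: str, chain: str,
                     resid: int, xyz: np.ndarray, element: str, segid: str) -> str:
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {name_f:<4.4s} {resname:<4.4s}{chain:1.1s}"
        f"{resid:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}      {segid:<4.4s}{element:>2.2s}\n"
    )


def write_pdb(structure: MolecularStructure, path: str | os.PathLike,
              trajectory: TrajectoryWindow | None = None) -> None:
    """Write a structure (optionally with trajectory frames as MODELs) to PDB.

    Coordinates are rounded to the format's 3 decimal places; subunit ids are
    stored in the segid column (chain gets the first character).
    """
    path = Path(path)
    frames = (trajectory.coordinates if trajectory is not None
              else structure.coordinates[None, :, :])
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            for i in range(structure.n_atoms):
                sub = structure.subunit_ids[i]
                fh.write(_format_pdb_line(
                    serial=int(structure.atom_ids[i]) % 100000,
                    name=structure.atom_names[i],
                    resname=structure.residue_names[i],
                    chain=sub[:1] if sub else "A",
                    resid=int(structure.residue_numbers[i]) % 10000,
                    xyz=coords[i],
                    element=structure.elements[i],
                    segid=sub,
                ))
            fh.write("ENDMDL\n" if multi else "END\n")
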