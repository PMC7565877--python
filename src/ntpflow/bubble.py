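"""Base-pair association-state classification and melting quantitation.

A Watson-Crick pair is classified per frame from its donor-acceptor
heavy-atom distances: ``associated`` when every hydrogen bond is intact
(distance <= cutoff, default 3.5 A, no angle term), ``melted`` when none
is, ``partial`` otherwise.  Time fractions can be stratified by an external
per-frame label (typically a ligand state from :mod:`ntpflow.states`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TopologyError
from .regions import MacroRegion
from .structures import MolecularStructure, ResidueSelection, TrajectoryWindow, resolve_selection

__all__ = [
    "BasePairDefinition",
    "BasePairStateSeries",
    "classify_pair",
    "classify_series",
    "melting_fractions",
    "base_flip_occupancy",
    "DEFAULT_BOND_CUTOFF",
]

DEFAULT_BOND_CUTOFF = 3.5  # A, donor-acceptor heavy atoms

STATES = ("associated", "partial", "melted")

AtomRef = tuple[str, int, str]  # (subunit, residue number, atom name)


@dataclass(frozen=True)
class BasePairDefinition:
    """A register label plus its Watson-Crick donor-acceptor atom pairs."""

    register: str                                  # e.g. "i+3"
    atom_pairs: tuple[tuple[AtomRef, AtomRef], ...]  # (template, non-template)

    def __post_init__(self) -> None:
        if len(self.atom_pairs) not in (2, 3):
            raise ValueError("a Watson-Crick pair has 2 (A.T) or 3 (G.C) bonds")

    @property
    def n_bonds(self) -> int:
        return len(self.atom_pairs)

    def resolve(self, structure: MolecularStructure) -> np.ndarray:
        """(n_bonds, 2) atom indices; raises TopologyError on missing atoms."""
        lut = {
            (structure.subunit_ids[i], int(structure.residue_numbers[i]),
             structure.atom_names[i].strip()): i
            for i in range(structure.n_atoms)
        }
        idx = np.empty((self.n_bonds, 2), dtype=np.int64)
        for b, (t_ref, n_ref) in enumerate(self.atom_pairs):
            for col, ref in enumerate((t_ref, n_ref)):
                key = (ref[0], int(ref[1]), ref[2])
                if key not in lut:
                    raise TopologyError(
                        f"register {self.register}: atom {key} not in structure")
                idx[b, col] = lut[key]
        return idx


@dataclass
class BasePairStateSeries:
    """Per-frame tri-state classification per register, plus optional strata."""

    states: pd.DataFrame            # frames x registers, values in STATES
    strata: list[str] | None = None  # per-frame stratum label

    def __post_init__(self) -> None:
        if self.strata is not None and len(self.strata) != len(self.states):
            raise ValueError("strata length must equal frame count")

    @property
    def registers(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_frames(self) -> int:
        return len(self.states)


def classify_pair(frame_coords: np.ndarray, bond_indices: np.ndarray,
                  bond_cutoff: float = DEFAULT_BOND_CUTOFF) -> str:
    """Classify one pair in one frame from resolved bond atom indices."""
    a = frame_coords[bond_indices[:, 0]]
    b = frame_coords[bond_indices[:, 1]]
    intact = np.linalg.norm(a - b, axis=1) <= bond_cutoff
    if intact.all():
        return "associated"
    if not intact.any():
        return "melted"
    return "partial"


def classify_series(traj: TrajectoryWindow,
                    pairs: Sequence[BasePairDefinition],
                    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
                    structure: MolecularStructure | None = None,
                    strata: Sequence[str] | None = None) -> BasePairStateSeries:
    """Classify every register in every frame of a trajectory."""
    structure = structure if structure is not None else traj.topology
    if structure is None:
        raise TopologyError("a topology structure is required")
    resolved = {p.register: p.resolve(structure) for p in pairs}
    data = {
        reg: [classify_pair(traj.coordinates[f], idx, bond_cutoff)
              for f in range(traj.n_frames)]
        for reg, idx in resolved.items()
    }
    return BasePairStateSeries(
        states=pd.DataFrame(data),
        strata=list(strata) if strata is not None else None,
    )


def melting_fractions(series: BasePairStateSeries) -> pd.DataFrame:
    """Time fractions per register (and stratum, when labels are present).

    Columns: associated / partial / melted fractions plus their cumulative
    partial+melted sum.  Strata with zero frames are absent from the result
    rather than reported as zero.
    """
    if series.n_frames == 0:
        raise ValueError("empty series")
    frames = series.states
    groups: list[tuple[str | None, pd.DataFrame]]
    if series.strata is None:
        groups = [(None, frames)]
    else:
        labels = pd.Series(series.strata, index=frames.index)
        groups = [(str(s), frames.loc[labels == s]) for s in
                  sorted(set(series.strata))]

    rows = []
    for stratum, block in groups:
        if len(block) == 0:
            continue  # empty stratum: fraction undefined, absent not zero
        for reg in frames.columns:
            vc = block[reg].value_counts()
            n = len(block)
            frac = {s: vc.get(s, 0) / n for s in STATES}
            rows.append({
                "register": reg,
                "stratum": stratum if stratum is not None else "all",
                "associated": frac["associated"],
                "partial": frac["partial"],
                "melted": frac["melted"],
                "partial_plus_melted": frac["partial"] + frac["melted"],
                "n_frames": n,
            })
    return pd.DataFrame(rows).set_index(["register", "stratum"])


@dataclass
class FlipOccupancy:
    in_pocket: np.ndarray    # (F,) bool
    in_fraction: float
    dwell_lengths: list[int]  # consecutive in-pocket run lengths, frames


def base_flip_occupancy(traj: TrajectoryWindow,
                        base_selection: ResidueSelection,
                        pocket: "MacroRegion | ResidueSelection",
                        cutoff: float = 4.0,
                        structure: MolecularStructure | None = None) -> FlipOccupancy:
    """Frame-wise pocket occupancy of a flipping base.

    A frame counts as "in" iff any heavy atom of the base lies within
    ``cutoff`` of any heavy atom of the pocket selection.
    """
    structure = structure if structure is not None else traj.topology
    if structure is None:
        raise TopologyError("a topology structure is required")
    pocket_sel = pocket.selection if isinstance(pocket, MacroRegion) else pocket
    heavy = structure.heavy_mask()
    base_idx = resolve_selection(structure, base_selection)
    base_idx = base_idx[heavy[base_idx]]
    pocket_idx = resolve_selection(structure, pocket_sel)
    pocket_idx = pocket_idx[heavy[pocket_idx]]

    flags = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        d = np.linalg.norm(
            coords[base_idx][:, None, :] - coords[pocket_idx][None, :, :], axis=2)
        flags[f] = bool((d <= cutoff).any())

    dwells: list[int] = []
    run = 0
    for flag in flags:
        if flag:
            run += 1
        elif run:
            dwells.append(run)
            run = 0
    if run:
        dwells.append(run)
    return FlipOccupancy(
        in_pocket=flags,
        in_fraction=float(flags.mean()) if len(flags) else 0.0,
        dwell_lengths=dwells,
    )
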