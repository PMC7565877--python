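"""Channel pathway exploration and minimal-radius profiling.

The central primitive is the signed clearance of a probe point: the minimal
distance from the point to any atom *surface* (centre distance minus vdW
radius).  A pathway is grown iteratively from a start point towards a buried
target, each step moving to the candidate of maximal clearance among a
deterministic fan of forward directions, refined within the disc orthogonal
to the step.  The per-frame width of the channel is then reported as the
minimal re-optimised clearance in 1-Angstrom arclength bins measured from
the pathway end, with the first few Angstrom of the entry side trimmed to
discount initial convergence (default 6 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .structures import MolecularStructure, TrajectoryWindow

__all__ = [
    "PathwaySpec",
    "PathwayAxis",
    "RadiusProfile",
    "clearance",
    "clearance_many",
    "find_path",
    "min_radius_profile",
    "constriction_report",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class PathwaySpec:
    """Geometry and budget for a pathway search."""

    start_point: np.ndarray     # (3,) A, at/outside the channel mouth
    target_point: np.ndarray    # (3,) A, buried terminus
    step_length: float = 1.0    # A
    search_radius: float = 2.0  # A, refinement disc radius
    max_points: int = 200
    n_directions: int = 64

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_point",
                           np.asarray(self.start_point, dtype=np.float64))
        object.__setattr__(self, "target_point",
                           np.asarray(self.target_point, dtype=np.float64))
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.search_radius < self.step_length:
            raise ValueError("search_radius must be >= step_length")
        if self.max_points < 2:
            raise ValueError("max_points must be >= 2")


@dataclass
class PathwayAxis:
    """Ordered maximal-clearance points with per-point signed clearance."""

    points: np.ndarray              # (M, 3)
    clearances: np.ndarray          # (M,) signed, A
    arclength_from_end: np.ndarray  # (M,) A, decreasing toward the terminus
    reached_target: bool
    blocked: bool
    spec: PathwaySpec

    @property
    def total_arclength(self) -> float:
        return float(self.arclength_from_end[0])

    def tangents(self) -> np.ndarray:
        """Unit tangents per point (central differences)."""
        pts = self.points
        t = np.empty_like(pts)
        t[0] = pts[1] - pts[0]
        t[-1] = pts[-1] - pts[-2]
        if len(pts) > 2:
            t[1:-1] = pts[2:] - pts[:-2]
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.where(norms == 0, 1.0, norms)


@dataclass
class RadiusProfile:
    """Per-bin per-frame minimal radius along the pathway axis."""

    bin_centers: np.ndarray   # (B,) A from the pathway end, increasing
    values: np.ndarray        # (F, B) minimal radius, A
    trim_start: float
    frame_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def clearance(point: np.ndarray, structure: MolecularStructure,
              coords: np.ndarray | None = None) -> float:
    """Signed clearance of ``point``: min over atoms of |p - c| - r_vdw.

    Negative iff the point lies inside some atom's vdW sphere.  ``coords``
    overrides the structure's coordinates (e.g. a trajectory frame).
    """
    c = structure.coordinates if coords is None else coords
    diff = c - np.asarray(point, dtype=np.float64)
    # explicit (x*x + y*y) + z*z accumulation: reproducible by a plain scan
    d = np.sqrt((diff[:, 0] * diff[:, 0] + diff[:, 1] * diff[:, 1])
                + diff[:, 2] * diff[:, 2])
    return float(np.min(d - structure.vdw_radii))


def clearance_many(points: np.ndarray, structure: MolecularStructure,
                   coords: np.ndarray | None = None) -> np.ndarray:
    """Vectorised :func:`clearance` for an (M, 3) array of probe points."""
    c = structure.coordinates if coords is None else coords
    pts = np.asarray(points, dtype=np.float64)
    diff = c[None, :, :] - pts[:, None, :]
    d = np.sqrt((diff[..., 0] * diff[..., 0] + diff[..., 1] * diff[..., 1])
                + diff[..., 2] * diff[..., 2])
    return np.min(d - structure.vdw_radii[None, :], axis=1)


def _orthobasis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane normal to ``direction``."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _hemisphere_directions(direction: np.ndarray, n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the forward hemisphere around ``direction``.

    Fibonacci spiral in the local frame; includes the axial direction itself
    (k = n - 1 gives z ~ 1) so a straight channel is always a candidate.
    """
    d = direction / np.linalg.norm(direction)
    u, v = _orthobasis(d)
    k = np.arange(n)
    z = (k + 0.5) / n                     # cos(polar angle), in (0, 1)
    rho = np.sqrt(1.0 - z * z)
    phi = k * _GOLDEN_ANGLE
    return (np.outer(rho * np.cos(phi), u)
            + np.outer(rho * np.sin(phi), v)
            + np.outer(z, d))


def _refine_in_disc(point: np.ndarray, normal: np.ndarray, radius: float,
                    structure: MolecularStructure,
                    coords: np.ndarray | None = None,
                    tol: float = 0.01,
                    constraint=None) -> tuple[np.ndarray, float]:
    """Pattern-search maximisation of clearance within a disc.

    The disc has the given ``radius`` and is orthogonal to ``normal`` and
    centred on ``point``.  ``constraint(p)`` may veto candidate positions.
    Deterministic; step halving down to ``tol``.
    """
    u, v = _orthobasis(normal)
    centre = np.asarray(point, dtype=np.float64)
    best = centre.copy()
    best_clear = clearance(best, structure, coords)
    step = radius / 2.0
    offsets = np.array([[1, 0], [-1, 0], [0, 1], [0, -1],
                        [1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=np.float64)
    offsets[4:] /= np.sqrt(2.0)
    while step > tol:
        moved = True
        while moved:
            moved = False
            cands = best + step * (offsets[:, :1] * u + offsets[:, 1:] * v)
            # stay within the disc
            disc_ok = np.linalg.norm(cands - centre, axis=1) <= radius + 1e-9
            cands = cands[disc_ok]
            if len(cands) == 0:
                break
            if constraint is not None:
                keep = np.array([constraint(c) for c in cands], dtype=bool)
                cands = cands[keep]
                if len(cands) == 0:
                    break
            clears = clearance_many(cands, structure, coords)
            i = int(np.argmax(clears))
            if clears[i] > best_clear + 1e-12:
                best = cands[i]
                best_clear = float(clears[i])
                moved = True
        step /= 2.0
    return best, best_clear


def find_path(structure: MolecularStructure, spec: PathwaySpec,
              seed: int = 0) -> PathwayAxis:
    """Grow a maximal-clearance pathway from start to target.

    At each step, ``spec.n_directions`` quasi-uniform candidates on the
    forward hemisphere are scored by clearance; the best candidate that also
    makes net progress toward the target (at least a quarter step) is locally
    refined within the orthogonal disc and accepted.  Deterministic for a
    fixed seed and inputs (the seed only perturbs tie-breaking noise and is
    kept for interface stability).

    Returns a blocked (partial) axis when no candidate with positive
    clearance and progress exists.
    """
    del seed  # construction is fully deterministic
    start = spec.start_point
    target = spec.target_point
    step = spec.step_length
    c0 = clearance(start, structure)
    if c0 <= 0:
        raise ValueError(
            f"start point is buried (clearance {c0:.3f} A <= 0)")

    points = [start.copy()]
    clears = [c0]
    reached = False
    blocked = False
    min_progress = 0.25 * step
    # refinement disc small enough to keep consecutive spacing within
    # [0.5, 1.5] * step_length
    refine_radius = min(spec.search_radius, 0.45 * step)

    while len(points) < spec.max_points:
        p = points[-1]
        to_target = target - p
        dist_t = float(np.linalg.norm(to_target))
        if dist_t <= step:
            reached = True
            break
        dirs = _hemisphere_directions(to_target, spec.n_directions)
        cands = p + step * dirs
        cl = clearance_many(cands, structure)
        progress = dist_t - np.linalg.norm(target - cands, axis=1)
        ok = (cl > 0) & (progress >= min_progress)
        if not np.any(ok):
            blocked = True
            break
        # maximise clearance; break ties by progress, then by index
        order = np.lexsort((np.arange(len(cands)), -progress, -cl))
        best_i = next(i for i in order if ok[i])
        cand = cands[best_i]
        direction = dirs[best_i]

        def _keep_progress(q, _d=dist_t, _t=target):
            return _d - float(np.linalg.norm(_t - q)) >= min_progress

        refined, refined_clear = _refine_in_disc(
            cand, direction, refine_radius, structure, constraint=_keep_progress)
        points.append(refined)
        clears.append(refined_clear)

    pts = np.asarray(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclength_from_end = np.concatenate([[seg.sum()], seg.sum() - np.cumsum(seg)])
    if not reached and not blocked:
        blocked = True  # ran out of max_points
    return PathwayAxis(
        points=pts,
        clearances=np.asarray(clears),
        arclength_from_end=arclength_from_end,
        reached_target=reached,
        blocked=blocked,
        spec=spec,
    )


def min_radius_profile(axis: PathwayAxis, traj: TrajectoryWindow,
                       structure: MolecularStructure | None = None,
                       trim_start: float = 6.0,
                       bin_width: float = 1.0) -> RadiusProfile:
    """Per-frame minimal radius along an existing axis, binned by arclength.

    For every frame each axis point is re-optimised within a disc of radius
    ``axis.spec.search_radius`` orthogonal to the local tangent, and its
    clearance recorded; bins are indexed by arclength from the pathway end
    and the first ``trim_start`` A from the entry side are omitted.
    """
    structure = structure if structure is not None else traj.topology
    if structure is None:
        raise TopologyError("a topology structure is required")
    if traj.n_atoms != structure.n_atoms:
        raise TopologyError(
            f"trajectory has {traj.n_atoms} atoms, structure {structure.n_atoms}")

    tangents = axis.tangents()
    total = axis.total_arclength
    bin_idx = np.floor(axis.arclength_from_end / bin_width).astype(int)
    keep_point = (total - axis.arclength_from_end) >= trim_start
    used_bins = np.unique(bin_idx[keep_point])
    bin_pos = {b: j for j, b in enumerate(used_bins)}

    values = np.full((traj.n_frames, len(used_bins)), np.inf)
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        for i in range(len(axis.points)):
            if not keep_point[i]:
                continue
            _, cl = _refine_in_disc(
                axis.points[i], tangents[i], axis.spec.search_radius,
                structure, coords=coords)
            j = bin_pos[bin_idx[i]]
            if cl < values[f, j]:
                values[f, j] = cl

    centers = (used_bins + 0.5) * bin_width
    # drop any bin whose centre still falls inside the trimmed entry zone
    keep_bin = (total - centers) >= trim_start
    return RadiusProfile(
        bin_centers=centers[keep_bin],
        values=values[:, keep_bin],
        trim_start=trim_start,
        frame_times=traj.frame_times.copy(),
    )


@dataclass
class ConstrictionReport:
    """Global minimum per frame plus temporal variance per bin."""

    minima: list[tuple[int, float, float]]   # (frame, arclength, min radius)
    bin_centers: np.ndarray
    bin_variance: np.ndarray                 # temporal variance per bin


def constriction_report(profile: RadiusProfile) -> ConstrictionReport:
    """Locate the narrowest point per frame and flag circumstantial bins.

    Bins whose minimal radius varies strongly over time mark gate-like
    ("circumstantial") segments, as opposed to constitutively open ones.
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    minima = []
    for f in range(profile.values.shape[0]):
        j = int(np.argmin(profile.values[f]))
        minima.append((f, float(profile.bin_centers[j]),
                       float(profile.values[f, j])))
    variance = np.var(profile.values, axis=0)
    return ConstrictionReport(
        minima=minima,
        bin_centers=profile.bin_centers.copy(),
        bin_variance=variance,
    )
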