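"""Stage-1 screen: maximal-inscribed-sphere pore profile along the membrane
normal, and the open/closed verdict in the transmembrane slab.

For every z slice the profiler maximizes the clearance

    r(c) = min_i ( |c - a_i| - vdw_i )

over in-plane centers c = (cx, cy, z_slice), walking slice by slice from the
seed and starting each local optimization from the previous slice's center
plus deterministically jittered restarts.  A frame is *open* when the radius
exceeds the chloride ionic radius (1.8 Å) at every slice inside the slab —
strictly, so a pore of exactly 1.8 Å is closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exceptions import AnalysisError, SelectionError
from .io_core import Frame, Topology

CHLORIDE_RADIUS = 1.8  # Å, the default open/closed threshold


@dataclass(frozen=True)
class MembraneSlab:
    """z interval between the intracellular and extracellular head-group levels."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if self.z_lower >= self.z_upper:
            raise AnalysisError("slab requires z_lower < z_upper")

    def contains(self, z: float | np.ndarray):
        return (self.z_lower <= z) & (z <= self.z_upper)


@dataclass
class PoreProfile:
    """Per-slice inscribed-sphere centers/radii for one frame."""

    frame_index: int
    slices: np.ndarray  # columns: z, cx, cy, radius
    slab: MembraneSlab
    unbounded: np.ndarray  # bool per slice: radius hit the cap

    @property
    def min_radius_in_slab(self) -> float:
        mask = self.slab.contains(self.slices[:, 0])
        if not mask.any():
            raise AnalysisError("profile has no slices inside the slab")
        return float(self.slices[mask, 3].min())


def compute_slab(
    frame: Frame,
    topology: Topology,
    lower_selection: Iterable[int],
    upper_selection: Iterable[int],
) -> MembraneSlab:
    """Slab from the COM z of two groups of Cα anchor atoms."""
    z_values = []
    for sel in (lower_selection, upper_selection):
        idx = topology.ca_indices(sel)
        if idx.size == 0:
            raise SelectionError(f"no Cα atoms for residues {sorted(sel)}")
        z_values.append(float(frame.coordinates[idx, 2].mean()))
    z_lo, z_hi = sorted(z_values)
    if z_lo == z_hi:
        raise AnalysisError("anchor groups give a zero-height slab")
    return MembraneSlab(z_lower=z_lo, z_upper=z_hi)


def _clearance(
    center: np.ndarray, coords: np.ndarray, radii: np.ndarray
) -> float:
    d = np.sqrt(((coords - center) ** 2).sum(axis=1))
    return float((d - radii).min())


class _ClearanceField:
    """min_i(|p − a_i| − vdw_i), exact via one KD-tree per unique radius."""

    def __init__(self, coords: np.ndarray, radii: np.ndarray):
        from scipy.spatial import cKDTree

        self.groups = [
            (cKDTree(coords[radii == r]), float(r)) for r in np.unique(radii)
        ]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        out = np.full(points.shape[0], np.inf)
        for tree, r in self.groups:
            np.minimum(out, tree.query(points)[0] - r, out=out)
        return out


_COMPASS = np.array([(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)])
_JITTER_STARTS = np.array(
    [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)]
)


def _optimize_slice(
    z: float,
    start_xy: np.ndarray,
    clearance: _ClearanceField,
    max_radius: float,
    jitter: float = 1.0,
    xtol: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Maximize the in-plane clearance by deterministic pattern search.

    Five starts (the previous slice's center plus four jittered offsets)
    walk a compass pattern with halving steps; all candidate points of an
    iteration go through one batched KD-tree query.
    """

    def values(xy: np.ndarray) -> np.ndarray:
        pts = np.column_stack([xy, np.full(xy.shape[0], z)])
        return clearance(pts)

    xy = start_xy + jitter * _JITTER_STARTS  # (5, 2)
    best = values(xy)
    step = max(1.0, jitter)
    while step >= xtol and best.max() < max_radius:
        # candidates: 4 compass moves per start, one batched evaluation
        cand = xy[:, None, :] + step * _COMPASS[None, :, :]  # (5, 4, 2)
        vals = values(cand.reshape(-1, 2)).reshape(5, 4)
        arg = vals.argmax(axis=1)
        gain = vals[np.arange(5), arg] > best + 1e-12
        if gain.any():
            xy[gain] = cand[np.arange(5), arg][gain]
            best[gain] = vals[np.arange(5), arg][gain]
        else:
            step /= 2.0
    k = int(best.argmax())
    return xy[k].copy(), float(min(best[k], max_radius))


def profile_pore(
    frame: Frame,
    topology: Topology,
    slab: MembraneSlab,
    seed_point: tuple[float, float, float],
    slice_step: float = 0.5,
    max_radius: float = 10.0,
    margin: float = 2.0,
    include_lipids: bool = False,
) -> PoreProfile:
    """Walk z slices from below the slab to above it, maximizing clearance.

    Pore-bounding atoms are protein atoms by default; ``include_lipids``
    adds lipid atoms (pore walls can be lipid-lined near kinked helices).
    Slices where the optimum exceeds ``max_radius`` are reported at the cap
    and flagged unbounded (pore merged with bulk).
    """
    if slice_step <= 0:
        raise AnalysisError("slice_step must be > 0")
    classes = {"protein", "lipid"} if include_lipids else {"protein"}
    sel = np.array(
        [a.index for a in topology.atoms if a.segment_class in classes]
    )
    if sel.size == 0:
        raise SelectionError("no pore-bounding atoms in the topology")
    coords_all = frame.coordinates[sel]
    radii_all = topology.vdw_radii()[sel]

    seed = np.asarray(seed_point, dtype=float)
    if _clearance(seed, coords_all, radii_all) <= -max(radii_all):
        raise AnalysisError("seed point lies inside an atom far from any pore")

    z_values = np.arange(
        slab.z_lower - margin, slab.z_upper + margin + slice_step / 2, slice_step
    )
    # walk outward from the slice nearest the seed so centers track the pore
    start_k = int(np.argmin(np.abs(z_values - seed[2])))
    order = list(range(start_k, len(z_values))) + list(
        range(start_k - 1, -1, -1)
    )

    rows = np.empty((len(z_values), 4))
    unbounded = np.zeros(len(z_values), dtype=bool)
    clearance = _ClearanceField(coords_all, radii_all)
    centers: dict[int, np.ndarray] = {}
    for k in order:
        z = z_values[k]
        if k == start_k:
            start_xy = seed[:2].copy()
        elif k > start_k:
            start_xy = centers[k - 1]
        else:
            start_xy = centers[k + 1]
        xy, r = _optimize_slice(z, start_xy, clearance, max_radius)
        rows[k] = (z, xy[0], xy[1], max(r, 0.0))
        unbounded[k] = r >= max_radius
        centers[k] = xy
    return PoreProfile(
        frame_index=frame.frame_index, slices=rows, slab=slab, unbounded=unbounded
    )


def classify_open(
    profile: PoreProfile,
    slab: MembraneSlab | None = None,
    r_min: float = CHLORIDE_RADIUS,
) -> bool:
    """True iff every slab slice radius is strictly larger than ``r_min``."""
    slab = slab or profile.slab
    mask = slab.contains(profile.slices[:, 0])
    if not mask.any():
        raise AnalysisError("no profile slices inside the slab")
    return bool(np.all(profile.slices[mask, 3] > r_min))


def brute_force_slice_radius(
    frame: Frame,
    topology: Topology,
    z: float,
    xy_center: tuple[float, float],
    half_extent: float = 6.0,
    grid: float = 0.05,
    include_lipids: bool = False,
) -> float:
    """Independent oracle: exhaustive in-plane grid scan of the clearance.

    Scans a (2*half_extent)^2 window at ``grid`` spacing around
    ``xy_center`` and returns the maximal clearance found.
    """
    classes = {"protein", "lipid"} if include_lipids else {"protein"}
    sel = np.array(
        [a.index for a in topology.atoms if a.segment_class in classes]
    )
    coords = frame.coordinates[sel]
    radii = topology.vdw_radii()[sel]
    near = np.abs(coords[:, 2] - z) <= 12.0 + radii.max()
    coords, radii = coords[near], radii[near]
    xs = np.arange(xy_center[0] - half_extent, xy_center[0] + half_extent + grid / 2, grid)
    ys = np.arange(xy_center[1] - half_extent, xy_center[1] + half_extent + grid / 2, grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    best = -np.inf
    for chunk in np.array_split(points, max(1, points.shape[0] // 20000)):
        d = np.sqrt(
            ((chunk[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        )
        clear = (d - radii[None, :]).min(axis=1)
        best = max(best, float(clear.max()))
    return best


def profile_trajectory(
    trajectory,
    slab: MembraneSlab,
    seed_point: tuple[float, float, float],
    **kwargs,
) -> list[PoreProfile]:
    """Profile every frame; convenience wrapper for the screening stage."""
    return [
        profile_pore(frame, trajectory.topology, slab, seed_point, **kwargs)
        for frame in trajectory.frames
    ]
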