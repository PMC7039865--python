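"""Stage-2 screen: grid-based tunnel search from an interior seed point.

A regular 3D grid is laid over the transmembrane atom selection.  Each node
carries the clearance r = min_i(|node - a_i| - vdw_i); nodes with r below
the cutoff radius (default 1.8 Å, the chloride ionic radius) are blocked.
Bulk solvent is marked where the clearance reaches the shell radius, and
exit nodes form the surface layer within shell depth of bulk.  Tunnels are
lowest-cost paths from the seed to exit nodes under the throughput cost

    edge cost = edge_length / r_mid**2

(r_mid = clearance at the edge midpoint; the exponent is configurable).
Distinct tunnels are kept apart by an average inter-path divergence
threshold (default 4.5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .exceptions import AnalysisError, SelectionError
from .io_core import Frame, Topology
from .pore_profile import MembraneSlab

_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class Tunnel:
    """An ordered sphere chain from the seed to the protein surface."""

    frame_index: int
    spheres: np.ndarray  # (n, 4): x, y, z, radius
    cost: float
    endpoint: str | None = None  # intracellular / extracellular / lateral
    n_members: int = 1  # near-duplicate paths merged into this tunnel

    @property
    def length(self) -> float:
        centers = self.spheres[:, :3]
        return float(np.sqrt(((np.diff(centers, axis=0)) ** 2).sum(axis=1)).sum())

    @property
    def bottleneck_radius(self) -> float:
        return float(self.spheres[:, 3].min())


@dataclass
class OpenConformation:
    """A frame with simultaneously open intracellular and extracellular routes."""

    frame_index: int
    tunnels: list[Tunnel]
    selected_pair: tuple[Tunnel, Tunnel]  # (intracellular, extracellular)


def seed_point(
    frame: Frame, topology: Topology, residue_pair: Sequence[int]
) -> np.ndarray:
    """Midpoint of the Cα atoms of two residues (the search start)."""
    if len(residue_pair) != 2:
        raise SelectionError("seed needs exactly two residues")
    points = []
    for res in residue_pair:
        idx = topology.ca_indices([res])
        points.append(frame.coordinates[idx[0]])
    return (points[0] + points[1]) / 2.0


def _clearance_batch(
    points: np.ndarray, coords: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """min_i(|p - a_i| - vdw_i) for each point.

    Exact for mixed radii: atoms are grouped by unique vdW radius and each
    group queried through its own KD-tree.
    """
    points = np.atleast_2d(points)
    out = np.full(points.shape[0], np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(points)
        np.minimum(out, d - r, out=out)
    return out


class TunnelGrid:
    """Clearance field on a regular grid; shared by search and re-checks."""

    def __init__(
        self,
        frame: Frame,
        topology: Topology,
        tm_selection: Iterable[int] | None,
        grid_step: float,
        cutoff_radius: float,
        shell_radius: float,
        margin: float | None = None,
    ):
        if tm_selection is not None:
            atom_idx = topology.select(residue_indices=tm_selection)
        else:
            atom_idx = topology.select(segment_class="protein")
        self.coords = frame.coordinates[atom_idx]
        self.radii = topology.vdw_radii()[atom_idx]
        self.grid_step = grid_step
        self.cutoff_radius = cutoff_radius
        self.shell_radius = shell_radius
        margin = shell_radius + 2 * grid_step if margin is None else margin
        lo = self.coords.min(axis=0) - margin
        hi = self.coords.max(axis=0) + margin
        self.shape = np.maximum(
            2, np.ceil((hi - lo) / grid_step).astype(int) + 1
        )
        self.origin = lo
        axes = [lo[k] + grid_step * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        self.points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        self.clearance = _clearance_batch(self.points, self.coords, self.radii)

    def node_index(self, ijk: np.ndarray) -> np.ndarray:
        return np.ravel_multi_index(ijk.T, self.shape)

    def nearest_node(self, point: np.ndarray) -> int:
        ijk = np.clip(
            np.round((point - self.origin) / self.grid_step).astype(int),
            0,
            self.shape - 1,
        )
        return int(np.ravel_multi_index(ijk, self.shape))

    def free_mask(self) -> np.ndarray:
        return self.clearance >= self.cutoff_radius

    def boundary_mask(self) -> np.ndarray:
        idx = np.unravel_index(np.arange(self.points.shape[0]), self.shape)
        mask = np.zeros(self.points.shape[0], dtype=bool)
        for k in range(3):
            mask |= (idx[k] == 0) | (idx[k] == self.shape[k] - 1)
        return mask

    def clearance_at(self, points: np.ndarray) -> np.ndarray:
        return _clearance_batch(np.atleast_2d(points), self.coords, self.radii)


def _build_graph(
    grid: TunnelGrid, cost_exponent: float, traversable: np.ndarray | None = None
) -> tuple[csr_matrix, np.ndarray]:
    """Sparse 26-connected graph over traversable nodes with throughput costs.

    Bulk solvent nodes are excluded by the caller: a tunnel terminates at
    the protein surface rather than wrapping around it through solvent.
    """
    free = grid.free_mask() if traversable is None else traversable
    n = grid.points.shape[0]
    all_ijk = np.column_stack(
        np.unravel_index(np.arange(n), grid.shape)
    )
    rows, cols = [], []
    free_ijk = all_ijk[free]
    free_nodes = np.flatnonzero(free)
    for off in _NEIGHBOR_OFFSETS:
        nb = free_ijk + off
        ok = np.all((nb >= 0) & (nb < grid.shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, grid.shape)
        src = free_nodes[ok]
        keep = free[nb_flat] & (src < nb_flat)  # undirected, once per pair
        rows.append(src[keep])
        cols.append(nb_flat[keep])
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    lengths = np.sqrt(
        ((grid.points[rows] - grid.points[cols]) ** 2).sum(axis=1)
    )
    mids = (grid.points[rows] + grid.points[cols]) / 2.0
    r_mid = grid.clearance_at(mids) if rows.size else np.empty(0)
    r_mid = np.maximum(r_mid, 1e-6)
    weights = lengths / r_mid**cost_exponent
    graph = csr_matrix(
        (
            np.concatenate([weights, weights]),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(n, n),
    )
    return graph, free


def path_divergence(path_a: np.ndarray, path_b: np.ndarray) -> float:
    """Symmetrized mean nearest-point distance between two center chains."""
    tree_a, tree_b = cKDTree(path_a), cKDTree(path_b)
    d_ab = tree_b.query(path_a)[0].mean()
    d_ba = tree_a.query(path_b)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def search_tunnels(
    frame: Frame,
    topology: Topology,
    seed: np.ndarray,
    cutoff_radius: float = 1.8,
    shell_radius: float = 6.0,
    shell_depth: float = 3.0,
    grid_step: float = 0.8,
    tm_selection: Iterable[int] | None = None,
    clustering_threshold: float = 4.5,
    cost_exponent: float = 2.0,
) -> list[Tunnel]:
    """Find distinct lowest-cost tunnels from the seed to the surface.

    Returns tunnels sorted by cost; each is the cheapest representative of a
    family of near-duplicate exit paths (families separated by the
    clustering threshold).  Raises if the seed is buried; returns an empty
    list when no exit is reachable.
    """
    grid = TunnelGrid(
        frame, topology, tm_selection, grid_step, cutoff_radius, shell_radius
    )
    all_free = grid.free_mask()
    bulk = (grid.clearance >= shell_radius) | (grid.boundary_mask() & all_free)
    if not bulk.any():
        return []
    graph, free = _build_graph(grid, cost_exponent, all_free & ~bulk)
    seed_node = grid.nearest_node(np.asarray(seed, dtype=float))
    if not free[seed_node]:
        # allow snapping to a free node within one step of the seed
        near = np.flatnonzero(free)
        if near.size == 0:
            raise AnalysisError("seed buried: no free grid nodes at all")
        d = np.sqrt(((grid.points[near] - seed) ** 2).sum(axis=1))
        if d.min() > grid_step * np.sqrt(3):
            raise AnalysisError("seed buried: clearance below the cutoff radius")
        seed_node = int(near[np.argmin(d)])

    bulk_tree = cKDTree(grid.points[bulk])
    free_nodes = np.flatnonzero(free & ~bulk)
    d_to_bulk = bulk_tree.query(grid.points[free_nodes])[0]
    exit_nodes = free_nodes[d_to_bulk <= shell_depth]
    if exit_nodes.size == 0:
        return []

    dist, predecessors = dijkstra(
        graph, directed=False, indices=seed_node, return_predecessors=True
    )
    reachable = exit_nodes[np.isfinite(dist[exit_nodes])]
    if reachable.size == 0:
        return []
    # one candidate path per local cost minimum on the exit layer: an exit
    # node kept only if no neighbouring exit node is cheaper to reach
    exit_set = set(int(e) for e in reachable)
    exit_ijk = np.column_stack(np.unravel_index(reachable, grid.shape))
    keep_local = []
    for node, ijk in zip(reachable, exit_ijk):
        best = True
        for off in _NEIGHBOR_OFFSETS:
            nb = ijk + off
            if np.any(nb < 0) or np.any(nb >= grid.shape):
                continue
            nb_flat = int(np.ravel_multi_index(nb, grid.shape))
            if nb_flat in exit_set and dist[nb_flat] < dist[node]:
                best = False
                break
        if best:
            keep_local.append(node)
    reachable = np.array(keep_local)
    order = reachable[np.argsort(dist[reachable], kind="stable")]

    tunnels: list[Tunnel] = []
    rep_paths: list[np.ndarray] = []
    for node in order:
        chain = []
        k = node
        while k != -9999 and k != seed_node:
            chain.append(k)
            k = predecessors[k]
        chain.append(seed_node)
        chain.reverse()
        centers = grid.points[chain]
        matched = False
        for t, rep in zip(tunnels, rep_paths):
            if path_divergence(centers, rep) < clustering_threshold:
                t.n_members += 1
                matched = True
                break
        if not matched:
            radii = grid.clearance[chain]
            spheres = np.column_stack([centers, radii])
            tunnels.append(
                Tunnel(
                    frame_index=frame.frame_index,
                    spheres=spheres,
                    cost=float(dist[node]),
                )
            )
            rep_paths.append(centers)
    return tunnels


def classify_endpoint(tunnel: Tunnel, slab: MembraneSlab) -> str:
    """Label a tunnel by where its last sphere exits relative to the slab."""
    if tunnel.spheres.shape[0] < 2:
        raise AnalysisError("tunnel needs at least 2 spheres to classify")
    z_end = tunnel.spheres[-1, 2]
    if z_end < slab.z_lower:
        label = "intracellular"
    elif z_end > slab.z_upper:
        label = "extracellular"
    else:
        label = "lateral"  # membrane-facing exit, excluded from IC/EC pairing
    tunnel.endpoint = label
    return label


def classify_tunnels(tunnels: Iterable[Tunnel], slab: MembraneSlab) -> None:
    for t in tunnels:
        classify_endpoint(t, slab)


def select_open_conformations(
    per_frame_tunnels: dict[int, list[Tunnel]],
) -> list[OpenConformation]:
    """Keep frames with ≥1 intracellular and ≥1 extracellular tunnel.

    The selected pair minimizes the summed cost; ties break toward the
    larger combined bottleneck, then toward lower tunnel indices within the
    frame.
    """
    out: list[OpenConformation] = []
    for frame_index in sorted(per_frame_tunnels):
        tunnels = per_frame_tunnels[frame_index]
        ic = [
            (i, t) for i, t in enumerate(tunnels) if t.endpoint == "intracellular"
        ]
        ec = [
            (i, t) for i, t in enumerate(tunnels) if t.endpoint == "extracellular"
        ]
        if not ic or not ec:
            continue
        best = min(
            ((a, b) for a in ic for b in ec),
            key=lambda pair: (
                pair[0][1].cost + pair[1][1].cost,
                -(pair[0][1].bottleneck_radius + pair[1][1].bottleneck_radius),
                pair[0][0],
                pair[1][0],
            ),
        )
        out.append(
            OpenConformation(
                frame_index=frame_index,
                tunnels=tunnels,
                selected_pair=(best[0][1], best[1][1]),
            )
        )
    return out


def verify_tunnel_clearance(
    tunnel: Tunnel,
    frame: Frame,
    topology: Topology,
    tm_selection: Iterable[int] | None,
    cutoff_radius: float,
) -> bool:
    """Independent re-check: every sphere keeps ≥ cutoff clearance."""
    if tm_selection is not None:
        idx = topology.select(residue_indices=tm_selection)
    else:
        idx = topology.select(segment_class="protein")
    coords = frame.coordinates[idx]
    radii = topology.vdw_radii()[idx]
    clear = _clearance_batch(tunnel.spheres[:, :3], coords, radii)
    return bool(np.all(clear >= cutoff_radius - 1e-9))
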