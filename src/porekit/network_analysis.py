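"""Dynamical-network analysis of correlated residue motions.

Nodes are residues (their Cα atoms); the dynamical cross-correlation

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)

is computed from mean-free Cα displacement vectors after superposing each
frame onto the window-mean structure.  Residue pairs in persistent contact
(any heavy-atom pair within the contact cutoff in at least a fraction of
the window frames) are connected by edges of weight w_ij = −ln|C_ij|, so
strongly (anti-)correlated neighbours are cheap to traverse.  Allosteric
coupling between two residues is measured by the number of suboptimal
paths: all simple paths no longer than the optimal path plus a tolerance,
enumerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import AnalysisError, SelectionError
from .io_core import Trajectory, superpose


def _ca_indices_per_residue(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    top = trajectory.topology
    idx = [a.index for a in top.atoms if a.name.strip().upper() == "CA"]
    if not idx:
        raise SelectionError("no Cα atoms in the trajectory")
    resids = np.array([top.atoms[i].residue_index for i in idx])
    if len(set(resids)) != len(resids):
        raise AnalysisError("expected exactly one Cα per residue")
    return np.array(idx), resids


def correlation_matrix(
    trajectory: Trajectory,
    window: tuple[int, int] | None = None,
    fit: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Dynamical cross-correlation matrix of Cα motions over a frame window.

    Returns (C, residue_indices).  With ``fit=True`` every frame is
    superposed onto the window-mean structure first, so rigid-body motion
    does not register as correlation; residues left with zero variance are
    flagged with a warning and their correlations set to 0.
    """
    ca_idx, resids = _ca_indices_per_residue(trajectory)
    frames = trajectory.frames
    if window is not None:
        frames = frames[window[0] : window[1]]
    if len(frames) < 10:
        raise AnalysisError("correlation window needs at least 10 frames")
    coords = np.array([f.coordinates[ca_idx] for f in frames])

    if fit:
        # two-pass: align to the first frame, then to the resulting mean
        reference = coords[0]
        for _ in range(2):
            aligned = np.empty_like(coords)
            for t in range(coords.shape[0]):
                aligned[t] = superpose(coords[t], reference).apply(coords[t])
            reference = aligned.mean(axis=0)
            coords = aligned
    mean = coords.mean(axis=0)
    delta = coords - mean  # (T, N, 3)

    inner = np.einsum("tix,tjx->ij", delta, delta) / delta.shape[0]
    var = np.diag(inner).copy()
    immobile = var < 1e-12
    if immobile.any():
        warnings.warn(
            f"{int(immobile.sum())} residue(s) immobile after superposition; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    denom = np.sqrt(np.outer(np.where(immobile, 1.0, var), np.where(immobile, 1.0, var)))
    C = inner / denom
    C[immobile, :] = 0.0
    C[:, immobile] = 0.0
    np.fill_diagonal(C, 1.0)
    return C, resids


@dataclass
class CorrelationNetwork:
    """Residue graph with correlation-derived edge weights w = −ln|C|."""

    graph: nx.Graph
    correlation: np.ndarray
    residue_indices: np.ndarray

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


def build_network(
    C: np.ndarray,
    residue_indices: np.ndarray,
    trajectory: Trajectory,
    window: tuple[int, int] | None = None,
    contact_cut: float = 4.5,
    contact_fraction: float = 0.75,
) -> CorrelationNetwork:
    """Contact-filtered weighted graph over residues.

    An edge (i, j) exists when any heavy-atom pair of the two residues is
    within ``contact_cut`` in at least ``contact_fraction`` of the window
    frames and |C_ij| > 0; consecutive residues are allowed.  Disconnected
    graphs are permitted.
    """
    top = trajectory.topology
    frames = trajectory.frames
    if window is not None:
        frames = frames[window[0] : window[1]]
    n_frames = len(frames)
    n = len(residue_indices)
    res_pos = {int(r): k for k, r in enumerate(residue_indices)}

    heavy: dict[int, np.ndarray] = {}
    for row, res in enumerate(top.residues):
        if res["residue_index"] in res_pos:
            atoms = top.atoms_of_residue_row(row)
            heavy[res_pos[res["residue_index"]]] = np.array(
                [i for i in atoms if top.atoms[i].element.upper() != "H"]
            )

    contact_counts = np.zeros((n, n), dtype=int)
    for frame in frames:
        pos = frame.coordinates
        # residue bounding check via min-distance between atom sets
        for i in range(n):
            ai = pos[heavy[i]]
            for j in range(i + 1, n):
                aj = pos[heavy[j]]
                d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(axis=2)
                if d2.min() < contact_cut**2:
                    contact_counts[i, j] += 1

    graph = nx.Graph()
    graph.add_nodes_from(int(r) for r in residue_indices)
    for i in range(n):
        for j in range(i + 1, n):
            if contact_counts[i, j] / n_frames >= contact_fraction:
                c = abs(C[i, j])
                if c > 0.0:
                    graph.add_edge(
                        int(residue_indices[i]),
                        int(residue_indices[j]),
                        weight=float(-np.log(min(c, 1.0))),
                    )
    return CorrelationNetwork(
        graph=graph, correlation=C, residue_indices=residue_indices
    )


@dataclass
class PathEnsemble:
    """Optimal plus all near-optimal simple paths between two residues."""

    source: int
    sink: int
    optimal_length: float
    optimal_path: list[int]
    paths: list[tuple[float, list[int]]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.paths)


def suboptimal_paths(
    network: CorrelationNetwork,
    source: int,
    sink: int,
    tolerance: float = 0.5,
) -> PathEnsemble:
    """Enumerate exactly all simple paths with weight ≤ optimal + tolerance.

    Enumeration is a depth-first search pruned with the exact
    remaining-distance-to-sink lower bound (admissible, so no qualifying
    path is missed).  A disconnected pair yields count 0 and an infinite
    optimal length.
    """
    g = network.graph
    if source not in g or sink not in g:
        raise SelectionError("source or sink residue not in the network")
    if source == sink:
        return PathEnsemble(source, sink, 0.0, [source], paths=[(0.0, [source])])
    try:
        dist_to_sink = nx.single_source_dijkstra_path_length(
            g, sink, weight="weight"
        )
        optimal_length = dist_to_sink[source]
        optimal_path = nx.dijkstra_path(g, source, sink, weight="weight")
    except (nx.NetworkXNoPath, KeyError):
        return PathEnsemble(source, sink, float("inf"), [], paths=[])

    budget = optimal_length + tolerance
    found: list[tuple[float, list[int]]] = []
    path = [source]
    on_path = {source}

    def dfs(node: int, used: float) -> None:
        if node == sink:
            found.append((used, list(path)))
            return
        for nb, data in g[node].items():
            if nb in on_path:
                continue
            w = data["weight"]
            bound = dist_to_sink.get(nb, float("inf"))
            if used + w + bound <= budget + 1e-12:
                path.append(nb)
                on_path.add(nb)
                dfs(nb, used + w)
                path.pop()
                on_path.remove(nb)

    dfs(source, 0.0)
    found.sort(key=lambda p: (p[0], p[1]))
    return PathEnsemble(
        source=source,
        sink=sink,
        optimal_length=optimal_length,
        optimal_path=optimal_path,
        paths=found,
    )


def coupling_table(
    network: CorrelationNetwork,
    sources: list[int],
    sinks: list[int],
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Suboptimal-path counts for every (source, sink) combination, ranked."""
    if not sources or not sinks:
        raise SelectionError("sources and sinks must be non-empty")
    rows = []
    for s in sources:
        for t in sinks:
            ens = suboptimal_paths(network, s, t, tolerance)
            rows.append(
                {
                    "source": s,
                    "sink": t,
                    "optimal_length": ens.optimal_length,
                    "n_paths": ens.count,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["n_paths", "optimal_length"], ascending=[False, True]
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
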