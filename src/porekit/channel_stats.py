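"""Post-detection statistics over the open conformations.

Covers lining-residue identification (any atom closer than the contact
distance, default 3.0 Å, to a tunnel sphere surface), normalized
lining-residue frequencies over the open frames, Ward clustering of open
channels on the lining-residue atom positions, and the averaged
radius-vs-z channel profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import AnalysisError
from .io_core import Frame, Topology, Trajectory
from .tunnel_search import OpenConformation, Tunnel

CAVER_CONTACT_DISTANCE = 3.0  # Å, distance from atom to sphere surface


def lining_residues(
    tunnel: Tunnel,
    frame: Frame,
    topology: Topology,
    contact_distance: float = CAVER_CONTACT_DISTANCE,
    heavy_only: bool = True,
) -> set[int]:
    """Residue indices with any atom within ``contact_distance`` of a sphere
    surface (atom-to-center distance minus sphere radius, strict <)."""
    atom_idx = np.array(
        [
            a.index
            for a in topology.atoms
            if a.segment_class == "protein"
            and (not heavy_only or a.element.upper() != "H")
        ]
    )
    if atom_idx.size == 0:
        return set()
    coords = frame.coordinates[atom_idx]
    centers = tunnel.spheres[:, :3]
    radii = tunnel.spheres[:, 3]
    out: set[int] = set()
    chunk = max(1, int(2_000_000 // max(centers.shape[0], 1)))
    for s in range(0, coords.shape[0], chunk):
        block = coords[s : s + chunk]
        d = np.sqrt(((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        gap = (d - radii[None, :]).min(axis=1)
        for local in np.flatnonzero(gap < contact_distance):
            out.add(topology.atoms[atom_idx[s + local]].residue_index)
    return out


def _pair_lining(
    oc: OpenConformation,
    trajectory: Trajectory,
    contact_distance: float,
) -> set[int]:
    frame = trajectory.frames[oc.frame_index]
    resids: set[int] = set()
    for tunnel in oc.selected_pair:
        resids |= lining_residues(
            tunnel, frame, trajectory.topology, contact_distance
        )
    return resids


def lining_frequency(
    open_conformations: list[OpenConformation],
    trajectory: Trajectory,
    contact_distance: float = CAVER_CONTACT_DISTANCE,
    normalization: str = "max",
) -> pd.DataFrame:
    """Per-residue count of open frames lined, normalized to the maximum
    count (``normalization='max'``) or to the number of open frames
    (``'n_open'``)."""
    if not open_conformations:
        raise AnalysisError("no open conformations to count lining residues in")
    if normalization not in ("max", "n_open"):
        raise AnalysisError(f"unknown normalization {normalization!r}")
    counts: dict[int, int] = {}
    for oc in open_conformations:
        for res in _pair_lining(oc, trajectory, contact_distance):
            counts[res] = counts.get(res, 0) + 1
    if not counts:
        raise AnalysisError("no residue lines any selected tunnel")
    names = {
        a.residue_index: a.residue_name for a in trajectory.topology.atoms
    }
    denom = max(counts.values()) if normalization == "max" else len(
        open_conformations
    )
    rows = [
        {
            "residue_index": res,
            "residue_name": names.get(res, "?"),
            "raw_count": n,
            "frequency": n / denom,
        }
        for res, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class ChannelCluster:
    members: list[int]  # open-frame indices
    medoid: int
    height: float  # linkage height at which the cluster formed


def _lining_rmsd_matrix(
    open_conformations: list[OpenConformation],
    trajectory: Trajectory,
    contact_distance: float,
) -> np.ndarray:
    """Pairwise frame distance = RMSD over the union of lining-residue atoms.

    Frames are assumed pre-aligned to a common reference; coordinates are
    compared as-is.  Every residue's atoms exist in every frame, so the
    union set is well-defined for each pair.
    """
    top = trajectory.topology
    linings = [
        _pair_lining(oc, trajectory, contact_distance)
        for oc in open_conformations
    ]
    atoms_of_res: dict[int, np.ndarray] = {}
    for row, res in enumerate(top.residues):
        atoms_of_res.setdefault(
            res["residue_index"], top.atoms_of_residue_row(row)
        )
    n = len(open_conformations)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sorted(linings[i] | linings[j])
            idx = np.concatenate([atoms_of_res[r] for r in union])
            a = trajectory.frames[open_conformations[i].frame_index].coordinates[idx]
            b = trajectory.frames[open_conformations[j].frame_index].coordinates[idx]
            dist[i, j] = dist[j, i] = float(
                np.sqrt(((a - b) ** 2).sum() / idx.size)
            )
    return dist


def cluster_channels(
    open_conformations: list[OpenConformation],
    trajectory: Trajectory,
    threshold: float = 4.5,
    contact_distance: float = CAVER_CONTACT_DISTANCE,
) -> tuple[list[ChannelCluster], np.ndarray]:
    """Ward clustering of open frames on lining-residue positions.

    Returns the clusters (cut at ``threshold``) and the full linkage matrix.
    With fewer than two open frames a single trivial cluster is returned.
    """
    n = len(open_conformations)
    if n == 0:
        raise AnalysisError("no open conformations to cluster")
    if n == 1:
        return [ChannelCluster(members=[0], medoid=0, height=0.0)], np.empty((0, 4))
    dist = _lining_rmsd_matrix(open_conformations, trajectory, contact_distance)
    link = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(link, t=threshold, criterion="distance")
    clusters: list[ChannelCluster] = []
    for lab in sorted(set(labels)):
        members = [i for i in range(n) if labels[i] == lab]
        sub = dist[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        heights = [
            float(row[2])
            for row in link
            if row[2] <= threshold
        ]
        clusters.append(
            ChannelCluster(
                members=members,
                medoid=medoid,
                height=max(heights) if heights and len(members) > 1 else 0.0,
            )
        )
    return clusters, link


def radius_profile_z(
    open_conformations: list[OpenConformation],
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Pool all spheres of the selected tunnel pairs and average radius by z."""
    if not open_conformations:
        raise AnalysisError("no open conformations to profile")
    spheres = np.vstack(
        [t.spheres for oc in open_conformations for t in oc.selected_pair]
    )
    if spheres.size == 0:
        raise AnalysisError("empty sphere pool")
    z = spheres[:, 2]
    lo = np.floor(z.min() / bin_width) * bin_width
    edges = np.arange(lo, z.max() + bin_width, bin_width)
    if edges[-1] <= z.max():
        edges = np.append(edges, edges[-1] + bin_width)
    which = np.digitize(z, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        rows.append(
            {
                "z_center": (edges[b] + edges[b + 1]) / 2.0,
                "mean_radius": float(spheres[mask, 3].mean()) if mask.any() else np.nan,
                "n_spheres": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
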