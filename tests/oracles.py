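"""Shared test helpers and independent oracle implementations."""

import numpy as np

from porekit.io_core import AtomRecord, Frame, Topology, Trajectory
from porekit.tunnel_search import OpenConformation, Tunnel


def chain_trajectory(frame_coords, n_res=4):
    """Cα-only chain topology with the given per-frame coordinates."""
    atoms = [
        AtomRecord(i, "CA", "C", 1.7, i + 1, "ALA", "A", "protein")
        for i in range(n_res)
    ]
    top = Topology(atoms)
    frames = [
        Frame(i, np.asarray(c, dtype=float)) for i, c in enumerate(frame_coords)
    ]
    return Trajectory(topology=top, frames=frames)


def stub_conf(frame_index, sphere_xyz=(0.0, 0.0, 0.0), radius=50.0):
    """Open conformation whose single-sphere tunnels cover chosen atoms."""
    spheres = np.array([[*sphere_xyz, radius], [*sphere_xyz, radius]])
    t = Tunnel(frame_index, spheres, cost=1.0, endpoint="intracellular")
    u = Tunnel(frame_index, spheres.copy(), cost=1.0, endpoint="extracellular")
    return OpenConformation(frame_index, [t, u], (t, u))


def carved_cavity(grid_step_atoms=1.6, vdw=1.0):
    """Solid atom lattice with a junction and two carved branches.

    Branch A (+x): carve radius 4.0 — wide.  Branch B (−x): carve radius
    2.6 — narrow.  The throughput cost ranks A first.
    """
    xs = np.arange(20.0, 61.0, grid_step_atoms)
    ys = np.arange(30.0, 51.0, grid_step_atoms)
    zs = np.arange(30.0, 51.0, grid_step_atoms)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    center = np.array([40.0, 40.0, 40.0])

    def in_branch(p, direction, radius):
        rel = p - center
        axial = rel @ direction
        lateral = np.linalg.norm(rel - np.outer(axial, direction), axis=1)
        return (axial >= -1.0) & (lateral < radius + vdw)

    keep = ~(
        in_branch(pts, np.array([1.0, 0, 0]), 4.0)
        | in_branch(pts, np.array([-1.0, 0, 0]), 2.6)
    )
    pts = pts[keep]
    atoms = [
        AtomRecord(i, "C", "C", vdw, i + 1, "GLY", "A", "protein")
        for i in range(len(pts))
    ]
    return Topology(atoms), Frame(0, pts)


def ward_oracle(dist):
    """Brute-force agglomerative Ward via the Lance–Williams update.

    Returns the merge sequence as (member_set_a, member_set_b, height) —
    an implementation independent of scipy's linkage.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(clusters) > 1:
        (a, b), dij = min(d.items(), key=lambda kv: kv[1])
        merges.append((clusters[a], clusters[b], dij))
        new = clusters[a] | clusters[b]
        na, nb = sizes[a], sizes[b]
        del clusters[a], clusters[b]
        updates = {}
        for m in clusters:
            nm = sizes[m]
            dam = d[(min(a, m), max(a, m))]
            dbm = d[(min(b, m), max(b, m))]
            updates[m] = np.sqrt(
                ((na + nm) * dam**2 + (nb + nm) * dbm**2 - nm * dij**2)
                / (na + nb + nm)
            )
        d = {
            (i, j): v
            for (i, j), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        for m, v in updates.items():
            d[(min(next_id, m), max(next_id, m))] = float(v)
        clusters[next_id] = new
        sizes[next_id] = na + nb
        next_id += 1
    return merges
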