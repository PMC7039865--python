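"""Ion–protein contact statistics.

A residue–ion contact is counted once per frame when any protein atom of
the residue lies strictly within the cutoff (default 4.0 Å) of the ion.
Frequencies are per-frame rates (count / frames in the partition) so that
open-frame and closed-frame maps are directly comparable.  Distances use
the minimum-image convention when a periodic box is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, SelectionError
from .io_core import Trajectory

ION_CONTACT_CUTOFF = 4.0  # Å, strict "<"


def _min_image_delta(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    if box is None or np.any(box >= 900.0):
        return delta
    return delta - box * np.round(delta / box)


@dataclass
class IonContactMap:
    """Raw per-(residue, ion) frame counts plus normalized frequencies."""

    residue_indices: np.ndarray
    ion_labels: list[str]
    counts: np.ndarray  # (n_residues, n_ions) frames in contact
    any_ion_counts: np.ndarray  # frames in which the residue contacts any ion
    n_frames: int
    partition: str  # all | open | closed

    @property
    def frequencies(self) -> np.ndarray:
        """Per-frame contact rate of each residue with any ion."""
        return self.any_ion_counts / self.n_frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": self.residue_indices,
                "count_any_ion": self.any_ion_counts,
                "frequency": self.frequencies,
            }
        )


def contact_map(
    trajectory: Trajectory,
    ion_selection: Iterable[int],
    protein_selection: Iterable[int] | None = None,
    d_cut: float = ION_CONTACT_CUTOFF,
    frame_subset: Sequence[int] | None = None,
    partition: str = "all",
) -> IonContactMap:
    """Count, per residue and ion, the frames with any atom–ion distance < d_cut."""
    top = trajectory.topology
    ion_idx = np.asarray(list(ion_selection), dtype=int)
    if ion_idx.size == 0:
        raise SelectionError("empty ion selection")
    if protein_selection is None:
        prot_idx = top.select(segment_class="protein")
    else:
        prot_idx = np.asarray(list(protein_selection), dtype=int)
    if prot_idx.size == 0:
        raise SelectionError("empty protein selection")

    res_of_atom = np.array([top.atoms[i].residue_index for i in prot_idx])
    residues = np.unique(res_of_atom)
    res_pos = {r: k for k, r in enumerate(residues)}
    rows = np.array([res_pos[r] for r in res_of_atom])

    frames = (
        trajectory.frames
        if frame_subset is None
        else [trajectory.frames[i] for i in frame_subset]
    )
    if not frames:
        raise AnalysisError("no frames in the requested partition")

    counts = np.zeros((residues.size, ion_idx.size), dtype=int)
    any_counts = np.zeros(residues.size, dtype=int)
    for frame in frames:
        prot = frame.coordinates[prot_idx]
        ions = frame.coordinates[ion_idx]
        delta = prot[:, None, :] - ions[None, :, :]
        delta = _min_image_delta(delta, frame.box)
        d = np.sqrt((delta**2).sum(axis=2))
        hit = d < d_cut  # strict
        # residue-level binarization: any atom of the residue within cutoff
        res_hit = np.zeros((residues.size, ion_idx.size), dtype=bool)
        np.logical_or.at(res_hit, rows, hit)
        counts += res_hit
        any_counts += res_hit.any(axis=1)
    return IonContactMap(
        residue_indices=residues,
        ion_labels=[top.atoms[i].name for i in ion_idx],
        counts=counts,
        any_ion_counts=any_counts,
        n_frames=len(frames),
        partition=partition,
    )


@dataclass
class IonTrack:
    """Per-frame z track of one ion with the leaflet boundaries."""

    ion_atom_index: int
    ion_label: str
    z: np.ndarray
    xyz: np.ndarray
    z_lower_boundary: np.ndarray  # per-frame lower-leaflet P COM z
    z_upper_boundary: np.ndarray
    entry_flags: np.ndarray  # bool per frame

    @property
    def entered(self) -> bool:
        return bool(self.entry_flags.any())


def ion_z_tracks(
    trajectory: Trajectory,
    ion_selection: Iterable[int],
    lipid_p_selection: Iterable[int] | None = None,
    pore_axis_xy: tuple[float, float] | None = None,
    lateral_envelope: float = 15.0,
) -> list[IonTrack]:
    """Track each ion's z against leaflet boundaries and flag pore entries.

    Leaflets are split at the P-marker z median each frame; the boundary is
    each leaflet's COM z.  An entry is flagged when the ion sits between
    the boundaries AND within ``lateral_envelope`` of the pore axis (the
    protein's xy COM when no axis is supplied).
    """
    top = trajectory.topology
    ion_idx = np.asarray(list(ion_selection), dtype=int)
    if lipid_p_selection is None:
        p_idx = np.array(
            [
                a.index
                for a in top.atoms
                if a.segment_class == "lipid" and a.name.strip().upper() == "P"
            ]
        )
    else:
        p_idx = np.asarray(list(lipid_p_selection), dtype=int)
    if p_idx.size == 0:
        raise AnalysisError("no lipid phosphorus markers in the trajectory")

    n = trajectory.n_frames
    lower = np.empty(n)
    upper = np.empty(n)
    axis = np.empty((n, 2))
    try:
        prot_idx = top.select(segment_class="protein")
    except SelectionError:
        prot_idx = None
    for f, frame in enumerate(trajectory.frames):
        pz = frame.coordinates[p_idx, 2]
        median = np.median(pz)
        lo_mask = pz <= median
        if lo_mask.all() or not lo_mask.any():
            raise AnalysisError("cannot split lipid markers into two leaflets")
        lower[f] = pz[lo_mask].mean()
        upper[f] = pz[~lo_mask].mean()
        if pore_axis_xy is not None:
            axis[f] = pore_axis_xy
        elif prot_idx is not None:
            axis[f] = frame.coordinates[prot_idx, :2].mean(axis=0)
        else:
            axis[f] = frame.box[:2] / 2.0

    tracks: list[IonTrack] = []
    for i in ion_idx:
        xyz = np.array([fr.coordinates[i] for fr in trajectory.frames])
        lateral = np.sqrt(((xyz[:, :2] - axis) ** 2).sum(axis=1))
        inside = (xyz[:, 2] > lower) & (xyz[:, 2] < upper)
        entry = inside & (lateral < lateral_envelope)
        tracks.append(
            IonTrack(
                ion_atom_index=int(i),
                ion_label=top.atoms[i].name,
                z=xyz[:, 2],
                xyz=xyz,
                z_lower_boundary=lower,
                z_upper_boundary=upper,
                entry_flags=entry,
            )
        )
    return tracks


def contact_map_difference(
    map_open: IonContactMap, map_closed: IonContactMap
) -> pd.DataFrame:
    """Residue-wise difference of per-frame contact rates (open − closed),
    sorted by decreasing |difference|."""
    if not np.array_equal(map_open.residue_indices, map_closed.residue_indices):
        raise AnalysisError("contact maps cover different residue sets")
    diff = map_open.frequencies - map_closed.frequencies
    df = pd.DataFrame(
        {
            "residue_index": map_open.residue_indices,
            "rate_open": map_open.frequencies,
            "rate_closed": map_closed.frequencies,
            "difference": diff,
        }
    )
    return df.reindex(
        df["difference"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
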