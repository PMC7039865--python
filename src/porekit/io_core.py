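"""Structure/trajectory I/O, vdW radius assignment and rigid-body superposition.

Coordinates are in Å everywhere.  The z axis is the membrane normal.  Frames
are 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    FormatError,
    SelectionError,
    TopologyError,
)

# Bondi-style van der Waals radii (Å); fallback configurable per call.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "SE": 1.90,
}
DEFAULT_FALLBACK_RADIUS = 1.70

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "MSE",
}
LIPID_RESIDUES = {
    "POPC", "POPE", "POPS", "POPG", "DPPC", "DOPC", "DMPC", "CHL1", "CHOL",
    "PC", "PE", "LIP",
}
ION_RESIDUES = {
    "CL", "CLA", "NA", "SOD", "K", "POT", "MG", "CA", "CAL", "ZN", "CL-",
    "NA+", "K+",
}
WATER_RESIDUES = {"HOH", "WAT", "TIP3", "TIP4", "SOL", "SPC", "H2O"}


def classify_segment(residue_name: str) -> str:
    """Infer the segment class (protein/lipid/ion/solvent/other) of a residue."""
    name = residue_name.strip().upper()
    if name in STANDARD_AMINO_ACIDS:
        return "protein"
    if name in LIPID_RESIDUES:
        return "lipid"
    if name in ION_RESIDUES:
        return "ion"
    if name in WATER_RESIDUES:
        return "solvent"
    return "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, vdW radius and residue membership."""

    index: int
    name: str
    element: str
    vdw_radius: float
    residue_index: int
    residue_name: str
    chain: str
    segment_class: str

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ConfigurationError(
                f"atom {self.index} ({self.name}): vdW radius must be > 0"
            )


class Topology:
    """Ordered atom list plus a derived residue table.

    A residue is identified by ``(residue_index, chain)``; atom order is
    stable across frames.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self._build_residue_table()

    def _build_residue_table(self) -> None:
        self.residues: list[dict] = []
        self._residue_of_atom = np.empty(len(self.atoms), dtype=int)
        current_key = None
        for atom in self.atoms:
            key = (atom.residue_index, atom.chain)
            if key != current_key:
                self.residues.append(
                    {
                        "residue_index": atom.residue_index,
                        "residue_name": atom.residue_name,
                        "chain": atom.chain,
                        "atom_start": atom.index,
                        "atom_stop": atom.index + 1,
                    }
                )
                current_key = key
            else:
                self.residues[-1]["atom_stop"] = atom.index + 1
            self._residue_of_atom[atom.index] = len(self.residues) - 1

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def residue_id_of_atom(self, atom_index: int) -> int:
        """Row of the residue table owning ``atom_index``."""
        return int(self._residue_of_atom[atom_index])

    def atoms_of_residue_row(self, row: int) -> np.ndarray:
        res = self.residues[row]
        return np.arange(res["atom_start"], res["atom_stop"])

    def select(
        self,
        residue_indices: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        segment_class: str | None = None,
        chains: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Atom indices matching all given filters (AND semantics).

        Raises :class:`SelectionError` naming the residues that matched
        nothing when ``residue_indices`` is given and some are absent.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_indices is not None:
            wanted = set(int(r) for r in residue_indices)
            res_ids = np.array([a.residue_index for a in self.atoms])
            mask &= np.isin(res_ids, list(wanted))
            present = {a.residue_index for a in self.atoms} & wanted
            missing = wanted - present
            if missing:
                raise SelectionError(
                    f"residues not found in topology: {sorted(missing)}"
                )
        if atom_names is not None:
            names = {n.strip().upper() for n in atom_names}
            mask &= np.array(
                [a.name.strip().upper() in names for a in self.atoms]
            )
        if segment_class is not None:
            mask &= np.array(
                [a.segment_class == segment_class for a in self.atoms]
            )
        if chains is not None:
            cset = set(chains)
            mask &= np.array([a.chain in cset for a in self.atoms])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError("selection matched no atoms")
        return idx

    def ca_indices(self, residue_indices: Iterable[int]) -> np.ndarray:
        """Cα atom indices of the given residues, in residue order."""
        return self.select(residue_indices=residue_indices, atom_names=["CA"])


@dataclass
class Frame:
    """One coordinate snapshot; box is orthorhombic (three lengths, Å)."""

    frame_index: int
    coordinates: np.ndarray
    box: np.ndarray = field(
        default_factory=lambda: np.array([999.0, 999.0, 999.0])
    )

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TopologyError("coordinates must be an (N, 3) array")
        if np.any(self.box <= 0):
            raise TopologyError("box lengths must be positive")


@dataclass
class Trajectory:
    """An ordered list of frames sharing one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        for fr in self.frames:
            if fr.coordinates.shape[0] != self.topology.n_atoms:
                raise TopologyError(
                    f"frame {fr.frame_index}: {fr.coordinates.shape[0]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, line_number: int) -> dict:
    try:
        return {
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "residue_name": line[17:21].strip(),
            "chain": line[21:22].strip() or "A",
            "residue_index": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
            "element": line[76:78].strip() if len(line) >= 77 else "",
        }
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record at line {line_number}: {exc}")


def _element_from_name(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    two = name[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "FE", "ZN", "SE"}:
        return two
    return name[0].upper()


def _resolve_radius(
    element: str,
    radius_table: Mapping[str, float],
    fallback: float | None,
) -> float:
    key = element.upper()
    if key in radius_table:
        return float(radius_table[key])
    if fallback is not None:
        return float(fallback)
    raise ConfigurationError(
        f"element {element!r} missing from radius table and no fallback given"
    )


def read_structure(
    path: str | Path,
    radius_table: Mapping[str, float] | None = None,
    fallback_radius: float | None = DEFAULT_FALLBACK_RADIUS,
) -> tuple[Topology, Frame]:
    """Read a PDB file: topology plus the first MODEL's coordinates.

    Altloc duplicates are reduced to the highest-occupancy record
    (tie → first encountered).  Segment classes are inferred from residue
    names.
    """
    table = dict(DEFAULT_VDW_RADII if radius_table is None else radius_table)
    raw: list[dict] = []
    box = np.array([999.0, 999.0, 999.0])
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError:
                    raise FormatError(f"bad CRYST1 record at line {line_number}")
            elif record in ("ATOM  ", "HETATM"):
                raw.append(_parse_atom_line(line, line_number))
            elif record.startswith("ENDMDL"):
                break  # topology from the first model only
    if not raw:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    # altloc filter: keep highest occupancy per atom identity
    best: dict[tuple, int] = {}
    for i, rec in enumerate(raw):
        key = (rec["residue_index"], rec["chain"], rec["residue_name"], rec["name"])
        if key not in best or rec["occupancy"] > raw[best[key]]["occupancy"]:
            best[key] = i
    keep = sorted(best.values())

    atoms: list[AtomRecord] = []
    coords = np.empty((len(keep), 3))
    for new_index, i in enumerate(keep):
        rec = raw[i]
        element = rec["element"] or _element_from_name(rec["name"])
        atoms.append(
            AtomRecord(
                index=new_index,
                name=rec["name"],
                element=element,
                vdw_radius=_resolve_radius(element, table, fallback_radius),
                residue_index=rec["residue_index"],
                residue_name=rec["residue_name"],
                chain=rec["chain"],
                segment_class=classify_segment(rec["residue_name"]),
            )
        )
        coords[new_index] = (rec["x"], rec["y"], rec["z"])
    return Topology(atoms), Frame(frame_index=0, coordinates=coords, box=box)


def read_trajectory(topology: Topology, path: str | Path) -> Trajectory:
    """Read a multi-model PDB or a binary DCD file against ``topology``."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        return _read_dcd(topology, path)
    return _read_multimodel_pdb(topology, path)


def _read_multimodel_pdb(topology: Topology, path: Path) -> Trajectory:
    frames: list[Frame] = []
    coords: list[list[float]] = []
    box = np.array([999.0, 999.0, 999.0])
    in_model = False
    saw_model_record = False
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "CRYST1":
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            elif record.startswith("MODEL"):
                in_model = True
                saw_model_record = True
                coords = []
            elif record in ("ATOM  ", "HETATM"):
                rec = _parse_atom_line(line, line_number)
                coords.append([rec["x"], rec["y"], rec["z"]])
            elif record.startswith("ENDMDL"):
                in_model = False
                _append_frame(frames, coords, topology, box, path)
                coords = []
    if coords:
        if in_model:
            raise FormatError(
                f"{path}: truncated frame after {len(frames)} complete frame(s)"
            )
        _append_frame(frames, coords, topology, box, path)
    if not frames and not saw_model_record:
        raise FormatError(f"{path}: no coordinate frames found")
    return Trajectory(topology=topology, frames=frames)


def _append_frame(frames, coords, topology, box, path) -> None:
    arr = np.array(coords)
    if arr.shape[0] != topology.n_atoms:
        raise TopologyError(
            f"{path}: frame {len(frames)} has {arr.shape[0]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    frames.append(Frame(frame_index=len(frames), coordinates=arr, box=box.copy()))


def _read_dcd(topology: Topology, path: Path) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    frames: list[Frame] = []
    reader = DCDReader(str(path))
    for i, ts in enumerate(reader):
        if ts.positions.shape[0] != topology.n_atoms:
            raise TopologyError(
                f"{path}: DCD has {ts.positions.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        box = np.array(ts.dimensions[:3]) if ts.dimensions is not None else None
        frames.append(
            Frame(
                frame_index=i,
                coordinates=np.array(ts.positions, dtype=float),
                box=box if box is not None and np.all(box > 0)
                else np.array([999.0, 999.0, 999.0]),
            )
        )
    reader.close()
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        box = trajectory.frames[0].box if trajectory.frames else None
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n"
            )
        for frame in trajectory.frames:
            fh.write(f"MODEL     {frame.frame_index + 1:4d}\n")
            for atom, xyz in zip(top.atoms, frame.coordinates):
                fh.write(_format_atom_line(atom, xyz))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _format_atom_line(
    atom: AtomRecord, xyz: np.ndarray, bfactor: float = 0.0
) -> str:
    record = "ATOM  " if atom.segment_class == "protein" else "HETATM"
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"{record}{(atom.index % 99999) + 1:5d} {name:<4s} "
        f"{atom.residue_name:<4s}{atom.chain:1s}"
        f"{atom.residue_index % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfactor:6.2f}"
        f"          {atom.element:>2s}\n"
    )


def write_spheres_pdb(
    spheres: Sequence[tuple[np.ndarray, float]], path: str | Path
) -> None:
    """Export tunnel spheres as HETATM pseudo-atoms, radius in the B-factor."""
    with open(path, "w") as fh:
        for i, (center, radius) in enumerate(spheres):
            fh.write(
                f"HETATM{(i % 99999) + 1:5d}  SPH TUN A{(i % 10000) + 1:4d}    "
                f"{center[0]:8.3f}{center[1]:8.3f}{center[2]:8.3f}"
                f"{1.0:6.2f}{radius:6.2f}           X\n"
            )
        fh.write("END\n")


def recenter_frame(frame: Frame, topology: Topology) -> Frame:
    """Re-image a frame so the protein COM sits at the box center.

    Protein atoms are shifted rigidly; all other atoms are wrapped back into
    the box by minimum image.  Analyses assume already-imaged frames; this
    utility repairs frames where the protein drifted across the boundary.
    """
    protein = topology.select(segment_class="protein")
    shift = frame.box / 2.0 - frame.coordinates[protein].mean(axis=0)
    moved = frame.coordinates + shift
    non_protein = np.setdiff1d(np.arange(topology.n_atoms), protein)
    moved[non_protein] = np.mod(moved[non_protein], frame.box)
    return Frame(frame_index=frame.frame_index, coordinates=moved, box=frame.box)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    """Optimal rigid-body fit: ``mobile @ rotation.T + translation ≈ reference``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    The returned rotation is always proper (det = +1).  Collinear/degenerate
    point sets fall back to a translation-only fit with ``degenerate=True``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3) and paired by index")
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    x = mobile - mob_center
    y = reference - ref_center

    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    rank = int(np.sum(s > 1e-9 * max(s[0], 1e-30)))
    if rank < 2:
        translation = ref_center - mob_center
        diff = mobile + translation - reference
        rmsd = float(np.sqrt((diff**2).sum() / mobile.shape[0]))
        return Superposition(np.eye(3), translation, rmsd, degenerate=True)

    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_center - rotation @ mob_center
    diff = mobile @ rotation.T + translation - reference
    rmsd = float(np.sqrt((diff**2).sum() / mobile.shape[0]))
    return Superposition(rotation, translation, rmsd)


def shared_residue_rmsd(
    top_a: Topology,
    frame_a: Frame,
    top_b: Topology,
    frame_b: Frame,
    atom_name: str = "CA",
) -> tuple[float, int]:
    """Cα RMSD over residues resolved in both structures, after superposition.

    Residues are matched by residue index (chains ignored when the two
    structures use different chain labels for the same polypeptide).
    Returns (rmsd, n_matched_residues).
    """
    def ca_map(top: Topology, frame: Frame) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        for atom in top.atoms:
            if (
                atom.name.strip().upper() == atom_name
                and atom.segment_class == "protein"
                and atom.residue_index not in out
            ):
                out[atom.residue_index] = frame.coordinates[atom.index]
        return out

    map_a = ca_map(top_a, frame_a)
    map_b = ca_map(top_b, frame_b)
    shared = sorted(set(map_a) & set(map_b))
    if len(shared) < 3:
        raise SelectionError("fewer than 3 shared residues with the given atom")
    coords_a = np.array([map_a[r] for r in shared])
    coords_b = np.array([map_b[r] for r in shared])
    fit = superpose(coords_a, coords_b)
    return fit.rmsd, len(shared)


def fetch_pdb(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry from RCSB (requires network access)."""
    import urllib.request

    dest = Path(dest_dir) / f"{pdb_id.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    urllib.request.urlretrieve(url, dest)
    return dest
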