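"""Ground-truth synthetic trajectories for testing the analysis pipeline.

The generators emulate, in idealized form, the ingredients of a
membrane-channel MD system: a pore whose radius profile along the membrane
normal is known analytically, lipid leaflets marked by phosphorus-like
atoms, ions performing reflecting random walks (optionally scripted through
waypoints to force known contacts), and Cα chains with a prescribed block
correlation structure.

All randomness flows through one seeded ``numpy.random.default_rng``;
identical specs and seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_core import AtomRecord, Frame, Topology, Trajectory

RadiusProfile = Callable[[float, int], float]


def constant_profile(radius: float) -> RadiusProfile:
    """Pore radius independent of z and frame."""
    return lambda z, frame: radius


def breathing_profile(
    baseline: Callable[[float], float], amplitude: float, period: int
) -> RadiusProfile:
    """Baseline z-profile plus a sinusoidal breathing term over frames."""
    return lambda z, frame: baseline(z) + amplitude * np.sin(
        2.0 * np.pi * frame / period
    )


def alternating_profile(
    baseline: Callable[[float], float], even_offset: float, odd_offset: float
) -> RadiusProfile:
    """Baseline profile shifted by one offset on even frames, another on odd."""
    return lambda z, frame: baseline(z) + (
        even_offset if frame % 2 == 0 else odd_offset
    )


def hourglass(
    z_mid: float, r_mouth: float, r_waist: float, half_width: float
) -> Callable[[float], float]:
    """Smooth hourglass z-profile: wide mouths, a narrow waist at ``z_mid``."""
    return lambda z: r_waist + (r_mouth - r_waist) * min(
        1.0, ((z - z_mid) / half_width) ** 2
    )


@dataclass
class ChannelSpec:
    """Parametric membrane-embedded channel built from rings of pseudo-atoms.

    Each z slice carries one ring of ``atoms_per_ring`` atoms centred on the
    z axis at ring radius ``radius_profile(z, frame) + atom_vdw``, so the
    maximal inscribed sphere on the axis at a slice plane has an exactly
    known radius (see :meth:`SyntheticChannel.true_radius`).
    """

    n_slices: int = 40
    slice_spacing: float = 1.0
    atoms_per_ring: int = 12
    radius_profile: RadiusProfile = field(
        default_factory=lambda: constant_profile(3.0)
    )
    atom_vdw: float = 1.5
    z_start: float = 50.0
    center_xy: tuple[float, float] = (40.0, 40.0)
    box: tuple[float, float, float] = (80.0, 80.0, 160.0)
    seed: int = 0

    def validate(self, n_frames: int) -> None:
        if self.atoms_per_ring < 6:
            raise ConfigurationError("atoms_per_ring must be ≥ 6")
        if self.n_slices < 2:
            raise ConfigurationError("need at least 2 slices")
        if self.slice_spacing <= 0 or self.atom_vdw <= 0:
            raise ConfigurationError("slice_spacing and atom_vdw must be > 0")
        for frame in range(n_frames):
            for z in self.slice_z():
                if self.radius_profile(z, frame) <= 0:
                    raise ConfigurationError(
                        f"radius_profile ≤ 0 at z={z}, frame={frame}"
                    )

    def slice_z(self) -> np.ndarray:
        return self.z_start + self.slice_spacing * np.arange(self.n_slices)


@dataclass
class SyntheticChannel:
    """A generated channel trajectory plus its analytic ground truth."""

    trajectory: Trajectory
    spec: ChannelSpec
    n_frames: int

    def ring_radius(self, z: float, frame: int) -> float:
        return self.spec.radius_profile(z, frame) + self.spec.atom_vdw

    def true_radius(self, z: float, frame: int) -> float:
        """Exact maximal-inscribed-sphere radius on the axis at height z.

        The nearest atom of the ring at height z_k lies at 3D distance
        sqrt((z - z_k)^2 + R_k^2) from the axis point, with R_k the ring
        radius; the inscribed radius is the minimum of those distances
        minus the atom vdW radius.
        """
        zs = self.spec.slice_z()
        rings = np.array([self.ring_radius(zk, frame) for zk in zs])
        dist = np.sqrt((z - zs) ** 2 + rings**2)
        return float(dist.min() - self.spec.atom_vdw)

    def true_min_slab_radius(
        self, frame: int, z_lower: float, z_upper: float, step: float = 0.25
    ) -> float:
        zs = np.arange(z_lower, z_upper + step / 2, step)
        return min(self.true_radius(z, frame) for z in zs)

    def open_frames(
        self, z_lower: float, z_upper: float, r_min: float = 1.8
    ) -> list[int]:
        """Frames whose true radius exceeds r_min everywhere in the slab."""
        return [
            f
            for f in range(self.n_frames)
            if self.true_min_slab_radius(f, z_lower, z_upper) > r_min
        ]


def make_channel_trajectory(spec: ChannelSpec, n_frames: int) -> SyntheticChannel:
    """Build a ring-stack channel; one residue per ring, atoms named C1..Cn."""
    spec.validate(n_frames)
    zs = spec.slice_z()
    cx, cy = spec.center_xy
    atoms: list[AtomRecord] = []
    index = 0
    for ring_id in range(spec.n_slices):
        for a in range(spec.atoms_per_ring):
            atoms.append(
                AtomRecord(
                    index=index,
                    name=f"C{a + 1}",
                    element="C",
                    vdw_radius=spec.atom_vdw,
                    residue_index=ring_id + 1,
                    residue_name="GLY",  # survives PDB round-trip as protein
                    chain="A",
                    segment_class="protein",
                )
            )
            index += 1
    topology = Topology(atoms)

    # deterministic per-ring phase offset so rings do not align
    phases = (np.arange(spec.n_slices) * 0.37) % (2 * np.pi)
    angles = 2 * np.pi * np.arange(spec.atoms_per_ring) / spec.atoms_per_ring

    frames: list[Frame] = []
    for f in range(n_frames):
        coords = np.empty((topology.n_atoms, 3))
        i = 0
        for ring_id, z in enumerate(zs):
            ring_r = spec.radius_profile(z, f) + spec.atom_vdw
            theta = angles + phases[ring_id]
            n = spec.atoms_per_ring
            coords[i : i + n, 0] = cx + ring_r * np.cos(theta)
            coords[i : i + n, 1] = cy + ring_r * np.sin(theta)
            coords[i : i + n, 2] = z
            i += n
        frames.append(Frame(frame_index=f, coordinates=coords, box=np.array(spec.box)))
    return SyntheticChannel(
        trajectory=Trajectory(topology=topology, frames=frames),
        spec=spec,
        n_frames=n_frames,
    )


def make_membrane_markers(
    z_lower_leaflet: float,
    z_upper_leaflet: float,
    n_per_leaflet: int,
    seed: int,
    xy_extent: tuple[float, float] = (80.0, 80.0),
    z_jitter: float = 1.0,
    first_atom_index: int = 0,
    first_residue_index: int = 5001,
) -> tuple[list[AtomRecord], np.ndarray]:
    """Phosphorus-like leaflet markers; each leaflet's COM z is exact.

    Returns an atom-record fragment plus coordinates, ready to be merged
    into a larger topology with :func:`combine_fragments`.
    """
    if z_lower_leaflet >= z_upper_leaflet:
        raise ConfigurationError("z_lower_leaflet must be < z_upper_leaflet")
    if n_per_leaflet < 1:
        raise ConfigurationError("n_per_leaflet must be ≥ 1")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    coords = np.empty((2 * n_per_leaflet, 3))
    for leaflet, z_target in enumerate((z_lower_leaflet, z_upper_leaflet)):
        xy = rng.uniform(0, 1, size=(n_per_leaflet, 2)) * np.array(xy_extent)
        dz = rng.normal(0.0, z_jitter, size=n_per_leaflet)
        dz -= dz.mean()  # COM z exactly at target
        start = leaflet * n_per_leaflet
        coords[start : start + n_per_leaflet, :2] = xy
        coords[start : start + n_per_leaflet, 2] = z_target + dz
        for i in range(n_per_leaflet):
            atoms.append(
                AtomRecord(
                    index=first_atom_index + start + i,
                    name="P",
                    element="P",
                    vdw_radius=1.8,
                    residue_index=first_residue_index + start + i,
                    residue_name="POPC",
                    chain="L",
                    segment_class="lipid",
                )
            )
    return atoms, coords


@dataclass
class IonSpec:
    """Reflecting-random-walk ions, optionally scripted through waypoints.

    ``waypoints`` maps an ion id (0-based) to a list of
    ``(frame, (x, y, z))`` entries; at those frames the ion sits exactly at
    the stated position, giving exact ground truth for contact tests.
    """

    n_ions: int = 4
    step_sigma: float = 1.5
    axial_bias: float = 0.0
    reflecting_box: tuple[float, float, float] = (80.0, 80.0, 160.0)
    species: str = "CL"
    seed: int = 0
    waypoints: dict[int, list[tuple[int, tuple[float, float, float]]]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        if self.step_sigma <= 0:
            raise ConfigurationError("step_sigma must be > 0")
        if self.n_ions < 0:
            raise ConfigurationError("n_ions must be ≥ 0")


def make_ion_tracks(
    spec: IonSpec,
    n_frames: int,
    first_atom_index: int = 0,
    first_residue_index: int = 9001,
) -> tuple[list[AtomRecord], np.ndarray, pd.DataFrame]:
    """Generate ion tracks; returns (atoms, coords[frame, ion, 3], truth table).

    The truth table has one row per (ion, frame) with the exact position and
    a flag marking scripted waypoint frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = np.array(spec.reflecting_box)
    coords = np.empty((n_frames, spec.n_ions, 3))
    scripted = np.zeros((n_frames, spec.n_ions), dtype=bool)
    for ion in range(spec.n_ions):
        pos = rng.uniform(0.1, 0.9, size=3) * box
        wp = dict(spec.waypoints.get(ion, []))
        for f in range(n_frames):
            if f in wp:
                pos = np.array(wp[f], dtype=float)
                scripted[f, ion] = True
            elif f > 0:
                step = rng.normal(0.0, spec.step_sigma, size=3)
                step[2] += spec.axial_bias
                pos = pos + step
                # reflect at the box faces
                for k in range(3):
                    if pos[k] < 0:
                        pos[k] = -pos[k]
                    if pos[k] > box[k]:
                        pos[k] = 2 * box[k] - pos[k]
                    pos[k] = np.clip(pos[k], 0, box[k])
            coords[f, ion] = pos

    element = spec.species.upper()
    atoms = [
        AtomRecord(
            index=first_atom_index + i,
            name=element,
            element=element,
            vdw_radius=1.81 if element == "CL" else 2.75,
            residue_index=first_residue_index + i,
            residue_name=element,
            chain="I",
            segment_class="ion",
        )
        for i in range(spec.n_ions)
    ]
    rows = [
        {
            "ion": ion,
            "frame": f,
            "x": coords[f, ion, 0],
            "y": coords[f, ion, 1],
            "z": coords[f, ion, 2],
            "scripted": bool(scripted[f, ion]),
        }
        for ion in range(spec.n_ions)
        for f in range(n_frames)
    ]
    truth = pd.DataFrame(
        rows, columns=["ion", "frame", "x", "y", "z", "scripted"]
    )
    return atoms, coords, truth


def combine_fragments(
    fragments: Sequence[tuple[list[AtomRecord], np.ndarray]],
    n_frames: int,
    box: tuple[float, float, float],
    per_frame_coords: dict[int, np.ndarray] | None = None,
) -> Trajectory:
    """Merge static fragments plus optional per-frame coordinate blocks.

    ``fragments`` are (atoms, coords) pairs whose coordinates repeat in every
    frame unless overridden by ``per_frame_coords[fragment_id]`` of shape
    (n_frames, n_atoms, 3).  Atom indices are renumbered contiguously.
    """
    atoms: list[AtomRecord] = []
    static_blocks: list[np.ndarray] = []
    offsets: list[int] = []
    index = 0
    for frag_atoms, frag_coords in fragments:
        offsets.append(index)
        for a in frag_atoms:
            atoms.append(
                AtomRecord(
                    index=index,
                    name=a.name,
                    element=a.element,
                    vdw_radius=a.vdw_radius,
                    residue_index=a.residue_index,
                    residue_name=a.residue_name,
                    chain=a.chain,
                    segment_class=a.segment_class,
                )
            )
            index += 1
        static_blocks.append(np.atleast_2d(frag_coords))
    topology = Topology(atoms)
    frames: list[Frame] = []
    for f in range(n_frames):
        parts = []
        for frag_id, block in enumerate(static_blocks):
            if per_frame_coords is not None and frag_id in per_frame_coords:
                parts.append(per_frame_coords[frag_id][f])
            else:
                parts.append(block)
        frames.append(
            Frame(frame_index=f, coordinates=np.vstack(parts), box=np.array(box))
        )
    return Trajectory(topology=topology, frames=frames)


def make_demo_system(
    seed: int, n_frames: int = 12
) -> tuple[Trajectory, dict]:
    """Bundled demo: breathing channel + Cα chain + leaflet markers + ions.

    The channel alternates between a 1.7 Å (even frames) and 2.2 Å (odd
    frames) pore, so the ground-truth open set is the odd frames.  A 16-
    residue correlated Cα chain (two 8-residue blocks) sits away from the
    channel for the network stage, and one chloride is scripted through the
    membrane slab.  Returns (trajectory, ground_truth dict).
    """
    channel_spec = ChannelSpec(
        radius_profile=alternating_profile(lambda z: 0.0, 1.7, 2.2),
        n_slices=30,
        seed=seed,
    )
    channel = make_channel_trajectory(channel_spec, n_frames)
    channel_coords = np.stack(
        [f.coordinates for f in channel.trajectory.frames]
    )

    markers, marker_coords = make_membrane_markers(
        55.0, 85.0, 40, seed=seed + 1
    )

    chain_spec = CorrelatedMotionSpec(
        block_structure=[(8, 0.95), (8, 0.95)],
        n_frames=n_frames,
        noise_sigma=0.3,
        seed=seed + 2,
    )
    chain = make_correlated_trajectory(chain_spec)
    chain_coords = np.stack([f.coordinates for f in chain.frames])
    chain_coords[:, :, 1] = 10.0  # park the chain away from the pore
    chain_coords[:, :, 2] = 20.0
    chain_coords[:, :, 0] += 10.0
    chain_atoms = [
        AtomRecord(
            index=a.index,
            name="CA",
            element="C",
            vdw_radius=1.7,
            residue_index=100 + a.residue_index,  # rings hold 1..30
            residue_name="ALA",
            chain="C",
            segment_class="protein",
        )
        for a in chain.topology.atoms
    ]

    ion_spec = IonSpec(
        n_ions=3,
        seed=seed + 3,
        waypoints={0: [(k, (40.0, 40.0, 50.0 + 3.0 * k)) for k in range(2, 10)]},
    )
    ion_atoms, ion_coords, ion_truth = make_ion_tracks(ion_spec, n_frames)

    trajectory = combine_fragments(
        [
            (channel.trajectory.topology.atoms, channel_coords[0]),
            (chain_atoms, chain_coords[0]),
            (markers, marker_coords),
            (ion_atoms, ion_coords[0]),
        ],
        n_frames,
        channel_spec.box,
        per_frame_coords={0: channel_coords, 1: chain_coords, 3: ion_coords},
    )
    truth = {
        "open_frames": channel.open_frames(55.0, 75.0, r_min=1.8),
        "ion_truth": ion_truth,
        "chain_residues": [100 + a.residue_index for a in chain.topology.atoms],
        "channel": channel,
    }
    return trajectory, truth


@dataclass
class CorrelatedMotionSpec:
    """Cα chain whose displacement correlations follow a block design.

    ``block_structure`` lists (n_residues_in_block, rho) pairs; residues in
    one block share a latent displacement with weight sqrt(rho), making the
    pairwise displacement correlation within the block equal rho and ≈ 0
    across blocks.
    """

    block_structure: list[tuple[int, float]] = field(
        default_factory=lambda: [(10, 0.9), (10, 0.9)]
    )
    n_frames: int = 2000
    noise_sigma: float = 0.5
    spacing: float = 3.8
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return sum(n for n, _ in self.block_structure)

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames for correlations")
        for n, rho in self.block_structure:
            if not (0.0 < rho <= 1.0):
                raise ConfigurationError(f"block correlation {rho} outside (0, 1]")
            if n < 1:
                raise ConfigurationError("empty block")


def make_correlated_trajectory(spec: CorrelatedMotionSpec) -> Trajectory:
    """Cα-only chain (3.8 Å spacing) with block-correlated displacements."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    base = np.zeros((n_res, 3))
    base[:, 0] = spec.spacing * np.arange(n_res)
    base[:, 1] = 40.0
    base[:, 2] = 40.0

    atoms = [
        AtomRecord(
            index=i,
            name="CA",
            element="C",
            vdw_radius=1.7,
            residue_index=i + 1,
            residue_name="ALA",
            chain="A",
            segment_class="protein",
        )
        for i in range(n_res)
    ]
    topology = Topology(atoms)

    disp = np.empty((spec.n_frames, n_res, 3))
    start = 0
    for n_block, rho in spec.block_structure:
        latent = rng.normal(0.0, 1.0, size=(spec.n_frames, 1, 3))
        own = rng.normal(0.0, 1.0, size=(spec.n_frames, n_block, 3))
        disp[:, start : start + n_block, :] = spec.noise_sigma * (
            np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * own
        )
        start += n_block

    frames = [
        Frame(
            frame_index=f,
            coordinates=base + disp[f],
            box=np.array([max(200.0, spec.spacing * n_res + 80), 80.0, 80.0]),
        )
        for f in range(spec.n_frames)
    ]
    return Trajectory(topology=topology, frames=frames)
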