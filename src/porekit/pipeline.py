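"""End-to-end pipeline: profile → tunnels → stats → contacts → network.

The configuration is a plain mapping (parsed from YAML by the CLI); every
selection and threshold is validated up front so a bad config fails before
any computation starts.  All tabular outputs are TSV with ``#`` header
comments recording the parameters actually used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import channel_stats, ion_contacts, network_analysis, pore_profile
from . import tunnel_search
from .exceptions import AnalysisError, ConfigurationError, SelectionError
from .io_core import Topology, Trajectory, read_structure, read_trajectory


@dataclass
class PipelineConfig:
    structure: str
    trajectory: str
    output_dir: str = "porekit_out"
    seed: int = 0
    # selections
    slab_lower_residues: list[int] | None = None
    slab_upper_residues: list[int] | None = None
    slab_z: tuple[float, float] | None = None  # explicit alternative
    seed_residues: list[int] | None = None
    seed_point: tuple[float, float, float] | None = None
    tm_residues: list[int] | None = None
    sources: list[int] = field(default_factory=list)
    sinks: list[int] = field(default_factory=list)
    # thresholds (defaults follow the published protocol)
    r_min: float = 1.8
    contact_distance: float = 3.0
    ion_contact: float = 4.0
    clustering_threshold: float = 4.5
    shell_radius: float = 6.0
    shell_depth: float = 3.0
    grid_step: float = 0.8
    slice_step: float = 0.5
    include_lipids: bool = False
    path_tolerance: float = 0.5
    correlation_window: tuple[int, int] | None = None
    contact_cut: float = 4.5
    contact_fraction: float = 0.75

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "PipelineConfig":
        flat: dict[str, Any] = {}
        for section in ("selections", "thresholds"):
            flat.update(data.get(section) or {})
        flat.update(
            {k: v for k, v in data.items() if k not in ("selections", "thresholds")}
        )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate_thresholds(self) -> None:
        for name in (
            "r_min", "contact_distance", "ion_contact", "clustering_threshold",
            "shell_radius", "shell_depth", "grid_step", "slice_step",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be > 0")


def _write_tsv(df: pd.DataFrame, path: Path, header_comments: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def preflight(config: PipelineConfig, trajectory: Trajectory) -> None:
    """Resolve every selection and threshold before stage 1 runs."""
    config.validate_thresholds()
    top = trajectory.topology
    if config.slab_z is None:
        if not (config.slab_lower_residues and config.slab_upper_residues):
            raise ConfigurationError(
                "either slab_z or both slab anchor selections are required"
            )
        top.ca_indices(config.slab_lower_residues)
        top.ca_indices(config.slab_upper_residues)
    if config.seed_point is None:
        if not config.seed_residues or len(config.seed_residues) != 2:
            raise ConfigurationError(
                "either seed_point or a pair of seed_residues is required"
            )
        top.ca_indices(config.seed_residues)
    if config.tm_residues is not None:
        top.select(residue_indices=config.tm_residues)
    for res in list(config.sources) + list(config.sinks):
        top.select(residue_indices=[res])


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order and write the report bundle.

    Returns a summary dict: frame counts, the open-frame set, cluster count
    and the top lining residues.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    topology, first = read_structure(config.structure)
    trajectory = read_trajectory(topology, config.trajectory)
    preflight(config, trajectory)

    # stage 1: pore profile screen
    if config.slab_z is not None:
        slab = pore_profile.MembraneSlab(*config.slab_z)
    else:
        slab = pore_profile.compute_slab(
            trajectory.frames[0], topology,
            config.slab_lower_residues, config.slab_upper_residues,
        )
    if config.seed_point is not None:
        seed = np.asarray(config.seed_point, dtype=float)
    else:
        seed = tunnel_search.seed_point(
            trajectory.frames[0], topology, config.seed_residues
        )

    profiles = []
    stage1_rows = []
    for frame in trajectory.frames:
        prof = pore_profile.profile_pore(
            frame, topology, slab, tuple(seed),
            slice_step=config.slice_step, include_lipids=config.include_lipids,
        )
        profiles.append(prof)
        stage1_rows.append(
            {
                "frame": frame.frame_index + 1,  # 1-based in reports
                "min_radius_in_slab": prof.min_radius_in_slab,
                "open": pore_profile.classify_open(prof, slab, config.r_min),
            }
        )
    stage1 = pd.DataFrame(stage1_rows)
    _write_tsv(
        stage1, out / "stage1_open_verdicts.tsv",
        [f"r_min={config.r_min} slice_step={config.slice_step} "
         f"slab=({slab.z_lower:.3f},{slab.z_upper:.3f}) "
         f"include_lipids={config.include_lipids}"],
    )

    # stage 2: tunnel search on stage-1 open frames
    stage1_open = [int(f) - 1 for f in stage1.loc[stage1["open"], "frame"]]
    per_frame: dict[int, list[tunnel_search.Tunnel]] = {}
    tunnel_rows = []
    for f in stage1_open:
        try:
            tunnels = tunnel_search.search_tunnels(
                trajectory.frames[f], topology, seed,
                cutoff_radius=config.r_min, shell_radius=config.shell_radius,
                shell_depth=config.shell_depth, grid_step=config.grid_step,
                tm_selection=config.tm_residues,
                clustering_threshold=config.clustering_threshold,
            )
        except AnalysisError:
            tunnels = []  # e.g. seed buried in this frame; no tunnels
        tunnel_search.classify_tunnels(tunnels, slab)
        per_frame[f] = tunnels
        for t in tunnels:
            tunnel_rows.append(
                {
                    "frame": f + 1,
                    "endpoint": t.endpoint,
                    "length": t.length,
                    "bottleneck": t.bottleneck_radius,
                    "cost": t.cost,
                    "n_members": t.n_members,
                }
            )
    open_confs = tunnel_search.select_open_conformations(per_frame)
    _write_tsv(
        pd.DataFrame(
            tunnel_rows,
            columns=["frame", "endpoint", "length", "bottleneck", "cost", "n_members"],
        ),
        out / "stage2_tunnels.tsv",
        [f"cutoff={config.r_min} shell={config.shell_radius}/{config.shell_depth} "
         f"grid_step={config.grid_step} clustering={config.clustering_threshold}"],
    )

    summary: dict[str, Any] = {
        "n_frames": trajectory.n_frames,
        "n_stage1_open": len(stage1_open),
        "n_open": len(open_confs),
        "open_frames": [oc.frame_index + 1 for oc in open_confs],
    }

    # stage 3: channel statistics
    if open_confs:
        lining = channel_stats.lining_frequency(
            open_confs, trajectory, config.contact_distance
        )
        _write_tsv(lining, out / "lining_residues.tsv",
                   [f"contact_distance={config.contact_distance} normalization=max"])
        clusters, _ = channel_stats.cluster_channels(
            open_confs, trajectory, config.clustering_threshold,
            config.contact_distance,
        )
        profile_z = channel_stats.radius_profile_z(open_confs)
        _write_tsv(profile_z, out / "radius_profile_z.tsv", ["bin_width=1.0"])
        top_lining = lining.sort_values(
            ["raw_count", "residue_index"], ascending=[False, True]
        ).head(10)
        summary["n_clusters"] = len(clusters)
        summary["top_lining_residues"] = [
            int(r) for r in top_lining["residue_index"]
        ]
    else:
        summary["n_clusters"] = 0
        summary["top_lining_residues"] = []

    # stage 4: ion contacts
    ion_idx = [a.index for a in topology.atoms if a.segment_class == "ion"]
    if ion_idx:
        cmap = ion_contacts.contact_map(
            trajectory, ion_idx, d_cut=config.ion_contact
        )
        _write_tsv(cmap.to_frame(), out / "ion_contacts.tsv",
                   [f"d_cut={config.ion_contact} partition=all"])
        has_p = any(
            a.segment_class == "lipid" and a.name.strip().upper() == "P"
            for a in topology.atoms
        )
        if has_p:
            tracks = ion_contacts.ion_z_tracks(trajectory, ion_idx)
            track_rows = [
                {
                    "ion": tr.ion_atom_index,
                    "frame": f + 1,
                    "z": tr.z[f],
                    "z_lower": tr.z_lower_boundary[f],
                    "z_upper": tr.z_upper_boundary[f],
                    "entry": bool(tr.entry_flags[f]),
                }
                for tr in tracks
                for f in range(len(tr.z))
            ]
            _write_tsv(pd.DataFrame(track_rows), out / "ion_tracks.tsv",
                       ["boundaries = per-leaflet P COM z"])
            summary["n_ion_entries"] = int(
                sum(tr.entry_flags.sum() for tr in tracks)
            )

    # stage 5: network analysis (needs Cα atoms and enough frames)
    has_ca = any(a.name.strip().upper() == "CA" for a in topology.atoms)
    if has_ca and trajectory.n_frames >= 10 and config.sources and config.sinks:
        C, resids = network_analysis.correlation_matrix(
            trajectory, config.correlation_window
        )
        net = network_analysis.build_network(
            C, resids, trajectory, config.correlation_window,
            config.contact_cut, config.contact_fraction,
        )
        table = network_analysis.coupling_table(
            net, config.sources, config.sinks, config.path_tolerance
        )
        _write_tsv(table, out / "coupling_table.tsv",
                   [f"tolerance={config.path_tolerance} "
                    f"contact_cut={config.contact_cut} "
                    f"contact_fraction={config.contact_fraction}"])
        summary["strongest_coupling"] = {
            "source": int(table.iloc[0]["source"]),
            "sink": int(table.iloc[0]["sink"]),
            "n_paths": int(table.iloc[0]["n_paths"]),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
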