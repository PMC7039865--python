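# porekit

Detecting and characterizing transient open states of membrane ion channels
in molecular-dynamics trajectories.

Cryo-EM structures of channels such as CFTR, the chloride channel mutated in
cystic fibrosis, are mostly captured in closed or near-closed conformations;
the conducting state appears only as rare, short-lived excursions in MD
simulations. Finding those frames and describing the permeation pathway
requires a chain of geometric and statistical analyses. `porekit`
implements that chain as a reusable library plus CLI:

1. **Pore profiling** — for each frame, the maximal inscribed sphere radius
   `r(c) = min_i(|c − a_i| − vdW_i)` is maximized slice by slice along the
   membrane normal. A frame is *open* when `r > 1.8 Å` (the chloride ionic
   radius) at every slice of the transmembrane slab, the slab being defined
   by the centers of mass of Cα anchor groups at the two lipid head-group
   levels.
2. **Tunnel search** — a grid-based shortest-path search from an interior
   seed point with edge cost `length / r_mid²`, cutoff radius 1.8 Å, shell
   radius/depth 6 Å / 3 Å, and tunnel de-duplication at 4.5 Å divergence.
   Frames with simultaneously open intracellular *and* extracellular routes
   are the open conformations; the lowest-cost pair is the putative pathway.
3. **Channel statistics** — pore-lining residues (any atom closer than
   3.0 Å to a tunnel sphere surface), their frequencies over the open
   frames, Ward clustering of open channels on lining-residue coordinates,
   and the mean radius-vs-z channel profile.
4. **Ion contacts** — residue–ion contact maps (`d < 4 Å`, counted once per
   residue per frame), per-ion z-tracks against the leaflet phosphorus COM
   boundaries, and open-vs-closed contact difference maps.
5. **Network analysis** — dynamical cross-correlation of Cα motions,
   a contact-filtered graph with edge weights `w = −ln|C_ij|`, and exact
   enumeration of optimal and suboptimal paths between source and sink
   residues; the path count measures allosteric coupling strength.
6. **Well-tempered metadynamics** — a self-contained biased-dynamics engine
   (overdamped Langevin on analytic potentials) with a distance collective
   variable `s = |r_ion − r_COM|`, half-harmonic walls (5–20 Å), a
   three-point leaflet-COM angle restraint (< 80°), Gaussian hills with the
   well-tempered height schedule, and free-energy reconstruction
   `F(s) = −(γ/(γ−1))·V(s)` plus reweighted 2D projections.

A synthetic-data module generates membrane-channel trajectories with
*analytically known* ground truth (ring-stack pores, scripted ion tracks,
block-correlated residue motions), so every stage is tested against
independent oracles without any MD output.

## Worked example

```bash
porekit generate --out demo --seed 7     # synthetic demo system + config
porekit run --config demo/demo_config.yaml
```

prints

```json
{
  "n_frames": 12,
  "n_stage1_open": 6,
  "n_open": 6,
  "open_frames": [2, 4, 6, 8, 10, 12],
  "n_clusters": 1,
  "top_lining_residues": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
  "n_ion_entries": 10,
  "strongest_coupling": {"source": 103, "sink": 107, "n_paths": 20}
}
```

The demo channel breathes between a 1.7 Å pore (even frames, closed: below
the chloride radius) and a 2.2 Å pore (odd frames, open); the pipeline
recovers exactly the six open frames (reported 1-based). All open channels
belong to one cluster, the pore is lined by the ring residues 1–30 nearest
the axis, the scripted chloride produces 10 membrane-entry events, and the
strongest allosteric coupling is found inside the correlated residue block
(residues 103→107 of the test chain, 20 near-optimal paths).

The metadynamics engine runs on an analytic double well:

```bash
porekit metad --seed 7 --n-steps 200000 --out metad_demo
# hills=400 estimated_barrier=13.15 kJ/mol
```

against a true barrier of 12.89 kJ/mol (5 k_BT at 310 K).

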