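# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate conventions

Coordinates and thresholds are in Å throughout; the z axis is the membrane
normal with z = 0 at the bottom of the simulation box. Boxes are
orthorhombic. Frames are 0-based internally and 1-based in written reports.
Analyses assume frames are already wrapped/imaged with the protein whole;
`io_core.recenter_frame` repairs frames where the protein drifted across a
boundary. Van der Waals radii come from a bundled Bondi-style element table
(fallback 1.70 Å, both overridable) — pore geometry depends directly on
this choice, so the table is part of the configuration surface.

## Pore profiling (stage 1)

The pore radius at height z is the maximal clearance
`r(c) = min_i(|c − a_i| − vdW_i)` over in-plane centers `c = (cx, cy, z)`.
The profiler walks slices (default step 0.5 Å) outward from the slice
nearest the seed point, starting each slice's optimization from the
previous slice's optimum so the center tracks a curved pore. The optimizer
is a deterministic compass pattern search run from five starts (previous
center plus four ±1 Å jitters), with halving steps down to 10⁻³ Å; all
candidate points of an iteration are evaluated in one batched KD-tree
query (one tree per unique vdW radius, which keeps mixed-radius clearances
exact). Pattern search was chosen over simplex methods because the
objective is a min of cone functions — piecewise smooth with ridges — and
axis-wise polling with step halving is robust there and fully
deterministic. Slices whose optimum exceeds the 10 Å cap are flagged
"unbounded" (pore merged with bulk solvent) and reported at the cap.

A frame is open when every slab slice radius strictly exceeds r_min
(default 1.8 Å, the chloride ionic radius); a pore of exactly 1.8 Å is
closed. The slab is the z interval between the COM of two Cα anchor
groups at the intracellular and extracellular head-group levels; anchors
are user configuration because residue numbering is system-specific.
Pore-bounding atoms are protein by default; an `include_lipids` flag adds
lipid atoms, which matters when lipid tails line a membrane-facing pore
opening — results change intentionally.

## Tunnel search (stage 2)

Stage 2 is stricter than stage 1: it requires a continuous route from an
interior seed (midpoint of two Cα atoms) to both membrane faces. A regular
grid (default 0.8 Å) over the transmembrane atom selection carries the
clearance field; nodes below the 1.8 Å cutoff are blocked. Bulk solvent is
where the clearance reaches the shell radius (6 Å, the probe that defines
the molecular surface); exit nodes are interior nodes within shell depth
(3 Å) of bulk, i.e. the surface layer eroded inward. Bulk nodes are not
traversable — a tunnel terminates at the surface instead of wrapping
around the protein through solvent. Paths are found by Dijkstra on the
26-connected free grid with edge cost `length / r_mid²` (clearance at the
edge midpoint); the inverse-square throughput cost penalizes long, narrow
segments, and the exponent is configurable because the upstream tools
only name, not define, their cost. One candidate path is kept per local
cost minimum on the exit layer, and candidates are merged into tunnel
families when their symmetrized mean nearest-point divergence is below
4.5 Å. Accuracy of bottleneck radii is bounded by the grid step.

Endpoints: a tunnel ending below the slab is intracellular, above it
extracellular, inside it lateral (membrane-facing; excluded from pairing).
A frame is an open conformation when it has at least one intracellular and
one extracellular tunnel; the selected pair minimizes summed cost, ties
broken toward the larger combined bottleneck, then lower tunnel index.

## Channel statistics

A residue lines a tunnel when any of its heavy atoms is strictly closer
than 3.0 Å to a sphere *surface* (center distance minus sphere radius).
Lining frequencies are counts over open frames normalized to the maximum
count (so the top residue plots at 1.0); normalization by the number of
open frames is available since either convention appears in practice.
Open-frame clustering uses the pairwise RMSD over the atoms of the union
of the two frames' lining sets (all atoms exist in all frames; only the
lining label differs), Ward linkage, dendrogram cut at 4.5 Å by default.
Frames must be pre-aligned to a common reference; the distance is computed
on coordinates as-is. The radius-vs-z profile pools the spheres of all
selected pairs and averages radii in 1.0 Å z bins (bin width configurable;
the choice trades resolution against per-bin counts).

## Ion contacts

A residue–ion contact is strict `d < 4.0 Å` between any protein atom of
the residue and the ion, counted once per residue per frame (residue-level
binarization, matching how per-amino-acid contact maps are read).
Frequencies are per-frame rates (count / frames in the partition), which
makes open-frame and closed-frame maps directly comparable and their
difference a rate difference. Minimum-image distances are used when a box
is present. Ion z-tracks record each frame's leaflet boundaries as the COM
z of the phosphorus markers in each leaflet (split at the P z median); an
*entry* is flagged when the ion sits strictly between the boundaries and
within a lateral envelope (default 15 Å) of the pore axis — the envelope
is a documented stand-in for "inside the protein", which has no unique
geometric definition.

## Network analysis

The dynamical cross-correlation is
`C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` over mean-free Cα
displacement vectors, after superposing every frame onto the window-mean
structure (two alignment passes); rigid-body motion therefore does not
register, and residues left with zero variance are flagged and zeroed.
Edges connect residues in persistent contact (any heavy-atom pair within
4.5 Å in ≥ 75 % of window frames; both exposed in config) with weight
`w = −ln|C_ij|`: perfectly (anti-)correlated neighbours cost 0,
uncorrelated ones are effectively disconnected. Anti-correlation counts as
coupling by design.

Suboptimal paths are *all* simple paths with total weight within a
user tolerance of the optimal path, enumerated exactly by depth-first
search pruned with the exact Dijkstra distance-to-sink lower bound
(admissible, so no qualifying path is missed). Weights are kept as real
numbers with a real tolerance rather than integer-scaled weights; absolute
counts are therefore comparable only within one run, and rankings are the
robust output. One subtlety the tests encode: with a shared tolerance, a
pair placed deep inside two different blocks can collect *more* simple
paths than a within-block pair because counts multiply across the
connecting bridge; the meaningful weak-coupling contrast is the spatially
adjacent pair straddling the block boundary, and that is the designed
ranking (within-block ≫ straddling) the test suite and acceptance script
check.

## Well-tempered metadynamics

The engine biases the distance CV `s = |r_ion − r_COM|` with unit-mass
anchor COM (the anchors are Cα atoms, so mass weighting is immaterial).
Gaussian hills `h_t·exp(−(s−s_k)²/2σ²)` are deposited every `stride` steps
with the well-tempered schedule `h_t = h0·exp(−V(s_t)/k_B ΔT)`,
`ΔT = (γ−1)T`. Defaults — h0 = 1.2 kJ/mol, σ = 0.35 Å, stride = 500,
γ = 10, T = 310 K — are conventional starting values for a distance CV of
this range; all are configurable. The CV is confined by half-harmonic
walls `E = k·Δ²` outside [5, 20] Å, and the ion is kept in the region of
interest by a three-point angle restraint: the angle at the
extracellular-leaflet P COM (vertex, first of the three listed points),
between the rays to the intracellular-leaflet COM and to the ion, is
penalized above 80°. The vertex assignment follows the stated point order;
the alternative vertex is selectable. All restraint and bias forces are
exact gradients, verified against finite differences in the tests.

Dynamics are overdamped Langevin,
`x ← x + (dt/ξ)F + √(2k_BT dt/ξ)·η`, on analytic potentials with fixed
anchors and leaflet COMs — the engine exercises the bias/restraint logic,
not all-atom forces. The 1D free energy is `F(s) = −(γ/(γ−1))·V(s)`; by
default the estimator averages the zero-aligned free-energy snapshots over
the second half of the deposition history, which damps the raggedness of
the instantaneous bias (the final-bias-only estimator is available). 2D
projections onto CV component pairs reweight samples with the final bias,
`w_t = exp(V(s_t)/k_BT)`, valid after convergence; empty cells are masked.
On the reference task — a 5 k_BT double well between 8 and 14 Å, exact
answer from the per-bin Boltzmann integral — 600 000 steps at dt = 0.005
and friction 1 recover the barrier to within ~10 % across seeds (measured
1–10 % over ten seeds), against the 20 % consistency target.

## Synthetic data: what it does and does not emulate

The channel generator stacks rings of pseudo-atoms on the z axis; ring
radius = target pore radius + atom vdW, so the true inscribed radius on
the axis is analytic: `min_k √((z−z_k)² + R_k²) − vdW`, exact at slice
planes. This makes the profiler, the open/closed screen and the gating
stage testable against construction rather than against the code itself.
Membrane leaflets are phosphorus-like markers with exactly centered COM z;
ions are reflecting random walks with optional scripted waypoints (exact
contact ground truth); correlated motion comes from a shared-latent block
model on a 3.8 Å Cα chain, giving within-block displacement correlation ρ
and ≈ 0 across blocks.

None of this emulates real MD: no thermal protein fluctuations around the
pore walls, no solvent, no electrostatics, no lipid dynamics, no
anisotropic correlation structure. Passing tests therefore demonstrate
algorithmic correctness on geometry with known truth — that the pipeline
measures what it claims to measure — not that any particular biological
system will show particular values. Problem sizes in the tests and the
acceptance script (50–100 frame trajectories of ~400–2000 atoms, 600 000
integrator steps) are chosen as the smallest sizes at which each property
is sharply testable.

## Degenerate inputs and tie-breaks

Altloc duplicates keep the highest occupancy, ties keep the first record.
Collinear point sets in superposition fall back to a translation-only fit,
flagged. Zero-variance residues get zero correlation with a warning.
A buried tunnel seed raises an error standalone but is treated as "no
tunnels in this frame" inside the pipeline, where stage 1 has already
vouched for the frame. Equal-cost tunnel pairs break toward the larger
combined bottleneck, then file order. Ward clustering of a single frame
returns one trivial cluster.

## Limitations

- The tunnel search is grid-based, not a Voronoi construction; bottleneck
  radii and costs carry O(grid step) discretization error, and the cost
  formula (length/r², configurable) is one member of the family of
  throughput costs used by cavity-search tools.
- Suboptimal-path counts grow combinatorially with tolerance; the
  enumerator is exact but intended for protein-sized graphs and moderate
  tolerances.
- The metadynamics engine is a single-walker, 1-CV implementation on
  analytic potentials; it is not a substitute for biased sampling in an MD
  engine and makes no attempt to reproduce system-specific free-energy
  surfaces.
- The structure-comparison utility matches residues by index, which
  presumes consistent numbering between the two structures; a sequence
  alignment is out of scope.
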