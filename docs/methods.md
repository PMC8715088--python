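# Methods

## The measurement problem

Pre-embedding immunogold FIB/SEM produces (i) a stack of serial images
segmented into labeled compartments — dendritic shafts of spiny
(pyramidal) or smooth (interneuron) dendrites and their spines — at an
anisotropic acquisition grid (typically 5 × 5 nm in-plane, 20 nm
sections), (ii) coordinates of silver-enhanced gold particles, and
(iii) painted synaptic specializations classed asymmetric (excitatory)
or symmetric (inhibitory). The quantities of interest are particle
counts and densities per compartment, the membrane vs intracellular
split, the spatial arrangement of membrane particles (clustered or
random), and their distances to synapses. Because proteins diffuse in
the membrane, all between-particle and particle-to-synapse distances
are measured **along the membrane surface** (geodesics), not through
space.

## Surface model

After majority-vote block reduction of the x-y plane to the section
thickness (default 20 nm; ties resolve to the lowest label so the
operation is deterministic; z is never resampled), the membrane of a
compartment is the graph of its boundary voxels:

- a voxel is a surface node when ≥ 1 of its 6 face-neighbors carries a
  different label or lies outside the volume;
- nodes are 26-adjacent boundary voxels, edge weight = Euclidean
  distance between voxel centers (20, 20√2 or 20√3 nm);
- each node carries an area weight = exposed-face count × face area.

This raster surface is deterministic and directly checkable against
brute-force shortest-path oracles, at two documented biases:

- **chamfer bias** — graph geodesics overestimate true surface distance
  direction-dependently by up to ~8% (worst at ~22.5° to a grid axis);
  observed and null patterns share the metric, so comparative
  statistics (z, p) are unaffected, and absolute NNDs carry this bias;
- **face-count area bias** — summed exposed-face area overestimates a
  smooth surface's area (×1.5 for a sphere); it is used only as a
  *relative* sampling weight, where the bias largely cancels.

Geodesic fields are computed with Dijkstra on the sparse adjacency
matrix; surfaces up to 6000 nodes cache the full distance matrix, which
makes the 100-replicate null and repeated-trial calibrations cheap.

## Membrane contact

A particle is plasma-membrane-bound when its distance to the nearest
surface node is ≤ `pm_contact_radius` (default 20 nm = one voxel),
an operationalization of the visual "touches the inner leaflet"
criterion at the scale of both the section thickness and a
silver-enhanced grain. Localization is judged against the *merged*
dendrite membrane (shaft + spines as one surface) so internal
spine/shaft interfaces never count as plasma membrane. Particles
digitized just outside the traced contour are attributed to the nearest
labeled voxel within the same radius; exact ties break to the closer
voxel and then the lower label id. The classification is monotone in
the radius by construction.

## Randomness test, clusters, synapse profiles

- **NND.** Per-particle geodesic nearest-neighbor distance via
  multi-source shortest paths (exact); mean and sample SD reported.
- **Null.** Each of `reps = 100` control placements draws the observed
  number of *distinct* surface nodes with probability proportional to
  node area (approximating uniformity over the continuous membrane,
  since boundary voxels expose 1–5 faces) and recomputes the mean NND.
  Reported: z = (obs − null mean)/null SD and the one-sided add-one
  empirical p = (1 + #{null ≤ obs})/(reps + 1). A single-replicate run
  is flagged degenerate (no SD, no z).
- **Clusters.** Single linkage at threshold mean + 2·SD of the NNDs
  (the published threshold phrase is ambiguous; mean − 2·SD is
  negative whenever SD > mean/2, which holds for clustered data and
  would void the analysis, so the "+" reading is the default and the
  choice is recorded in every run manifest; `minus2sd` is available).
  Groups of ≥ 3 particles are clusters; 1–2 are scattered.
- **Synapse profiles.** Distance from each membrane particle to the
  nearest patch-*edge* node (patch nodes adjacent to ≥ 1 non-patch
  node) of the requested synapse type; particles under a patch score 0.
  Counts fall in 60-nm bins over [0, 660) — exactly 11 bins.
  Proportions are normalized over within-limit particles; the
  within/beyond totals are both reported since either denominator can
  be of interest.

## Synthetic scenes

The generator emulates the geometry and labeling statistics of the
reconstructed CA1 dendrites: a gently curved capped-cylinder shaft
(defaults 4 μm long, 0.5 μm radius ≈ 3.1 μm³, matching the 1.8–6.7 μm³
range of the study's shafts), mushroom spines (head radius 110–190 nm →
volumes ≈ 0.005–0.03 μm³, neck 300 × 60 nm; neck dimensions are
conventions, as only qualitative descriptions exist) with one
asymmetric patch per head, symmetric patches on the shaft, and two
particle models:

- `csr_surface` — Poisson(λ_pm × area) particles placed area-weighted
  on surface nodes (default 34 gold/μm², the study's approximate
  membrane intensity);
- `clustered_surface` — a Thomas-like parent–offspring process with
  geodesic offspring spread (defaults: 40 parents, Poisson(5) offspring,
  σ = 30 nm), which reproduces the qualitative 3–8-particle cluster
  range;
- intracellular deposits as 3D Poisson (default 125 gold/μm³, the
  study's shaft-interior scale), restricted to voxels two
  26-connectivity erosions deep so no deposit can fall within the
  20-nm contact radius after sub-voxel jitter.

Membrane deposits sit on surface nodes with ≤ 5 nm jitter — the same
surface model the analyzer uses — so ground-truth recovery tests are
clean by construction. Scenes default to the 20-nm isotropic analysis
grid; acquisition-grid scenes (5, 5, 20) are supported and resampled
internally before particle placement. Everything is deterministic given
the seed.

What the generator does **not** emulate: imaging noise and silver-grain
segmentation (coordinates are inputs), antibody penetration gradients,
axons/boutons and neuropil packing, curvature-dependent labeling.
Passing tests therefore validate the *quantification machinery*, not
robustness to upstream segmentation or staining artifacts.

## Transcribed tables and the per-spine stand-in

The published per-dendrite tables (counts, volumes, densities for six
pyramidal and six interneuron dendrites) are packaged as fixtures and
drive the worked example. Two conventions matter:

- totals-row densities follow the published convention of averaging the
  per-dendrite density column *as printed* (8.86 ± 0.15 and
  45.22 ± 12.12 arise only from the printed rounded values; recomputing
  densities from raw counts/volumes gives 45.24 — both are reported);
- the printed total shaft volume (23.89 μm³) differs from its column
  sum (24.89 μm³); totals are always recomputed from per-dendrite
  values here.

Per-spine measurements are not deposited. `reference_spine_table()` is
an explicitly **synthetic** per-spine reconstruction constrained to all
published per-dendrite aggregates (spine counts, gold totals and
ranges, summed volumes, 22/84 immunonegative spines, immunonegative
mean volume 0.0079 μm³); within a dendrite immunopositive volumes are
allocated ∝ (count + 1). Statistics computed from it (26%
immunonegative share, positive-spine mean volume ≈ 0.0154 μm³,
Mann-Whitney p < 0.001) reproduce the published aggregate behavior, but
per-spine values are a construction, and its volume–count correlation
(r ≈ 0.95) is a property of the allocation rule, not a measured value.

## Numerical and design choices

- Single physical frame: 0-based voxel-center coordinates in nm; CSVs
  store nm so resampling never rewrites particle files. Voxel (k, j, i)
  center = ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz).
- One global seed fans out to per-stage substreams
  (`numpy.random.SeedSequence`); result CSVs are byte-identical across
  reruns, manifests differ only in their timestamp.
- Statistics use scipy.stats (Pearson, Mann-Whitney with exact/normal
  null selection, one-way ANOVA, pairwise t-tests with
  Bonferroni min(1, m·p), two-sample KS). All-constant groups are
  flagged degenerate instead of raising.
- Fold ratios are reported raw and integer-rounded; reciprocal pairs
  multiply to 1 before rounding.

## Problem sizes used in tests

Calibration and oracle tests run on reduced geometries with the study's
*process* parameters kept: oracle comparisons on a ≤ 500-node sphere
surface; randomization type-I calibration with 500 trials × 100
replicates of 20 particles on a ~1900-node sheet; power runs with
σ = 30 nm clustering on a ~5000-node smooth dendrite; classification
recovery and end-to-end determinism on a 2-μm spiny scene. The
acceptance script uses a 2-μm clustered scene for its end-to-end
demonstration.

## Limitations

- Geodesics are chamfer-biased (≤ ~8%); absolute NNDs inherit this.
- The boundary-voxel surface has no sub-voxel geometry; patches thinner
  than one voxel cannot be represented.
- Per-surface analysis assumes each compartment's membrane is
  connected; disconnected pieces yield infinite distances and a
  warning.
- No Ripley's K / pair-correlation analysis and no cross-type
  co-clustering; no mixed-effects modeling of spines within dendrites.
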