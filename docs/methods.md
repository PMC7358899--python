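# Methods

netanat builds the anatomical basis of a neural-network model in two
stages: it places quasi-spherical cellular structures as a densely packed
point process, and it derives candidate synaptic connections from the
geometry of extended structures (dendrites, axons) represented as point
clouds or line segments. This note records the models, the numerical
choices, and what the package's validation does and does not demonstrate.

## Cell placement as maximal Poisson-disk sampling

Cell somata and synaptic structures in many neural tissues are neither
lattice-like nor Poisson-random: they resemble a dense packing of slightly
compressible spheres. The placement model is Poisson-disk sampling (PDS):
points are inserted uniformly at random subject to a minimal mutual
distance r. In *maximal* mode insertion continues until no further point
can be added anywhere — the saturation regime of random sequential
adsorption, which ties a density to every spacing r.

The sampler is a voxelized dart-throwing variant of Bridson's algorithm.
The generation box is covered by cubic voxels of side r/D (D the
dimensionality; the divisor is configurable, and any value ≥ √D keeps at
most one accepted point per voxel). Each round selects 20% of the eligible
voxels at random, throws one uniform candidate into each, and accepts
candidates that keep distance ≥ r to all previously accepted points and to
earlier-accepted candidates of the same round (a deterministic sequential
greedy pass). Voxels that receive an accepted point become ineligible, and
voxels that accumulate 16 consecutive rejections drop into a low-priority
pool that is only sampled when no other voxels remain. When a round adds
fewer new points than 0.06% of the target count, all eligible voxels are
split into half-side subvoxels and subvoxels that provably contain no
insertable location are discarded; subdivision recurses (down to a
resolution floor of r/256) until the eligible set is exhausted.

Two implementation details are worth recording:

- **Coverage certificates.** A subvoxel can be discarded only if *no*
  point of it could ever be accepted. The free-distance field
  f(x) = min_i |x − p_i| is 1-Lipschitz, so evaluating it on the
  {0, ½, 1}^D node lattice of a voxel (covering radius √D·s/4 for side s)
  gives a rigorous bound: if every node is within r − √D·s/4 of an
  accepted point (or within the margin-reduced exclusion distance of a
  previously placed population), the voxel is dead. The test never
  over-prunes, so maximality is preserved exactly; under-pruned slivers
  are resolved at deeper levels. Neighbour queries run on uniform grids
  with cell size equal to the query radius (compiled with numba), which
  keeps the cost of a full placement linear in the number of cells.
- **Ancestor removal.** When a point is accepted after subdivision, all
  active subvoxels of its top-level ancestor voxel are removed. This loses
  nothing: the top-level voxel diagonal is below r, so any other candidate
  in the same ancestor would be rejected anyway.

**Soft spheres.** Real cells deform; hard-core packings produce an
unrealistically sharp cut-off in the nearest-neighbour distribution. A
softness margin δ is therefore subtracted from every exclusion distance
before sampling, and after sampling every coordinate is jittered by
independent N(0, δ²) noise. The granular-layer example uses δ = 1 µm for
Golgi cells and glomeruli and δ = 0.2 µm for granule cells.

**Anisotropy.** Populations whose spacing is directionally biased are
sampled in a "squeezed" frame: coordinates are multiplied by a per-axis
scale vector, sampling is isotropic there, and the result is mapped back.
Glomeruli use sagittal scale 1/3, making their real-space sagittal spacing
three times the mediolateral one.

**Multi-population exclusion.** Populations are generated sequentially;
candidates of a later population are rejected when they come closer to any
earlier point, in real coordinates, than the mean of the two diameters
minus the softness margin. The intra-population distance is enforced in
the squeezed frame, the inter-population distance in real space (a prior
population's exclusion zone should be a sphere around each of its members
regardless of the frame the new population is sampled in).

**Boundary handling.** Packing against a wall biases density upward near
it, so every population is generated in a box extended by 25 µm per side;
after generation, all points in 25 µm strips at the boundaries are
removed and the rest shifted back to the origin. Point ids are assigned
before trimming and preserved.

## Density-targeted distance tuning

Given a target density ρ, the spacing r is unknown a priori. The tuning
search anchors at the complete-fill distance d_c = (6V/(π n))^(1/3) in 3D
(the diameter at which n spheres would exactly fill V; (4V/(π n))^(1/2) in
2D), starts at d_1 = 1.05·d_c, and finds the threshold d_θ at which the
trimmed count of a maximal run crosses the target n = ρV. Since the
saturation count scales as d^-D, the bracketing phase jumps toward the
target with that exponent (descending at least 5% and at most 40% per
step); bisection then narrows the bracket to a relative width of 10⁻³.
Every evaluation is a full maximal run at a seed derived deterministically
from the master seed and the iteration index, so the search is
reproducible. A final set of runs (3 by default) at d_θ measures the
achieved density; the result records whether its deviation from the target
is below the configured tolerance rather than raising, because the
attainable agreement depends on the cell count: the default tolerance of
10⁻⁴ is meaningful for populations of 10⁵–10⁶ cells, while at desk-scale
counts (10³–10⁴ cells) seed-to-seed fluctuation of the saturation count is
on the order of 0.5–1% and the verification is checked at the 1% level.

Tuned on the granular-layer targets this yields r within a few percent of
the published spacings (mossy fibres ≈ 20.4 vs 20.9 µm, Golgi ≈ 43.1 vs
45 µm, glomeruli ≈ 8.37 vs 8.39 µm, granule cells ≈ 6.26 vs 6.15 µm); the
residual offsets are consistent with the ideal-saturation density of
random sequential adsorption and with finite-volume effects at the reduced
problem sizes used here (see below).

## Morphology representation

Extended structures are represented as tagged point clouds
(`QueryPoints`: position, owning cell, compartment label, segment id,
arc-length from the structure origin) or, for mutually parallel axons, as
line segments (`AxonBundle`).

Golgi cells carry two apical and two basal straight dendrites, sampled at
25 and 12 uniformly spaced points respectively (74 points per cell),
apical pointing into the upper hemisphere and basal into the lower one,
with an azimuthal preference for the sagittal direction. The angular
distributions and dendrite lengths are model *inputs*: the defaults
(apical 150 µm, basal 80 µm, polar bands 10–60° and 120–170°, azimuth
cone half-width 45° around ±y) are placeholder assumptions chosen to
produce plausible morphologies, not derived values, and should be replaced
with measured parameters for quantitative use.

Granule-cell axons ascend vertically from the soma to a branch point (the
ascending axon, AA) whose height is fixed or drawn uniformly from a
molecular-layer depth band, then extend symmetrically along the
mediolateral axis as the parallel fiber (PF; default half-length 1000 µm).
Axonal path length — used downstream for conduction delays — is measured
from the soma: along the AA directly, and for PF contacts as branch height
plus distance along the fiber.

Segment ids are assigned by a fixed segment length (default 10 µm,
`floor(arc/len)` clipped so the tip belongs to the last segment); a
callable rule mapping structure length to segment count can be supplied
instead, standing in for electrotonic segmentation rules whose membrane
constants are not part of this package.

## Connectivity searches

All searches are exact fixed-radius neighbour problems solved on a K-d
tree (scipy's cKDTree) built over the larger of the two clouds — tree
construction is cheaper per point than querying, so the smaller cloud
queries the bigger tree; results are independent of which side hosts the
tree, and chunking the query cloud (for parallel dispatch) provably
preserves the result set.

- **Point-to-population** (granule cell somata → glomeruli): both clouds
  are scaled per axis before the search, so a radius r_c acceptance ball
  becomes a real-space ellipsoid with semi-axes r_c/scale. The example
  uses r_c = 7.85 µm with sagittal scale 1/4 (GC dendrites reach about
  four times farther sagittally). At most one record per (source, target)
  cell pair is kept — the nearest target point in scaled distance — and
  reported distances are always real-space Euclidean.
- **Projection search** (axon bundles → dendrite clouds): each axon,
  being parallel to a coordinate axis, projects to a single point on the
  perpendicular plane. A 2D ranged search finds laterally close targets
  and an interval test along the axis rejects targets beyond the axonal
  stretch. This searches a true cylinder around the axon — the limit of a
  bead-chain 3D search as the bead spacing goes to zero — at a fraction
  of the cost and without discretization artifacts.
- **Post-processing cap**: clustered multiple contacts between one axon
  and one dendrite can be limited to the k nearest per cell pair, with
  deterministic tie-breaking (segment id, then synapse x).

Radius comparisons are inclusive (≤ r_c). Output tables are sorted by
(source, target, segment, distance), making runs byte-reproducible.

## Validation statistics

- Nearest-neighbour distances (exact, via the tree).
- Pair correlation g(r) on regular bins. Edge handling restricts
  reference points to the core eroded by r_max so every shell lies inside
  the box; with r_max = 20 µm in a 350 µm box this retains most points
  and is unbiased. For homogeneous Poisson input, g is 1 within sampling
  error (calibrated in the tests at 3 standard errors).
- Degree statistics of connection tables: mean, *population* standard
  deviation (divide by N), and the fractions of source cells with degree
  < 3 and > 7; cells without records count as degree 0.

## Problem sizes and what the validation shows

The granular-layer validation runs in a 350 × 350 × 100 µm box (about
23,000 granule cells and 7,000 glomeruli after trimming), a linear factor
of 2 below the full published model, and averages stochastic quantities
over three seeds; the tuning searches for glomeruli and granule cells use
the same or a further reduced box. These sizes keep a complete validation
run in the tens of minutes on one CPU while leaving edge effects small
relative to the stated tolerances (the largest acceptance ellipsoid
semi-axis, 31.4 µm sagittally, is still an order of magnitude below the
box side). The connectivity statistics reproduce the published values
(4.43 ± 1.37 connections per granule cell at mean distance 13.47 µm in
the volume-filling model versus 4.25 ± 2.12 for random positions) within
the tolerances stated in the tests.

Passing these checks shows that the placement process realizes a maximal
soft-sphere packing with the intended densities and anisotropies and that
the searches implement their geometric definitions exactly. It does not
validate the biological parameter values themselves (densities, reach
factors, morphology parameters are inputs taken from the literature), nor
does it exercise features of real tissue the generators deliberately
omit: curved laminar geometry, branching dendritic trees, reconstructed
morphologies, diameter variation along neurites, and activity- or
chemistry-dependent synapse selection beyond proximity (Peter's rule).

## Degenerate inputs and edge cases

A domain smaller than the spacing yields a single point (never an error);
a Bridson request that cannot be satisfied reports the shortfall instead
of truncating silently; an empty position set renders an empty point
cloud; zero-length dendrites collapse onto the soma; a zero-height
ascending axon degenerates to the soma with the parallel fiber passing
through it; a tuning target unreachable under the given priors raises a
bracketing error. Randomness is drawn exclusively from named substreams
of one master seed (stable CRC-based keys), so every pipeline stage is
individually and jointly reproducible; re-running a pipeline with the
same configuration and seed reproduces every output file byte for byte.
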