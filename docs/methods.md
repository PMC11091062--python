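# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind each stage of the pipeline, and what the phantom-based
validation does and does not establish about real scans.

## Coordinate and data conventions

Volumes are `(z, y, x)` arrays with a physical voxel pitch
`voxel_size_um = (dz, dy, dx)`; the voxel `(k, j, i)` is centred at
`(k·dz, j·dy, i·dx)` µm. All geometry (centerlines, node positions,
distances) lives in micrometres, so anisotropic acquisitions are handled
uniformly: distance transforms use per-axis sampling, structuring elements
can be ellipsoidal, and phantom rasterization converts physical
coordinates per axis. Masks are boolean arrays on the volume lattice and
are stored as 0/255 8-bit TIFF stacks; volumes as 16-bit TIFF with a JSON
sidecar carrying the voxel size.

## Synthetic phantoms

The generator emulates the salient features of micro-CT scans of
contrast-perfused vasculature: bright tubular lumina of known centerline
and radius over a darker tissue background, a Gaussian blur standing in
for the partial-volume effect (each voxel averages the attenuation of the
materials inside it), additive Gaussian noise (seeded, clipped to the
16-bit range) standing in for reconstruction noise, and an annular-sector
("C"-shaped) tissue wedge on which the zonation geometry is analytically
known. Default tube diameters span 15–135 µm and the default resolutions
are 60 / 30 / 15 µm voxels — the regimes of low-, medium- and
high-resolution laboratory scanning of small musculoskeletal specimens,
where the thinnest vessels sit at or below a voxel.

A voxel belongs to a tube when its centre lies within the (linearly
interpolated) radius of the centerline polyline. This rule is simple,
convergent and analytically checkable; note its limit object is a
*capsule* (cylinder plus hemispherical end caps), which the volume
convergence test uses. Ground-truth lengths, diameters, tortuosities and
branching topology are computed from the tube specifications, never from
the raster, so refining the voxel size leaves the truth fixed while the
recovered estimates converge toward it.

What the phantoms do **not** emulate: beam hardening, ring artifacts,
cone-beam geometry, inhomogeneous contrast filling and perfusion gaps,
or textured soft-tissue backgrounds. Passing recovery tests therefore
demonstrates the correctness and convergence of the *analysis* chain, not
robustness to every acquisition artifact of real scanners.

## Segmentation

Histograms use 256 equal-width bins over the observed min–max range
(8-bit semantics even for 16-bit data, matching the behaviour of the
common ImageJ-family implementations). The maximum-entropy criterion is
evaluated with natural logarithms — the argmax is base-invariant, but the
reported criterion values are in nats. Class probabilities and entropy
partial sums for the upper class are accumulated by *reversed* cumulative
sums: computing the tail as `total − head` cancels catastrophically when
the tail class is nearly empty and can corrupt the argmax. Analytic ties
in the criterion (recognized within 1e-10) resolve to the smallest
threshold for determinism.

When a tissue mask is available the histograms are restricted to tissue
voxels, so the flattened exterior produced by background removal does not
dominate the gray-level statistics; the output masks are then also clipped
to the tissue.

The top-hat structuring element defaults to a ball of radius 2 voxels
(per-axis radii configurable for anisotropic data): vessels thinner than
about 5 voxels across count as "detail". The top-hat response is binarized
by a second maximum-entropy threshold on its own histogram by default; a
fixed numeric threshold can be supplied instead. The final vessel mask is
the voxelwise union of the global-threshold mask and the top-hat mask —
the two are complementary by construction (main network vs. sub-element
detail).

Degenerate inputs: a single-valued volume has no separating threshold and
raises; an all-background volume therefore fails fast rather than
producing an arbitrary mask.

## Skeletonization and the vessel graph

The Euclidean distance transform (exact, anisotropy-aware) is computed
*before* thinning, so every centerline voxel carries the local vessel
radius; local diameter is twice that value. Thinning uses a
topology-preserving 3D algorithm producing a 26-connected, one-voxel-wide
skeleton; connected components and cycles of the mask are preserved.

Graph organization: skeleton voxels with exactly two 26-neighbours are
interior segment points; all others are node candidates. Adjacent
candidates are merged into a single node at their centroid (thinning
yields thick junction clusters; merging prevents spurious degree
inflation). Chains between nodes become segments whose endpoints are the
node centroids. Nodes are terminal (degree 1) or branching (degree ≥ 3);
degree-2 nodes arising from junction-cluster artifacts are dissolved by
merging their two incident segments. Junction-free 26-connected cycles
are kept as loop-flagged segments: their chord is zero, so tortuosity is
undefined and they are excluded from tortuosity aggregates while still
counting toward lengths and volumes. A non-thin input (any solid 2×2×2
block) is rejected with an instruction to skeletonize first.

Interior segment points receive a light moving-average smoothing (window
3, endpoints fixed, `smooth_window` configurable, 0 disables). The raw
voxel chain overestimates curved length — and hence tortuosity — by
several percent on oblique and curved vessels because of the lattice
staircase; the 3-point window removes single-voxel jitter while barely
shortening genuine curvature. With it, phantom recovery achieves ~1% on
length and tortuosity at radius ≥ 3 voxels.

Spur pruning (`prune_spurs`) removes terminal segments shorter than a
physical threshold and dissolves the degree-2 nodes this creates,
iterating to a fixed point (idempotent at a fixed threshold). The default
threshold is 0 — off — because the upstream workflow this mirrors reports
no pruning; isolated segments (both endpoints terminal) are never removed.

## Morphometry

Per segment: curved length = Σ consecutive point distances; chord =
first-to-last point distance (the two node positions); tortuosity =
length/chord, flagged undefined when the chord vanishes. Mean diameter =
unweighted mean of 2 × local radius over the segment's points.

Network level: totals are sums over segments; the network mean diameter is
the unweighted mean of per-segment means by default (`"segment"`), with a
point-weighted alternative (`"point"`) exposed because descriptive tables
in the field are ambiguous between the two. Total vascular volume is the
segmented-mask voxel count times the voxel volume, reported in mm³.
Diameter and length histograms use left-closed bins of 10 µm and 25 µm by
default. The resolution sweep rasterizes one physical phantom at several
voxel sizes and runs the full chain at each; with sub-resolution tubes
present it reproduces the expected pattern — more segments, greater total
length, smaller mean diameter at finer voxels. On noisy phantoms the fine
grids also fragment noise into many small spurious segments, which
exaggerates the segment-count ratio; the *direction* of the effect is the
validated claim.

## Zonation

Circumferential zones: the perimeniscal region is taken from an explicit
mask when available (it is delineated on real images by appearance and
density; no densitometric auto-detection is attempted). As a fallback, a
band of fixed physical width along the outer periphery is constructed
with a star-convexity heuristic (background voxels farther from the
in-plane centroid than all adjacent tissue). The heuristic is only valid
for roughly convex outlines — on a strongly C-shaped solid the concavity
confuses it, so explicit masks are preferred there.

The remaining tissue gets a normalized radial coordinate
`f = d_outer / (d_outer + d_inner)` from two distance transforms: `d_outer`
to the PM set, `d_inner` to the detected free edge. Zone 1 is `f < 1/3`,
zone 2 `1/3 ≤ f < 2/3`, zone 3 `f ≥ 2/3` (half-open, lower-inclusive).
This generalizes "thirds of the radius" to arbitrary cross-sections as
equal-*thickness* shells; thirds of *area* would be a different
convention. Free-edge detection is the delicate step: a background voxel
adjacent to the zone-able tissue is accepted as free edge only if its
PM-distance exceeds that of *all* its adjacent tissue voxels by at least
0.3 of the smallest voxel pitch, and it does not touch PM itself. Cut
faces (specimen cuts, stack top/bottom) run parallel to the PM-distance
gradient, so some adjacent tissue voxel is always deeper and they are
excluded; without this, a handful of leaked face voxels poison `d_inner`
over large regions. The 0.3-pitch margin separates the genuine half-voxel
step of a free edge from the zero step of a cut face under discretization
jitter. Voxels where both distances vanish go to zone 1 by convention and
are logged.

Radial sectors: the in-plane angle of each voxel about the center
(tissue centroid unless specified) is measured *relative to the sagittal
plane* and folded onto [0°, 180°] — both sides of the plane belong to the
same cut, matching sectioning at 45°/90°/135°. Bins are half-open,
lower-inclusive; the last closes at 180°. The `side` flag
(lateral/medial) mirrors the anatomical order; chirality is configuration,
never inferred. Voxels exactly at the center get the boundary rule and are
logged.

Contributions are vessel-voxel fractions over the labeled partition;
excluding PM renormalizes over zones 1–3. Whole segments are assigned to
the zone holding the majority of their centerline points (ties: the
midpoint's zone); nodes by their position.

## Statistics

One-way ANOVA by the classical between/within decomposition. Degenerate
inputs are flagged explicitly: zero within-group variance with unequal
means yields F = ∞, p = 0; all-identical data yields F = 0, p = 1.
Tukey–Kramer uses
`q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j))`
with p-values from SciPy's studentized-range distribution (numerically
integrated CDF); with equal group sizes this reduces exactly to Tukey's
HSD, and it matches the statsmodels implementation to 1e-6 in tests.
Pooled SEM concatenates observations across the connected subnetworks
("graphs") before computing sd/√n, and is flagged undefined for a single
pooled value.

The unit of analysis is explicit: group comparisons operate on whatever
observations the caller puts into `GroupSample` (per-specimen means for
zone comparisons with N specimens, per-graph pooling for descriptive
errors). The pipeline's built-in zone comparison uses per-segment
diameters within one run and is labelled as such in the report.

Report tables map p-values to the conventional bands
(* 0.01–0.05, ** 0.001–0.01, *** < 0.001).

## Pipeline determinism

The six stages (phantom/input, segment, skeleton, measure, zones, report)
each persist their outputs plus a manifest with the configuration hash,
package version and per-file SHA-256 checksums. All randomness flows from
the single config seed through `numpy.random.default_rng`; TIFF and
CSV/JSON writers emit no timestamps, so identical configurations reproduce
bit-identical output trees — verified by checksum comparison in the tests.

## Problem sizes used in validation

Phantom volumes in the test-suite and acceptance runs range from ~10⁵ to
~2.5×10⁶ voxels (e.g. a 40×40×128 straight-tube phantom at 15 µm, a
10×125×225 half-annulus wedge at 200 µm, and a resolution sweep whose
fine grid is 80×120×240). These sizes give sub-voxel-converged metrics
and stable zone fractions while keeping a full validation run in minutes
on one CPU; the algorithms themselves are resolution-agnostic and stream
through SciPy/scikit-image primitives, so full-scale scans are limited
only by memory.

## Known limitations

* Recovery bands (2% length, one-pitch diameter) assume vessel radius
  ≥ 3 voxels and lengths well above the pitch; endpoint erosion by
  thinning costs roughly one voxel per end, which dominates the error for
  very short segments.
* The mean-diameter estimate at junctions blends the junction bulge into
  adjacent segments via the node radius; on phantoms this biases segment
  diameters by a few percent near branch points.
* The PM-band fallback assumes a star-convex periphery (see above).
* Zone geometry is defined in the axial plane; strongly oblique tissue
  orientations should be reoriented first.
* No vesselness filtering or machine-learning segmentation: the two-mask
  strategy is deliberately simple and operator-independent.
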