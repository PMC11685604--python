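# Methods

This note documents the models, conventions and numerical choices behind
`deepstain3d`, and what the synthetic phantoms do and do not establish about
real data.

## Conventions

All volumes are 3D arrays in (z, y, x) axis order — z is the TIFF page axis —
with physical voxel spacing (dz, dy, dx) in µm. Every distance-valued
quantity (depths, σ scales, geodesics, proximity values) is in µm. Distance
transforms and Gaussian filters are spacing-aware: a σ given in µm is
converted to per-axis voxel sigmas, so anisotropic grids are handled
correctly; passing `spacing=(1,1,1)` reproduces naive voxel-unit behavior
where a comparison to spacing-unaware pipelines is needed. Convolution
boundaries use reflect padding, which avoids edge ringing on finite volumes.

## Penetration benchmark

**Model.** Per segmented cell, the ratio of bulk-staining to cut-staining
mean intensity is regressed on penetration depth d with
ratio = A·exp(−τ·d). Two variants are exposed: *fixed-amplitude* (A ≡ 1,
appropriate when ratios are normalized so that surface cells sit at 1) and
*free-amplitude* (A estimated, the default, because real channel intensities
are in arbitrary units and their relative gain is unknown). τ ≥ 0 is
enforced; the reported unit is 1/µm and log 2/τ is the half-depth.

**Depth.** The penetration depth field seeds a Euclidean distance transform
from the tissue's staining-entry surface: tissue voxels exposed on the
declared imaged face plus any interior tissue/background interface. Grid
faces other than the imaged one are treated as continuing tissue, so the
field of view's artificial borders do not masquerade as stain-entry
surfaces. A cell's depth is the mean of this field over its voxels (robust
to off-grid centroids); its intensity values are voxel means within its
label.

**Cell detection.** Bright blobs are segmented by a scale-normalized
Laplacian-of-Gaussian response (positive inside bright blobs) gated by a
Gaussian-smoothed intensity threshold, then 26-connected component labeling.
This is a deliberately simple detector: the package's contract starts at
feature extraction, and any external segmentation (e.g. a trained deep
model) can supply the label volume instead.

**Fitting.** Nonlinear least squares on the ratio scale (the model is stated
on ratios; the noise model of real data is unknown), trust-region-reflective
with τ ≥ 0, initialized from the log-linear slope of positive ratios. A
boundary polish compares the solver's result with the exact τ = 0 boundary
solution (with its closed-form optimal amplitude) and keeps whichever has
lower RSS, so the ideal, depth-independent case returns τ = 0 exactly
rather than a solver-epsilon. A log-space linear fit (`fit_decay_log`) is
provided as a cross-check. Cells whose cut-channel mean falls below a floor
(default 0; recommended 5× background SD when supplied) are excluded from
the fit and flagged, never divided through.

## Structure tensor

Gradients are Gaussian derivatives (∇I = I ∗ ∇G_σ); the tensor is the
outer product smoothed at a second scale, T̄ = G_ρ ∗ (∇I ⊗ ∇I). Defaults
σ_grad = 1 µm, ρ = 3 µm: ρ > σ is the standard regime in which the tensor
averages gradient orientation over a neighborhood rather than a point. Both
are exposed on the CLI, and should scale with the fiber diameter of
interest.

Eigendecomposition uses the symmetric solver; eigenvalues are sorted
descending and clipped at 0 (T̄ is PSD in exact arithmetic; small negative
values are roundoff). Eigenvector sign is fixed by making the first
component of magnitude > 1e−12 positive; orientation is axial, so the
orientation-RGB encoding uses absolute components and antipodal vectors map
to the same color. FA of a voxel whose eigenvalues are all below 1e−12 ×
the volume maximum is defined as 0 ("no structure"; the formula is 0/0
there). The RGB map defaults to x→R, y→G, z→B and multiplies |v3| by FA and
by max-normalized voxel intensity; the axis-to-channel assignment is
configurable since conventions differ between tools.

Inside a tubular ridge the gradient varies strongly in the two transverse
directions and weakly along the axis, so λ1 ≥ λ2 ≫ λ3 and the tertiary
eigenvector v3 is the fiber axis — the property the fiber-phantom tests
assert quantitatively (< 5° median axial error in noiseless cores).

## Filament morphometry

d_path is polyline arc length; d_fil the start-to-end Euclidean
displacement; d_min the absolute difference of the distance-field values at
the endpoints (nearest-voxel lookup by default, matching a voxel-value
reading; trilinear lookup available). Tortuosity = d_path/d_fil and
skewness = d_fil/d_min; undefined ratios (zero denominator) are NaN, never
±inf. The take-off angle is measured between the unit displacement vector
and the distance-field gradient at the path start; the gradient is a
Gaussian derivative at σ = 2 µm because one-voxel differences of a
voxelized distance field are piecewise constant and noisy. Both the raw
[0, 180]° angle and a folded [0, 90]° variant are emitted, since either
convention is defensible. A filament is a *reacher* when its end point lies
within a tolerance (CLI default 2 µm) of the target-surface mask, via a
distance-transform lookup.

**Surface geodesics.** The surface voxel set A is the mask's foreground
voxels with ≥ 1 background face-neighbor (outer shell). The surface graph
joins voxels within the 26-neighborhood (6-connectivity optional) with
physical Euclidean edge weights; 26-connectivity markedly reduces
metrication error of grid geodesics. Shortest paths use Dijkstra
(scipy.sparse.csgraph); tests cross-check against an independently built
Bellman–Ford oracle. Geodesic distances are a metric on connected
components and always bound the straight-line distance from below.
Attachment points given in µm are snapped to the nearest surface voxel.
Nearest-neighbor geodesic statistics report, per attachment point, the
minimal geodesic distance to any other point, with both Pearson and
Spearman correlations against path length (either may be wanted for
clustering analyses).

**Trees.** Sholl counts are exact transversal crossings of each segment with
each sphere, obtained from the quadratic in the segment parameter; roots are
counted in (0, 1] so a node on a sphere attributes to its incoming segment
once, and tangencies (discriminant 0) count zero crossings. The test oracle
is the dense-resampling sign-change counter instead. Horton–Strahler order
is the standard recursion (leaf = 1; a parent gets m+1 iff ≥ 2 children
attain the max m), implemented iteratively and checked against a direct
recursive oracle.

## Proximity profiling

Per-cell marker statistics are the mean and *population* SD over the
label's voxels — the cell is the full population of its voxels, and the SD
is the within-cell heterogeneity statistic that separates compartmentalized
from uniform expression at equal mean. "Normalized" intensity defaults to
per-channel rescaling to the [0.1, 99.9] percentile range of in-cell
voxels (robust to hot pixels); `none` and `zscore` modes are available and
`none` reproduces raw moments exactly. Labels below 10 voxels are dropped
by default (tiny labels destabilize SD). Vessel distance is the cell-mean
of the vessel EDT by default (centroid lookup optional). Fiber proximity is
the cell-mean of the fiber EDT.

k-NN dispersion: per member, the mean distance to its k (default 30)
nearest same-group neighbors; per group, the mean, SD and CV of those
member values. `eval_subset` implements guard-zone edge correction — all
members remain neighbor candidates but only interior members are
aggregated — standard practice for finite observation windows, and the
mechanism by which a perfect lattice yields exactly CV = 0.

## Synthetic phantoms

Each generator is a pure function of (arguments, seed) and stores analytic
ground truth.

- **Benchmark phantom**: cells as isotropic Gaussian blobs (σ = radius/2;
  default radius 6 µm ≈ a neuronal soma) in a half-space tissue whose cut
  face is the x = 0 grid face, so true depth = x. Defaults: 48×48×128
  voxels at 4 µm isotropic (depth span 0–508 µm), 150 cells, τ = 0.005/µm,
  10% multiplicative ratio noise plus additive read noise (SD 0.5 against
  cut amplitudes of 500–1000) — chosen as a plausible mid-range of decay
  severity and detection SNR for this benchmark geometry. A record-level
  sampler draws (depth, ratio) pairs from the same generating law for
  large-n parameter-recovery studies (4 τ values × 20 seeds × 1000 cells)
  without rendering 80 volumes.
- **Fiber phantom**: parallel Gaussian tubes (radial σ 1.5 µm, unit peak)
  through random anchors along a shared unit orientation, additive noise SD
  = 1/SNR; the core mask (≤ 1σ from a centerline) defines where orientation
  recovery is asserted.
- **Glomerulus phantom**: inner sphere (R = 30 µm) and concentric shell at
  R + 10 µm (2 µm thick) at 1 µm isotropic spacing; filaments alternate
  straight lines taking off at a known angle and helices wound about the
  radial axis. Truth metrics are closed-form (helix arc length
  √(H² + a²ω²), etc.), not measurements on rasters; reachers end on the
  shell, stayers strictly inside the gap.
- **Proximity phantom**: spherical cells split into two slabs at 10 µm and
  80 µm from a fiber tube; channels cycle uniform / nuclear / cytoplasmic
  patterns constructed mean-preserving so the compartmentalized patterns
  have strictly higher within-cell SD. Intensity-truth moments are computed
  by direct voxel indexing at generation time, independently of the
  ndimage-based pipeline statistics they validate.

**What passing phantoms does not show.** The phantoms have no optics: no
PSF anisotropy, no depth-dependent attenuation or scattering, no
autofluorescence background structure, no segmentation errors beyond the
simple LoG detector's, and the filament tracings are noise-free polylines
rather than human tracings of noisy images. Results on phantoms validate
the computations, not the robustness of any upstream acquisition or
segmentation step.

## Tolerances used in validation

Discrete geometry sets the meaningful precision: polyline-derived lengths
are checked at 1e−3 relative (truth is closed-form; 400-point sampling
contributes ≤ 5e−4), field-lookup quantities (d_min) at one voxel diagonal,
ratio metrics via the propagated one-voxel error on their denominator, and
take-off angles at 10° (Gaussian gradient of a voxelized sphere EDT at
σ = 2 µm). Decay-fit recovery is asserted at < 10% median relative error
under the stated noise model. Gaussian-derivative checks against central
finite differences allow the O(h²) truncation error of the difference
oracle. Problem sizes (64³ fiber volumes, 93³ glomerulus, ≤ 260-node
surface patches for exhaustive oracles, 20-seed recovery studies) keep the
full suite under half a minute while leaving every assertion
discretization-limited rather than sample-limited.

## Known limitations

- The LoG detector merges touching cells; it is meant for well-separated
  blobs and benchmark phantoms, not dense tissue (use external instance
  segmentation there).
- Geodesics are grid-graph shortest paths; even with 26-connectivity they
  overestimate true surface geodesics by a small metrication factor on
  oblique routes.
- `DistanceField.value_at` nearest-voxel lookup quantizes endpoint metrics
  to the voxel grid; trilinear mode reduces but does not remove this.
- The decay fit assumes independent per-cell noise; spatially correlated
  staining artifacts (e.g. vasculature-limited access) violate that and
  widen the true uncertainty beyond the reported standard error.
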