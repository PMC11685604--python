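# deepstain3d

Quantitative 3D image analysis for deep-immunostaining microscopy volumes.

Modern tissue-clearing and deep-immunostaining protocols image whole organs
in 3D, but the analyses that make those images quantitative — was the stain
homogeneous in depth? which way do the fibers run? how do traced filaments
cross a cavity? how close is each cell to a fiber or vessel? — are usually
buried in one-off scripts. `deepstain3d` packages four of those analyses as
a tested Python library with a CLI, exercised end-to-end on synthetic 3D
phantoms with analytic ground truth:

- **Penetration benchmarking.** In a bulk/cut staining benchmark an organ is
  stained in bulk, cut, and re-stained on the cut face with a
  penetration-unlimited reference. For each segmented cell the bulk:cut
  intensity ratio is regressed against penetration depth *d* with a
  single-term exponential decay, ratio = A·e^(−τd); the decay constant τ
  (1/µm) quantifies the "rimming" of surface-limited staining, with τ → 0⁺
  the ideal homogeneous case. Pearson correlation of the two channels across
  cells measures quantification fidelity.
- **Structure-tensor orientation mapping.** T̄ = G_ρ ∗ (∇I ⊗ ∇I) with
  Gaussian-derivative gradients; eigendecomposition gives per-voxel fiber
  orientation (the tertiary eigenvector) and fractional anisotropy
  FA = √( ((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (2(λ1²+λ2²+λ3²)) ) ∈ [0, 1],
  rendered as orientation-RGB volumes.
- **Filament morphometry.** For traced filaments (SWC): path length d_path,
  displacement d_fil, minimal distance d_min, tortuosity d_path/d_fil,
  skewness d_fil/d_min, take-off angle against the distance-field gradient,
  reacher/stayer classification against a target surface, geodesic distances
  along a voxelized surface (Dijkstra on the 26-connected surface-voxel
  graph), nearest-neighbor geodesic statistics, Sholl profiles and
  Horton–Strahler orders for traced trees.
- **Proximity profiling.** Per-cell mean/SD of each marker channel (the
  within-cell SD flags strictly nuclear or cytoplasmic expression), distance
  to the nearest vessel, mean fiber-distance-field value, and k-NN spatial
  dispersion statistics (mean, SD, CV; k = 30 default) per cell group.

All volumes are (z, y, x) arrays with physical voxel spacing in µm;
distances, σ scales and depths are in µm throughout.

## Worked example

Recover a known decay constant from a synthetic bulk/cut benchmark phantom
(150 Gaussian-blob cells in a half-space tissue, τ_true = 0.005/µm, 10%
ratio noise), end to end through cell detection, depth mapping, and the
fixed-amplitude decay fit:

```bash
$ deepstain3d demo benchmark --seed 1
{
  "n_cells": 85,
  "pearson_r": 0.10386896379278512,
  "relative_error": 0.00975913206288856,
  "seed": 1,
  "tau_hat": 0.004951204339685557,
  "tau_true": 0.005
}
```

85 cells passed detection; the fitted decay constant τ̂ = 0.00495/µm
recovers the generating value within 1%. The low bulk-vs-cut Pearson r is
expected here: at τ = 0.005/µm the bulk signal decays ~40-fold across the
512 µm depth range, destroying the cross-channel correlation an ideal
(τ → 0⁺) method would show.

The same pipeline runs on real data from TIFF stacks:

```bash
deepstain3d benchmark bulk.tif cut.tif tissue_mask.tif \
    --threshold 150 --model eq1 --spacing 4,2,2 --out results/
deepstain3d stensor fibers.tif --sigma-grad 1 --sigma-smooth 3 --out st/
deepstain3d filaments trace_*.swc --glom-mask glom.tif --pec-mask pec.tif --out fil/
deepstain3d profile labels.tif ch_*.tif --vessel-mask vessels.tif --out prof/
```

Library use mirrors the CLI; the decay fit is a model/results pair:

```python
from deepstain3d.penetration import ExponentialDecayModel
fit = ExponentialDecayModel(depths_um, ratios, model="fixed-amplitude").fit()
print(fit.summary())   # tau, std err, amplitude, RSS, half depth
```

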