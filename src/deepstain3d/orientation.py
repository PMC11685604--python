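"""3D structure-tensor orientation and fractional-anisotropy analysis.

For an image I the structure tensor is the Gaussian-smoothed outer product of
the Gaussian-derivative gradient with itself,

    T̄ = G_ρ * (∇I ⊗ ∇I),   ∇I = I * ∇G_σ,

with σ the gradient scale and ρ the neighborhood-smoothing scale (both µm).
Eigendecomposition of T̄ gives the local shape (eigenvalues λ1 ≥ λ2 ≥ λ3 ≥ 0)
and orientation (orthonormal eigenvectors).  Inside a fiber the gradient
varies least along the fiber axis, so the tertiary eigenvector v3 points
along the fiber.  Fractional anisotropy

    FA = sqrt( ((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (2(λ1²+λ2²+λ3²)) )

ranges from 0 (isotropic) to 1 (a single nonzero eigenvalue).  The
orientation-RGB encoding maps |v3| components to color channels modulated by
FA and the original voxel intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .grid import VolumeGrid, gaussian_gradient

__all__ = [
    "TensorField",
    "EigenField",
    "structure_tensor",
    "eigendecompose",
    "fractional_anisotropy",
    "orientation_rgb",
]

# unique-component storage order (x = image axis 2, y = 1, z = 0)
COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class TensorField:
    """Per-voxel symmetric 3×3 structure tensor as 6 unique components.

    ``components`` has shape (nz, ny, nx, 6) in :data:`COMPONENT_ORDER`
    (⟨Ix²⟩, ⟨Iy²⟩, ⟨Iz²⟩, ⟨IxIy⟩, ⟨IxIz⟩, ⟨IyIz⟩).
    """

    components: np.ndarray
    spacing: tuple[float, float, float]
    sigma_grad: float
    sigma_smooth: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def to_matrices(self) -> np.ndarray:
        """Dense (nz, ny, nx, 3, 3) symmetric matrices in (z, y, x) basis."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.components, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=self.components.dtype)
        m[..., 0, 0] = zz
        m[..., 1, 1] = yy
        m[..., 2, 2] = xx
        m[..., 0, 1] = m[..., 1, 0] = yz
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = xy
        return m


@dataclass
class EigenField:
    """Eigenstructure of a tensor field.

    ``eigenvalues``: (nz, ny, nx, 3) sorted descending, clipped at 0.
    ``eigenvectors``: (nz, ny, nx, 3, 3); ``eigenvectors[..., i, :]`` is the
    unit eigenvector of λ_i with (z, y, x) components, sign-fixed so the
    first component of magnitude > 1e-12 is positive.
    ``fa``: fractional anisotropy in [0, 1].
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    fa: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.eigenvalues.shape[:3]

    @property
    def tertiary(self) -> np.ndarray:
        """Unit eigenvector of the smallest eigenvalue (the fiber axis)."""
        return self.eigenvectors[..., 2, :]


def structure_tensor(volume: VolumeGrid, sigma_grad: float, sigma_smooth: float) -> TensorField:
    """Smoothed structure tensor T̄ = G_ρ * (∇I ⊗ ∇I), spacing-aware.

    Both scales are in µm; boundary handling is reflect padding.
    """
    if not (sigma_grad > 0) or not (sigma_smooth > 0):
        raise ValueError("sigma_grad and sigma_smooth must be > 0 µm")
    gz, gy, gx = gaussian_gradient(volume, sigma_grad)
    smooth_vox = sigma_smooth / np.asarray(volume.spacing)
    pairs = (
        (gx, gx), (gy, gy), (gz, gz), (gx, gy), (gx, gz), (gy, gz),
    )
    comps = np.empty(volume.shape + (6,), dtype=float)
    for k, (a, b) in enumerate(pairs):
        comps[..., k] = ndi.gaussian_filter(a * b, smooth_vox, mode="reflect")
    return TensorField(comps, volume.spacing, float(sigma_grad), float(sigma_smooth))


def _fix_sign(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each eigenvector so its first component of |·| > tol is positive."""
    sign = np.ones(vectors.shape[:-1])
    undecided = np.ones(vectors.shape[:-1], dtype=bool)
    for k in range(3):
        comp = vectors[..., k]
        pick = undecided & (np.abs(comp) > tol)
        sign[pick] = np.sign(comp[pick])
        undecided &= ~pick
    return vectors * sign[..., None]


def eigendecompose(tensor: TensorField) -> EigenField:
    """Sorted eigendecomposition of every voxel tensor.

    Eigenvalues come out descending and clipped at zero (T̄ is positive
    semi-definite in exact arithmetic; small negative values are numerical
    noise); eigenvectors are orthonormal with a fixed sign convention.
    """
    mats = tensor.to_matrices()
    evals, evecs = np.linalg.eigh(mats)  # ascending; columns are vectors
    evals = np.clip(evals[..., ::-1], 0.0, None)  # descending
    evecs = np.moveaxis(evecs[..., :, ::-1], -1, -2)  # [..., i, :] = i-th vector
    evecs = _fix_sign(evecs)
    fa = fractional_anisotropy(evals)
    return EigenField(eigenvalues=evals, eigenvectors=np.ascontiguousarray(evecs), fa=fa)


def fractional_anisotropy(eigenvalues: np.ndarray, eps_rel: float = 1e-12) -> np.ndarray:
    """FA of eigenvalue triples (last axis of length 3), in [0, 1].

    Degenerate voxels — all eigenvalues below ``eps_rel`` times the volume
    maximum — are the 0/0 limit and defined as FA = 0 (no structure).
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = 2.0 * (l1**2 + l2**2 + l3**2)
    eps = eps_rel * float(lam.max()) if lam.size else 0.0
    degenerate = (l1 < eps) & (l2 < eps) & (l3 < eps)
    out = np.zeros_like(l1)
    ok = ~degenerate & (den > 0)
    out[ok] = np.sqrt(num[ok] / den[ok])
    return np.clip(out, 0.0, 1.0)


def orientation_rgb(
    eigen: EigenField,
    volume: VolumeGrid,
    axis_channels: tuple[str, str, str] = ("x", "y", "z"),
) -> np.ndarray:
    """Orientation color volume: |v3| → RGB, modulated by FA and intensity.

    ``axis_channels`` names the image axis rendered in (R, G, B); the default
    maps x→R, y→G, z→B.  Absolute eigenvector components are used, so
    antipodal orientations share a color.  Output shape (nz, ny, nx, 3),
    values in [0, 1]; voxels with zero FA or zero intensity are black.
    """
    if eigen.shape != volume.shape:
        raise ValueError("eigen field and volume shapes differ")
    axis_index = {"z": 0, "y": 1, "x": 2}
    try:
        order = [axis_index[a] for a in axis_channels]
    except KeyError as e:
        raise ValueError(f"axis_channels entries must be 'x','y','z', got {axis_channels}") from e
    if sorted(order) != [0, 1, 2]:
        raise ValueError("axis_channels must be a permutation of x, y, z")
    v3 = np.abs(eigen.tertiary)  # (z, y, x) components
    rgb = np.stack([v3[..., i] for i in order], axis=-1)
    intensity = np.asarray(volume.data, dtype=float)
    vmax = intensity.max()
    norm = np.clip(intensity / vmax, 0.0, 1.0) if vmax > 0 else np.zeros_like(intensity)
    rgb = rgb * eigen.fa[..., None] * norm[..., None]
    return np.clip(rgb, 0.0, 1.0)
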