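"""Synthetic 3D phantoms with stored ground truth.

Every generator is a pure function of its arguments and seed, so identical
calls produce voxel-identical volumes.  Each phantom stores the analytic
ground truth it was built from; the analysis modules are tested by recovering
that truth.

Phantoms
--------
- :func:`make_benchmark_phantom` — two-channel (bulk / cut) staining volume of
  Gaussian cell blobs in a half-space tissue, where the bulk:cut intensity
  ratio decays exponentially with depth from the cut face at a known rate τ.
- :func:`make_fiber_phantom` — parallel tubular ridges of known 3D
  orientation, for structure-tensor analysis.
- :func:`make_glomerulus_phantom` — inner sphere ("glomerulus") and outer
  shell ("parietal epithelial cell capsule") with attached filament paths of
  analytically known morphometrics and reacher/stayer labels.
- :func:`make_proximity_phantom` — labelled spherical cells with per-channel
  expression patterns (uniform / nuclear / cytoplasmic) of exactly known
  per-cell intensity moments, plus fiber and vessel masks at known offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .grid import DistanceField, LabelVolume, MaskVolume, Spacing, VolumeGrid, distance_transform
from .morphometry import TracedPath

__all__ = [
    "BenchmarkPhantom",
    "FiberPhantom",
    "GlomerulusPhantom",
    "ProximityPhantom",
    "make_benchmark_phantom",
    "make_fiber_phantom",
    "make_glomerulus_phantom",
    "make_proximity_phantom",
    "sample_ratio_records",
]


def _coordinate_grid(shape, spacing):
    """Physical (z, y, x) µm coordinate arrays for voxel centers."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _place_centers(rng, shape, spacing, n, min_sep, margin, max_tries=20000):
    """Rejection-sample n centers (µm) with pairwise separation >= min_sep."""
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    lo = np.asarray(margin, dtype=float)
    hi = extent - lo
    if np.any(hi <= lo):
        raise ValueError("volume too small for the requested margin")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} cells with separation {min_sep} µm after {max_tries} tries"
            )
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    return np.array(centers)


# ---------------------------------------------------------------------------
# Benchmark (bulk/cut staining) phantom
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkPhantom:
    """Two-channel staining benchmark volume with known decay constant.

    ``truth_cells`` columns: cz, cy, cx (µm), radius (µm), depth (µm),
    true_ratio (noisy per-cell bulk:cut amplitude ratio actually rendered) and
    ideal_ratio = exp(−τ·depth) (the noiseless generating value).
    """

    bulk_channel: VolumeGrid
    cut_channel: VolumeGrid
    tissue_mask: MaskVolume
    truth_cells: pd.DataFrame
    tau_true: float
    seed: int


def make_benchmark_phantom(
    shape: tuple[int, int, int] = (48, 48, 128),
    n_cells: int = 150,
    tau_true: float = 0.005,
    ratio_noise_sd: float = 0.1,
    seed: int = 0,
    spacing: Spacing = (4.0, 4.0, 4.0),
    cell_radius: float = 6.0,
    cut_amplitude: tuple[float, float] = (500.0, 1000.0),
    read_noise_sd: float = 0.5,
) -> BenchmarkPhantom:
    """Generate the bulk/cut staining benchmark phantom.

    The tissue is the full half-space of the grid with its cut (imaged) face
    at x = 0, so a cell's penetration depth is its x coordinate in µm.  Cells
    are isotropic Gaussian blobs (σ = radius / 2).  The cut channel renders
    each cell at a depth-independent amplitude; the bulk channel multiplies
    that amplitude by ``exp(−tau_true · depth) · (1 + ε)`` with
    ε ~ N(0, ratio_noise_sd²), and both channels receive additive Gaussian
    read noise.

    Parameters
    ----------
    tau_true : 1/µm
        Generating decay constant (0 = ideal, depth-independent staining).
    ratio_noise_sd :
        SD of the multiplicative noise on the per-cell bulk:cut ratio.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if tau_true < 0:
        raise ValueError("tau_true must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = cell_radius / 2.0
    centers = _place_centers(
        rng, shape, spacing, n_cells, min_sep=4 * cell_radius, margin=2 * cell_radius
    )
    depths = centers[:, 2].copy()  # x coordinate = distance from the cut face
    amp_cut = rng.uniform(*cut_amplitude, size=n_cells)
    ideal_ratio = np.exp(-tau_true * depths)
    noise = rng.normal(0.0, ratio_noise_sd, size=n_cells) if ratio_noise_sd > 0 else 0.0
    true_ratio = np.clip(ideal_ratio * (1.0 + noise), 0.0, None)

    zz, yy, xx = _coordinate_grid(shape, spacing)
    cut = np.zeros(shape, dtype=float)
    bulk = np.zeros(shape, dtype=float)
    for c, a_cut, r in zip(centers, amp_cut, true_ratio):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        blob = np.exp(-d2 / (2 * sigma**2))
        cut += a_cut * blob
        bulk += a_cut * r * blob
    if read_noise_sd > 0:
        cut += rng.normal(0.0, read_noise_sd, size=shape)
        bulk += rng.normal(0.0, read_noise_sd, size=shape)

    truth = pd.DataFrame(
        {
            "cz": centers[:, 0],
            "cy": centers[:, 1],
            "cx": centers[:, 2],
            "radius": cell_radius,
            "depth": depths,
            "true_ratio": true_ratio,
            "ideal_ratio": ideal_ratio,
        }
    )
    return BenchmarkPhantom(
        bulk_channel=VolumeGrid(bulk, spacing),
        cut_channel=VolumeGrid(cut, spacing),
        tissue_mask=MaskVolume(np.ones(shape, dtype=bool), spacing),
        truth_cells=truth,
        tau_true=float(tau_true),
        seed=seed,
    )


def sample_ratio_records(
    n: int,
    tau_true: float,
    ratio_noise_sd: float,
    seed: int,
    depth_range: tuple[float, float] = (0.0, 1000.0),
) -> pd.DataFrame:
    """Draw (depth, ratio) pairs from the benchmark generating model.

    A lightweight record-level counterpart of :func:`make_benchmark_phantom`
    (same model: ratio = exp(−τ·depth)·(1+ε), ε ~ N(0, sd²)) for parameter
    recovery studies at large n, where rendering full volumes adds nothing.
    """
    rng = np.random.default_rng(seed)
    depths = rng.uniform(*depth_range, size=n)
    noise = rng.normal(0.0, ratio_noise_sd, size=n) if ratio_noise_sd > 0 else np.zeros(n)
    ratios = np.clip(np.exp(-tau_true * depths) * (1.0 + noise), 0.0, None)
    return pd.DataFrame({"depth": depths, "ratio": ratios})


# ---------------------------------------------------------------------------
# Fiber phantom
# ---------------------------------------------------------------------------


@dataclass
class FiberPhantom:
    """Parallel tubular ridges with known orientation.

    ``truth_orientation`` is the shared (z, y, x) unit vector of all fiber
    axes; ``anchors`` holds one on-axis point (µm) per fiber; ``core_mask``
    marks voxels within one fiber radius of a centerline.
    """

    volume: VolumeGrid
    truth_orientation: np.ndarray
    anchors: np.ndarray
    core_mask: MaskVolume
    snr: float
    seed: int


def make_fiber_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    orientation: Sequence[float] = (0.0, 0.0, 1.0),
    n_fibers: int = 8,
    fiber_sigma: float = 1.5,
    snr: float = 10.0,
    seed: int = 0,
    spacing: Spacing = (1.0, 1.0, 1.0),
) -> FiberPhantom:
    """Generate straight parallel fibers along ``orientation`` (z, y, x).

    Each fiber is a Gaussian tube of radial scale ``fiber_sigma`` µm and unit
    peak intensity through a random anchor point; additive Gaussian noise has
    SD = 1/snr (``snr = inf`` for a noiseless volume).
    """
    u = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("orientation must be a non-zero vector")
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    u = u / norm
    rng = np.random.default_rng(seed)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    anchors = rng.uniform(0.15 * extent, 0.85 * extent, size=(n_fibers, 3))

    zz, yy, xx = _coordinate_grid(shape, spacing)
    pts = np.stack([zz, yy, xx], axis=-1)  # (nz, ny, nx, 3)
    vol = np.zeros(shape, dtype=float)
    min_d2 = np.full(shape, np.inf)
    for a in anchors:
        rel = pts - a
        proj = rel @ u
        d2 = np.einsum("...i,...i->...", rel, rel) - proj**2
        d2 = np.clip(d2, 0.0, None)  # numerical negatives
        vol += np.exp(-d2 / (2 * fiber_sigma**2))
        min_d2 = np.minimum(min_d2, d2)
    if np.isfinite(snr):
        vol += rng.normal(0.0, 1.0 / snr, size=shape)
    core = MaskVolume(min_d2 <= fiber_sigma**2, spacing)
    return FiberPhantom(
        volume=VolumeGrid(vol, spacing),
        truth_orientation=u,
        anchors=anchors,
        core_mask=core,
        snr=float(snr),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Glomerulus phantom
# ---------------------------------------------------------------------------


@dataclass
class GlomerulusPhantom:
    """Spherical glomerulus + capsule shell with attached filament paths.

    ``truth_metrics`` columns: path_id, d_path, d_fil, d_min, tortuosity,
    skewness, takeoff_angle (degrees), is_reacher — all closed-form values of
    the generating geometry, not measurements on the rasters.
    ``bowman_field`` is the Euclidean distance from the glomerular mask, so a
    point at radius r carries value ≈ r − R.
    """

    glom_mask: MaskVolume
    pec_mask: MaskVolume
    bowman_field: DistanceField
    paths: list[TracedPath]
    truth_metrics: pd.DataFrame
    attachment_points: np.ndarray
    seed: int
    radius: float
    shell_gap: float


def _tangent_basis(u: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pair spanning the plane perpendicular to unit vector u."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    theta = rng.uniform(0, 2 * np.pi)
    return np.cos(theta) * e1 + np.sin(theta) * e2, -np.sin(theta) * e1 + np.cos(theta) * e2


def make_glomerulus_phantom(
    radius: float = 30.0,
    shell_gap: float = 10.0,
    n_reachers: int = 4,
    n_stayers: int = 4,
    seed: int = 0,
    spacing: Spacing = (1.0, 1.0, 1.0),
    shell_thickness: float = 2.0,
    n_points_per_path: int = 400,
) -> GlomerulusPhantom:
    """Generate the glomerulus/Bowman-space phantom with traced filaments.

    Half of the generated paths of each class are straight lines taking off at
    a known angle from the radial direction; the other half are helices wound
    about the radial axis.  Reachers terminate on the inner capsule (PEC)
    surface at radius R + gap; stayers terminate strictly inside the gap.  All
    path metrics are stored in closed form.
    """
    if n_reachers < 0 or n_stayers < 0:
        raise ValueError("path counts must be >= 0")
    if shell_gap <= 0:
        raise ValueError("shell_gap must be > 0")
    rng = np.random.default_rng(seed)
    margin = 4.0
    half = radius + shell_gap + shell_thickness + margin
    shape = tuple(int(2 * math.ceil(half / s)) + 1 for s in spacing)
    center = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])

    zz, yy, xx = _coordinate_grid(shape, spacing)
    r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    glom = MaskVolume(r <= radius, spacing)
    pec = MaskVolume((r >= radius + shell_gap) & (r <= radius + shell_gap + shell_thickness), spacing)
    bowman = distance_transform(glom)

    paths: list[TracedPath] = []
    rows = []
    starts = []
    labels = [True] * n_reachers + [False] * n_stayers
    for i, is_reacher in enumerate(labels):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        start = center + radius * u
        r_target = radius + shell_gap if is_reacher else radius + rng.uniform(0.3, 0.7) * shell_gap
        helical = i % 2 == 1
        if not helical:
            # straight filament at take-off angle theta from radial
            theta = np.deg2rad(rng.uniform(0.0, 35.0))
            e1, _ = _tangent_basis(u, rng)
            direction = np.cos(theta) * u + np.sin(theta) * e1
            # |R·u + L·dir| = r_target
            L = -radius * np.cos(theta) + math.sqrt(
                radius**2 * np.cos(theta) ** 2 - radius**2 + r_target**2
            )
            t = np.linspace(0.0, 1.0, n_points_per_path)
            pts = start[None, :] + (t * L)[:, None] * direction[None, :]
            d_path = L
            d_fil = L
            takeoff = np.rad2deg(theta)
        else:
            # helix about the radial axis
            a = 2.0
            omega = rng.uniform(np.pi, 3 * np.pi)
            H = math.sqrt(r_target**2 - 2 * a**2 * (1 - np.cos(omega))) - radius
            e1, e2 = _tangent_basis(u, rng)
            t = np.linspace(0.0, 1.0, n_points_per_path)
            pts = (
                start[None, :]
                + (t * H)[:, None] * u[None, :]
                + a * (np.cos(omega * t) - 1)[:, None] * e1[None, :]
                + a * np.sin(omega * t)[:, None] * e2[None, :]
            )
            d_path = math.sqrt(H**2 + a**2 * omega**2)
            d_fil = math.sqrt(H**2 + 2 * a**2 * (1 - np.cos(omega)))
            takeoff = np.rad2deg(math.acos(np.clip(H / d_fil, -1.0, 1.0)))
        d_min = r_target - radius
        pid = f"path{i:03d}"
        paths.append(TracedPath(points=pts, id=pid))
        starts.append(start)
        rows.append(
            {
                "path_id": pid,
                "d_path": d_path,
                "d_fil": d_fil,
                "d_min": d_min,
                "tortuosity": d_path / d_fil,
                "skewness": d_fil / d_min,
                "takeoff_angle": takeoff,
                "is_reacher": is_reacher,
            }
        )
    truth = pd.DataFrame(rows)
    return GlomerulusPhantom(
        glom_mask=glom,
        pec_mask=pec,
        bowman_field=bowman,
        paths=paths,
        truth_metrics=truth,
        attachment_points=np.array(starts).reshape(-1, 3),
        seed=seed,
        radius=float(radius),
        shell_gap=float(shell_gap),
    )


# ---------------------------------------------------------------------------
# Proximity (multiplexed profiling) phantom
# ---------------------------------------------------------------------------


@dataclass
class ProximityPhantom:
    """Labelled cells with per-channel expression patterns and known moments.

    ``truth_features`` columns per cell: label, group, n_voxels, distance to
    the fiber and vessel masks (mean of the respective EDT over the cell's
    voxels), and mean_ch{i} / sd_ch{i} — the exact population moments of the
    rendered voxel values under each label.
    """

    cell_labels: LabelVolume
    channel_stack: list[VolumeGrid]
    fiber_mask: MaskVolume
    vessel_mask: MaskVolume
    truth_features: pd.DataFrame
    patterns: list[str]
    seed: int


_PATTERNS = ("uniform", "nuclear", "cytoplasmic")


def make_proximity_phantom(
    shape: tuple[int, int, int] = (40, 56, 72),
    n_cells: int = 24,
    n_channels: int = 3,
    patterns: Optional[Sequence[str]] = None,
    seed: int = 0,
    spacing: Spacing = (2.0, 2.0, 2.0),
    cell_radius: float = 6.0,
    group_offsets: tuple[float, float] = (10.0, 80.0),
) -> ProximityPhantom:
    """Generate labelled spherical cells plus fiber/vessel masks.

    Channel patterns (cycled over channels if ``patterns`` is None):

    - ``uniform`` — constant value m over the whole cell (per-cell SD 0);
    - ``nuclear`` — value concentrated in the inner half-radius core, scaled
      so the per-cell mean stays m while the SD rises;
    - ``cytoplasmic`` — value confined to the outer shell, likewise
      mean-preserving.

    Cells are split into two groups placed in slabs at the two
    ``group_offsets`` distances (µm) from a straight fiber running along y, to
    exercise fiber-proximity profiling; a vessel tube runs along x near the
    opposite face.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if patterns is None:
        patterns = [_PATTERNS[i % len(_PATTERNS)] for i in range(n_channels)]
    patterns = list(patterns)
    if len(patterns) != n_channels:
        raise ValueError("patterns must have one entry per channel")
    for p in patterns:
        if p not in _PATTERNS:
            raise ValueError(f"unknown pattern {p!r}; choose from {_PATTERNS}")
    rng = np.random.default_rng(seed)

    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    # fiber along y at z = mid, x = fiber_x; vessel along x at z = mid, y near far edge
    fiber_x = 0.15 * extent[2]
    zz, yy, xx = _coordinate_grid(shape, spacing)
    tube_r = 3.0
    fiber = MaskVolume(
        (np.sqrt((zz - extent[0] / 2) ** 2 + (xx - fiber_x) ** 2) <= tube_r), spacing
    )
    vessel = MaskVolume(
        (np.sqrt((zz - extent[0] / 2) ** 2 + (yy - 0.9 * extent[1]) ** 2) <= tube_r), spacing
    )

    # two x-slabs at the requested offsets from the fiber centerline
    n_near = n_cells // 2
    groups = np.array([0] * n_near + [1] * (n_cells - n_near))
    centers = []
    placed: list[np.ndarray] = []
    tries = 0
    for g in groups:
        target_x = fiber_x + group_offsets[g]
        while True:
            tries += 1
            if tries > 20000:
                raise ValueError("could not place cells without overlap")
            cand = np.array(
                [
                    rng.uniform(cell_radius + 2, extent[0] - cell_radius - 2),
                    rng.uniform(cell_radius + 2, 0.75 * extent[1]),
                    target_x + rng.uniform(-3.0, 3.0),
                ]
            )
            if all(np.linalg.norm(cand - c) >= 2 * cell_radius + 2 for c in placed):
                placed.append(cand)
                centers.append(cand)
                break
    centers = np.array(centers)

    labels = np.zeros(shape, dtype=np.int32)
    channels = [np.zeros(shape, dtype=float) for _ in range(n_channels)]
    pts = np.stack([zz, yy, xx], axis=-1)
    for idx, c in enumerate(centers, start=1):
        d = np.linalg.norm(pts - c, axis=-1)
        cell = d <= cell_radius
        nucleus = d <= cell_radius / 2
        labels[cell] = idx
        n_tot = int(cell.sum())
        n_nuc = int(nucleus.sum())
        for ch in range(n_channels):
            m = rng.uniform(0.5, 1.5)
            pat = patterns[ch]
            if pat == "uniform":
                channels[ch][cell] = m
            elif pat == "nuclear":
                channels[ch][cell & ~nucleus] = 0.0
                channels[ch][nucleus] = m * n_tot / n_nuc
            else:  # cytoplasmic
                n_cyt = n_tot - n_nuc
                channels[ch][nucleus] = 0.0
                channels[ch][cell & ~nucleus] = m * n_tot / n_cyt

    fiber_dist = ndi.distance_transform_edt(~fiber.data, sampling=spacing)
    vessel_dist = ndi.distance_transform_edt(~vessel.data, sampling=spacing)

    rows = []
    for idx in range(1, n_cells + 1):
        sel = labels == idx
        row = {
            "label": idx,
            "group": int(groups[idx - 1]),
            "n_voxels": int(sel.sum()),
            "fiber_distance": float(fiber_dist[sel].mean()),
            "vessel_distance": float(vessel_dist[sel].mean()),
        }
        for ch in range(n_channels):
            vals = channels[ch][sel]
            row[f"mean_ch{ch}"] = float(vals.mean())
            row[f"sd_ch{ch}"] = float(vals.std())  # population SD
        rows.append(row)

    return ProximityPhantom(
        cell_labels=LabelVolume(labels, spacing),
        channel_stack=[VolumeGrid(c, spacing) for c in channels],
        fiber_mask=fiber,
        vessel_mask=vessel,
        truth_features=pd.DataFrame(rows),
        patterns=patterns,
        seed=seed,
    )
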