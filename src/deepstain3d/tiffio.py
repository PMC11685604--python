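"""Multi-page TIFF I/O with voxel-spacing metadata.

Volumes are stored planewise (z is the page axis). Spacing is written as
ImageJ-style metadata (x/y resolution + z ``spacing`` tag) so other tools can
pick it up; OME pixel-size metadata is honored on read when present.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import tifffile

from .grid import DistanceField, LabelVolume, MaskVolume, Spacing, VolumeGrid

__all__ = ["read_volume", "read_mask", "read_labels", "write_volume", "write_mask", "write_labels"]


def _spacing_from_tiff(tif: tifffile.TiffFile) -> Optional[Spacing]:
    # OME metadata first, then ImageJ
    try:
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    dx = el.get("PhysicalSizeX")
                    dy = el.get("PhysicalSizeY")
                    dz = el.get("PhysicalSizeZ")
                    if dx and dy and dz:
                        return (float(dz), float(dy), float(dx))
    except Exception:
        pass
    ij = tif.imagej_metadata
    if ij and "spacing" in ij:
        dz = float(ij["spacing"])
        page = tif.pages[0]
        dy = dx = 1.0
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                dx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                dy = den / num
        return (dz, dy, dx)
    return None


def read_volume(path, spacing: Optional[Spacing] = None) -> VolumeGrid:
    """Read a 3D TIFF stack; ``spacing`` overrides any file metadata."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if spacing is None:
            spacing = _spacing_from_tiff(tif) or (1.0, 1.0, 1.0)
    if data.ndim == 2:
        data = data[None]
    return VolumeGrid(data, spacing)


def read_mask(path, spacing: Optional[Spacing] = None) -> MaskVolume:
    vol = read_volume(path, spacing)
    return MaskVolume(vol.data > 0, vol.spacing)


def read_labels(path, spacing: Optional[Spacing] = None) -> LabelVolume:
    vol = read_volume(path, spacing)
    return LabelVolume(np.asarray(vol.data).astype(np.int32), vol.spacing)


def _write(path, data: np.ndarray, spacing: Spacing) -> None:
    dz, dy, dx = spacing
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def write_volume(path, volume: VolumeGrid | DistanceField, dtype=np.float32) -> None:
    _write(path, np.asarray(volume.data, dtype=dtype), volume.spacing)


def write_mask(path, mask: MaskVolume) -> None:
    _write(path, mask.data.astype(np.uint8), mask.spacing)


def write_labels(path, labels: LabelVolume) -> None:
    data = labels.data
    dtype = np.uint16 if data.max() < 2**16 else np.uint32
    _write(path, data.astype(dtype), labels.spacing)
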