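"""Reading SWI volumes and reconstructing windowed minimum-intensity-projection slabs.

Veins are paramagnetic (deoxyhemoglobin) and appear dark on susceptibility-weighted
magnitude images, so projecting the *minimum* intensity over a slab of contiguous axial
slices enhances them.  The default slab geometry (20 mm thickness, 1 mm gap) and the
window ranges (width 40-65, level 30-45) follow routine clinical MinIP reformatting of
0.8 x 0.8 x 1 mm SWI acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SwiVolume",
    "MinipSlab",
    "load_volume",
    "reconstruct_minip",
    "apply_window",
    "export_slabs",
]


class VolumeFormatError(ValueError):
    """The file is unreadable or is not a supported 3D volume."""


class DimensionalityError(VolumeFormatError):
    """The volume is not three-dimensional (e.g. a 2D image or a 4D time series)."""


@dataclass(frozen=True)
class SwiVolume:
    """A 3D axial SWI magnitude volume.

    ``voxels`` is indexed (slice, row, col); ``spacing_mm`` is (dz, dy, dx).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 0.8, 0.8)
    orientation: str = "axial"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {vox.ndim} dimensions"
            )
        if vox.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class MinipSlab:
    """One minimum-intensity projection over a contiguous range of axial slices."""

    pixels: np.ndarray
    slab_start_mm: float
    slab_thickness_mm: float
    slice_range: tuple[int, int]  # inclusive (first, last) source slice indices
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)  # (dy, dx)
    windowed: bool = False
    partial: bool = False

    def __post_init__(self) -> None:
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError("slab pixels must be 2D")
        if self.windowed:
            if pix.dtype != np.uint8:
                raise ValueError("a windowed slab must hold 8-bit integers")
        object.__setattr__(self, "pixels", pix)
        object.__setattr__(
            self, "pixel_spacing_mm", tuple(float(s) for s in self.pixel_spacing_mm)
        )


def load_volume(path: str | Path) -> SwiVolume:
    """Load a NIfTI volume and reorient it so axis 0 is the axial slice axis.

    The grid is brought to RAS canonical orientation first, then transposed to
    (slice, row, col) with spacing (dz, dy, dx) taken from the header zooms.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"expected a 3D volume, got shape {img.shape} in {path.name}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=float)
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    # canonical data is (x, y, z); axial slices stack along z
    voxels = np.transpose(data, (2, 1, 0))
    return SwiVolume(voxels=voxels, spacing_mm=(dz, dy, dx))


def save_volume(vol: SwiVolume, path: str | Path) -> Path:
    """Write a :class:`SwiVolume` as NIfTI (inverse of :func:`load_volume`)."""
    import nibabel as nib

    dz, dy, dx = vol.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.transpose(vol.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    path = Path(path)
    nib.save(img, str(path))
    return path


def reconstruct_minip(
    vol: SwiVolume, thickness_mm: float = 20.0, gap_mm: float = 1.0
) -> list[MinipSlab]:
    """Tile the slice axis into MinIP slabs of ``thickness_mm`` separated by ``gap_mm``.

    The stride between slab starts is ``thickness + gap`` (the gap is unprojected
    tissue between consecutive slabs, the usual reformat convention).  A trailing
    partial slab shorter than half the thickness is dropped; otherwise it is kept
    and flagged ``partial``.
    """
    dz, dy, dx = vol.spacing_mm
    if thickness_mm < dz:
        raise ValueError(f"thickness {thickness_mm} mm is below one slice ({dz} mm)")
    if gap_mm < 0:
        raise ValueError("gap must be non-negative")

    n = vol.n_slices
    t_slices = max(1, int(round(thickness_mm / dz)))
    stride = t_slices + int(round(gap_mm / dz))
    if n < t_slices:
        warnings.warn(
            f"volume has only {n} slices (< one {thickness_mm} mm slab); "
            "returning a single partial slab",
            stacklevel=2,
        )
    slabs: list[MinipSlab] = []
    start = 0
    index = 0
    while start < n:
        stop = min(start + t_slices, n)  # exclusive
        length = stop - start
        partial = length < t_slices
        if partial and slabs and length < t_slices / 2:
            break  # trailing sliver: drop
        slabs.append(
            MinipSlab(
                pixels=vol.voxels[start:stop].min(axis=0),
                slab_start_mm=start * dz,
                slab_thickness_mm=length * dz,
                slice_range=(start, stop - 1),
                pixel_spacing_mm=(dy, dx),
                partial=partial,
            )
        )
        index += 1
        start += stride
    return slabs


def apply_window(slab: MinipSlab, width: float, level: float) -> MinipSlab:
    """Linearly window a slab to 8 bits.

    Intensities at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` to 255, linearly in between with round-half-up.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    lo = level - width / 2.0
    frac = np.clip((slab.pixels - lo) / width, 0.0, 1.0)
    out = np.floor(frac * 255.0 + 0.5).astype(np.uint8)  # round half up
    return replace(slab, pixels=out, windowed=True)


def export_slabs(
    slabs: list[MinipSlab],
    directory: str | Path,
    format: str = "png",
    jpeg_quality: int = 95,
) -> list[Path]:
    """Write windowed slabs as 8-bit grayscale images named ``slab_{i:03d}``.

    PNG (lossless) is the default; JPEG reproduces the clinical export dialect
    but introduces compression artifacts that can perturb downstream masks.
    """
    from PIL import Image

    fmt = format.lower()
    if fmt not in {"png", "jpg", "jpeg"}:
        raise ValueError(f"unsupported format {format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i, slab in enumerate(slabs):
        if not slab.windowed:
            raise RuntimeError(
                f"slab {i} is not windowed; call apply_window before export"
            )
        ext = "png" if fmt == "png" else "jpg"
        out = directory / f"slab_{i:03d}.{ext}"
        img = Image.fromarray(slab.pixels, mode="L")
        if ext == "png":
            img.save(out)
        else:
            img.save(out, quality=jpeg_quality)
        paths.append(out)
    return paths
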