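"""Volumes, contour rasterization, and network-grid preprocessing.

Conventions
-----------
* Arrays are indexed ``data[i, j, k]`` with axes ``(x, y, z)`` =
  (left-right, posterior-anterior, superior-inferior); *axial* means ``z``.
* Voxel ``(i, j, k)`` has its center at ``origin + (i, j, k) * spacing`` (mm).
* Crops use half-open 0-based index ranges.

Files are read and written through SimpleITK, so NIfTI-1 (``.nii``,
``.nii.gz``) and MetaImage (``.mha``, ``.mhd``) behave identically.
SimpleITK's arrays are z-fastest-last, hence the transposes at the I/O border.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from propnet.errors import (
    DimensionalityError,
    FormatError,
    GeometryError,
    MaskTypeError,
    RoiError,
    SpecError,
)

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _is_binary(data: np.ndarray) -> bool:
    return bool(np.isin(np.unique(data), (0, 1)).all())


@dataclass
class Volume3D:
    """A 3D scalar grid with physical spacing.

    Used both for images (continuous intensities) and binary masks; the
    ``is_mask`` flag selects the interpolation rules downstream (nearest
    neighbor for masks, spline for images).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_mask: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 2:
            raise DimensionalityError(
                f"every axis needs >= 2 voxels, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if self.is_mask and not _is_binary(self.data):
            raise MaskTypeError("mask volume contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view per axis: size * spacing (mm)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def center_mm(self) -> tuple[float, float, float]:
        """Physical position of the grid center (mm)."""
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin, self.data.shape, self.spacing)
        )

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, data: np.ndarray, **kw) -> "Volume3D":
        return replace(self, data=data, **kw)


@dataclass
class ContourStack:
    """Per-axial-slice closed planar polygons in in-plane voxel coordinates.

    ``slices`` maps an axial index ``z`` to a list of polygons, each an
    ``(n, 2)`` array of ``(x, y)`` vertices.  Polygons are implicitly closed
    (last vertex connects back to the first).
    """

    slices: list[tuple[int, list[np.ndarray]]] = field(default_factory=list)

    def __post_init__(self):
        norm = []
        for z, polys in self.slices:
            arrs = []
            for p in polys:
                a = np.asarray(p, dtype=float)
                if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 3:
                    raise GeometryError(
                        "each polygon needs >= 3 (x, y) vertices; "
                        f"got shape {a.shape}"
                    )
                arrs.append(a)
            norm.append((int(z), arrs))
        self.slices = norm

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ContourStack":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [(s["z"], [np.asarray(p, float) for p in s["polygons"]])
             for s in payload["slices"]]
        )

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "slices": [
                {"z": z, "polygons": [p.tolist() for p in polys]}
                for z, polys in self.slices
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _check_power_of_two(n: int) -> bool:
    return n >= 8 and (n & (n - 1)) == 0


@dataclass
class NetworkGridSpec:
    """Geometry of the network input grid.

    The preprocessing zooms into the center of the field of view by
    ``in_plane_scale`` in x/y and ``axial_scale`` in z, then resamples onto a
    ``size``-voxel grid.  With the clinical acquisition (400 mm in-plane FOV)
    and the defaults below this yields a 200 x 200 mm2 effective in-plane FOV
    at 1.5625 mm voxels.
    """

    size: tuple[int, int, int] = (128, 128, 128)
    in_plane_scale: float = 2.0
    axial_scale: float = 1.33
    axial_margin_mm: float = 30.0

    def __post_init__(self):
        self.size = tuple(int(n) for n in self.size)
        if not all(_check_power_of_two(n) for n in self.size):
            raise SpecError(
                f"grid sizes must be powers of two >= 8, got {self.size}"
            )
        if self.in_plane_scale < 1 or self.axial_scale < 1:
            raise SpecError("scale factors must be >= 1")

    @property
    def scales(self) -> tuple[float, float, float]:
        return (self.in_plane_scale, self.in_plane_scale, self.axial_scale)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _check_ext(path: str) -> None:
    p = str(path)
    if not any(p.endswith(ext) for ext in _SUPPORTED_EXT):
        raise FormatError(
            f"unsupported volume extension for {p!r}; "
            f"expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI or MetaImage volume.

    The mask flag is set automatically when all stored values are 0/1.
    """
    _check_ext(path)
    if not os.path.exists(path) and not os.path.exists(str(path)):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path} holds a {img.GetDimension()}D payload, expected 3D"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Volume3D(
        data=data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        is_mask=_is_binary(data),
    )


def write_volume(v: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI or MetaImage (chosen by extension)."""
    _check_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, str(path))


def write_field(u: np.ndarray, spacing, path: str | os.PathLike) -> None:
    """Serialize a dense displacement field as a 4D NIfTI/MetaImage volume.

    ``u`` has shape ``(3, nx, ny, nz)`` in voxel units; the component axis is
    stored last in the file.
    """
    _check_ext(path)
    arr = np.ascontiguousarray(u.transpose(3, 2, 1, 0)).astype(np.float32)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(spacing)
    sitk.WriteImage(img, str(path))


def read_field(path: str | os.PathLike) -> np.ndarray:
    """Read a displacement field written by :func:`write_field`."""
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise DimensionalityError(f"{path} is not a 3-component field")
    return np.ascontiguousarray(arr.transpose(3, 2, 1, 0)).astype(np.float64)


# ---------------------------------------------------------------------------
# Contour rasterization
# ---------------------------------------------------------------------------

def _fill_polygon_even_odd(poly: np.ndarray, nx: int, ny: int) -> np.ndarray:
    """Even-odd scanline fill on integer voxel centers.

    A center is inside when a ray to x = -inf crosses the boundary an odd
    number of times.  Edges are counted with the half-open rule
    ``min(y1, y2) <= y < max(y1, y2)`` and spans are half-open in x
    (``x_left <= center < x_right``), so centers exactly on a shared edge
    belong to exactly one side: the standard "lower boundary" tie-break.
    """
    out = np.zeros((nx, ny), dtype=bool)
    xs, ys = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    for j in range(ny):
        y = float(j)
        lo = np.minimum(ys, y2)
        hi = np.maximum(ys, y2)
        active = (lo <= y) & (y < hi)
        if not active.any():
            continue
        x1a, y1a = xs[active], ys[active]
        x2a, y2a = x2[active], y2[active]
        cross = x1a + (y - y1a) * (x2a - x1a) / (y2a - y1a)
        cross.sort()
        for a, b in zip(cross[0::2], cross[1::2]):
            i0 = max(0, math.ceil(a))
            i1 = min(nx - 1, math.ceil(b) - 1)
            if i0 <= i1:
                out[i0 : i1 + 1, j] = True
    return out


def rasterize_contours(c: ContourStack, grid: Volume3D) -> Volume3D:
    """Convert per-slice contour polygons to a binary mask on ``grid``.

    A voxel is set iff its center lies inside any polygon of its axial slice
    under the even-odd rule (multiple overlapping polygons toggle by XOR
    within a slice entry is *not* applied: polygons are OR-ed, each filled
    even-odd on its own).
    """
    nx, ny, nz = grid.shape
    mask = np.zeros(grid.shape, dtype=np.uint8)
    for z, polys in c.slices:
        if not (0 <= z < nz):
            raise GeometryError(f"slice index {z} outside axial extent 0..{nz - 1}")
        for poly in polys:
            mask[:, :, z] |= _fill_polygon_even_odd(poly, nx, ny).astype(np.uint8)
    return Volume3D(mask, spacing=grid.spacing, origin=grid.origin, is_mask=True)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_intensities(v: Volume3D) -> Volume3D:
    """Linearly rescale intensities to span [0, 1].

    Constant volumes map to all zeros so degenerate synthetic crops do not
    kill a training pipeline.
    """
    if v.is_mask:
        raise MaskTypeError("normalize_intensities expects an image, got a mask")
    data = v.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return v.copy_with(np.zeros_like(data))
    return v.copy_with((data - lo) / (hi - lo))


def crop_axial_roi(image: Volume3D, roi_mask: Volume3D, margin_mm: float = 30.0) -> Volume3D:
    """Crop axially to the ROI's slice range expanded by ``margin_mm``.

    The in-plane extent is kept; the axial range is ``[first, last]`` mask
    slice, each side expanded by ``ceil(margin_mm / axial_spacing)`` slices
    and clipped to the volume.
    """
    if not roi_mask.is_mask:
        raise MaskTypeError("roi_mask must be a mask")
    if image.data.shape != roi_mask.data.shape:
        raise GeometryError("image and ROI mask must share the grid")
    occupied = np.flatnonzero(roi_mask.data.any(axis=(0, 1)))
    if occupied.size == 0:
        raise RoiError("ROI mask is empty")
    m = math.ceil(margin_mm / image.spacing[2])
    z0 = max(0, int(occupied[0]) - m)
    z1 = min(image.data.shape[2] - 1, int(occupied[-1]) + m)
    data = image.data[:, :, z0 : z1 + 1]
    origin = (image.origin[0], image.origin[1], image.origin[2] + z0 * image.spacing[2])
    return Volume3D(data, spacing=image.spacing, origin=origin, is_mask=image.is_mask)


def resample_to_network_grid(v: Volume3D, spec: NetworkGridSpec,
                             center_shift_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> Volume3D:
    """Zoom into the FOV center and resample onto the network grid.

    Per axis the output covers ``input extent / scale`` millimetres centered
    on the input center (optionally displaced by ``center_shift_mm``, which is
    how axial-shift robustness experiments move the cropping window), sampled
    at ``spec.size`` voxels.  Images use third-order spline interpolation,
    masks nearest neighbor.
    """
    in_extent = v.extent_mm()
    out_extent = [e / s for e, s in zip(in_extent, spec.scales)]
    for e, oe in zip(in_extent, out_extent):
        if oe > e + 1e-9:
            raise GeometryError("requested window exceeds the input extent")
    out_spacing = tuple(oe / n for oe, n in zip(out_extent, spec.size))
    center = [c + d for c, d in zip(v.center_mm(), center_shift_mm)]
    # physical position of output voxel i along an axis:
    #   center + (i - (n_out - 1)/2) * out_spacing
    coords = []
    for ax in range(3):
        i = np.arange(spec.size[ax], dtype=np.float64)
        phys = center[ax] + (i - (spec.size[ax] - 1) / 2.0) * out_spacing[ax]
        coords.append((phys - v.origin[ax]) / v.spacing[ax])  # input voxel coords
    lo = [c[0] for c in coords]
    hi = [c[-1] for c in coords]
    for ax in range(3):
        if lo[ax] < -0.5 - 1e-9 or hi[ax] > v.data.shape[ax] - 0.5 + 1e-9:
            raise GeometryError("resampling window falls outside the input volume")
    grid = np.meshgrid(*coords, indexing="ij")
    pts = np.stack(grid)
    order = 0 if v.is_mask else 3
    data = ndimage.map_coordinates(
        v.data.astype(np.float64), pts, order=order, mode="nearest"
    )
    if v.is_mask:
        data = data.astype(np.uint8)
    origin = tuple(
        c - (n - 1) / 2.0 * s for c, n, s in zip(center, spec.size, out_spacing)
    )
    return Volume3D(data, spacing=out_spacing, origin=origin, is_mask=v.is_mask)
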