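"""Spatial transforms, dense displacement fields, warping, and folding.

All transforms map *output* (fixed-grid) voxel coordinates to *input*
(moving-image) voxel coordinates — the pull/backward convention:
``warped(x) = input(T(x))`` with displacement ``u(x) = T(x) - x`` in voxel
units.  Composition ``T = c1 ∘ c2`` means ``T(x) = c1(c2(x))``, so warping an
image once by the composite equals warping by ``c1`` first and then by ``c2``.

The free-form deformations are cubic B-spline lattices: a grid of ``n``
control points per axis is placed equidistantly over the voxel extent
(spacing ``(D - 1) / (n - 1)``) and the displacement at a point is the
tensor-product cubic B-spline sum of the control vectors, with the
coefficient lattice edge-replicated beyond its borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from propnet.errors import LatticeError, MaskTypeError, RegionError, ShapeError
from propnet.volume import Volume3D

try:  # jitted kernel for the hot path; scipy path is the reference fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=False)
    def _ffd_eval_kernel(cpad, t, out):  # pragma: no cover - compiled
        """Tensor-product cubic B-spline sum over a padded coefficient lattice.

        cpad: (m1, m2, m3, 3); t: (3, N) lattice coords already offset by the
        pad; out: (3, N).  Matches spline interpolation without prefiltering.
        """
        m = cpad.shape
        n = t.shape[1]
        w = np.empty((3, 4))
        base = np.empty(3, dtype=np.int64)
        for p in range(n):
            for ax in range(3):
                tc = t[ax, p]
                if tc < 0.0:
                    tc = 0.0
                hi = m[ax] - 1.0
                if tc > hi:
                    tc = hi
                fl = int(np.floor(tc))
                if fl < 1:
                    fl = 1
                if fl > m[ax] - 3:
                    fl = m[ax] - 3
                f = tc - fl
                f2 = f * f
                f3 = f2 * f
                w[ax, 0] = (1.0 - 3.0 * f + 3.0 * f2 - f3) / 6.0
                w[ax, 1] = (4.0 - 6.0 * f2 + 3.0 * f3) / 6.0
                w[ax, 2] = (1.0 + 3.0 * f + 3.0 * f2 - 3.0 * f3) / 6.0
                w[ax, 3] = f3 / 6.0
                base[ax] = fl - 1
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for a in range(4):
                wa = w[0, a]
                ia = base[0] + a
                for b in range(4):
                    wab = wa * w[1, b]
                    ib = base[1] + b
                    for c in range(4):
                        wabc = wab * w[2, c]
                        ic = base[2] + c
                        s0 += wabc * cpad[ia, ib, ic, 0]
                        s1 += wabc * cpad[ia, ib, ic, 1]
                        s2 += wabc * cpad[ia, ib, ic, 2]
            out[0, p] = s0
            out[1, p] = s1
            out[2, p] = s2

Extent = Sequence[int]


def _grid_points(shape) -> np.ndarray:
    """Voxel-coordinate grid, shape (3, *shape)."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


# ---------------------------------------------------------------------------
# Transform types
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rotation about the grid center followed by translation (voxels).

    The rotation matrix is ``Rz @ Ry @ Rx`` built from the three angles
    (radians, about the x, y, z axes through the grid center).
    """

    angles: tuple[float, float, float]
    translation: tuple[float, float, float]
    extent: tuple[int, int, int]

    def matrix(self) -> np.ndarray:
        ax, ay, az = self.angles
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def map(self, pts: np.ndarray) -> np.ndarray:
        c = (np.asarray(self.extent, float) - 1) / 2.0
        r = self.matrix()
        flat = pts.reshape(3, -1)
        out = r @ (flat - c[:, None]) + c[:, None] + np.asarray(self.translation)[:, None]
        return out.reshape(pts.shape)


@dataclass
class BSplineTransform:
    """Cubic B-spline free-form deformation on an equidistant control lattice."""

    coefficients: np.ndarray  # (n1, n2, n3, 3) control displacements, voxels
    extent: tuple[int, int, int]

    _PAD = 3  # edge-replication depth; > cubic kernel support so interior code paths run

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise LatticeError("coefficients must have shape (n1, n2, n3, 3)")
        if min(self.coefficients.shape[:3]) < 2:
            raise LatticeError("control lattice needs >= 2 points per axis")
        p = self._PAD
        self._padded = np.pad(
            self.coefficients, ((p, p), (p, p), (p, p), (0, 0)), mode="edge"
        )

    @property
    def grid_size(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    def _lattice_coords(self, pts: np.ndarray) -> np.ndarray:
        h = [
            (d - 1) / (n - 1)
            for d, n in zip(self.extent, self.grid_size)
        ]
        flat = pts.reshape(3, -1)
        return flat / np.asarray(h)[:, None]

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        """Displacement u at arbitrary voxel coordinates, shape like ``pts``.

        Evaluated as the B-spline basis expansion of the coefficients:
        ``map_coordinates(order=3, prefilter=False, mode='nearest')`` computes
        exactly the tensor-product sum with edge-replicated coefficients.
        """
        t = self._lattice_coords(pts) + self._PAD
        if _HAVE_NUMBA:
            out = np.empty_like(t)
            _ffd_eval_kernel(self._padded, np.ascontiguousarray(t), out)
            return out.reshape(pts.shape)
        u = np.empty_like(t)
        for comp in range(3):
            u[comp] = ndimage.map_coordinates(
                self._padded[..., comp], t, order=3,
                prefilter=False, mode="nearest",
            )
        return u.reshape(pts.shape)

    def map(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)


@dataclass
class ScalingTransform:
    """Per-axis scaling of coordinates anchored at the grid center.

    ``T(x) = c + factors * (x - c)``; under the pull convention a factor
    below 1 magnifies the image content (zoom/crop) and the Jacobian of the
    mapping is ``diag(factors)``.
    """

    factors: tuple[float, float, float]
    extent: tuple[int, int, int]

    def __post_init__(self):
        if any(f <= 0 for f in self.factors):
            raise ShapeError("scaling factors must be positive")

    def map(self, pts: np.ndarray) -> np.ndarray:
        c = (np.asarray(self.extent, float) - 1) / 2.0
        f = np.asarray(self.factors, float)
        flat = pts.reshape(3, -1)
        return (c[:, None] + f[:, None] * (flat - c[:, None])).reshape(pts.shape)


@dataclass
class CompositeTransform:
    """Ordered composition ``T = c1 ∘ c2 ∘ ... ∘ cn`` with ``T(x) = c1(c2(...cn(x)))``."""

    components: list

    def __post_init__(self):
        if not self.components:
            raise ShapeError("composite transform needs >= 1 component")

    def map(self, pts: np.ndarray) -> np.ndarray:
        out = pts
        for t in reversed(self.components):
            out = t.map(out)
        return out


Transform = Union[RigidTransform, BSplineTransform, ScalingTransform, CompositeTransform]


@dataclass
class DisplacementField:
    """Dense displacement u = (ux, uy, uz) in voxel units on an output grid."""

    u: np.ndarray  # (3, nx, ny, nz)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ShapeError("displacement field must have shape (3, nx, ny, nz)")
        if not np.isfinite(self.u).all():
            raise ShapeError("displacement field contains non-finite values")

    @property
    def grid_size(self) -> tuple[int, int, int]:
        return self.u.shape[1:]


# ---------------------------------------------------------------------------
# Sampling the random transforms
# ---------------------------------------------------------------------------

def sample_bspline(grid_size, amplitude: float, extent, rng: np.random.Generator) -> BSplineTransform:
    """Draw a B-spline deformation with iid Uniform(-amplitude, amplitude) coefficients."""
    grid_size = tuple(int(n) for n in np.broadcast_to(grid_size, (3,)))
    if min(grid_size) < 2:
        raise LatticeError(f"control lattice needs >= 2 points per axis, got {grid_size}")
    if amplitude < 0:
        raise LatticeError("amplitude must be >= 0")
    coeffs = rng.uniform(-amplitude, amplitude, size=grid_size + (3,))
    return BSplineTransform(coefficients=coeffs, extent=tuple(extent))


#: (lattice points per axis, coefficient amplitude in voxels) for the four
#: concatenated stages of the learned transformation, coarse to fine, on the
#: 128-voxel network grid.
LEARNED_STAGES = ((2, 6.4), (4, 3.2), (8, 1.6), (16, 0.8))


def sample_learned_transform(extent, rng: np.random.Generator,
                             stages=LEARNED_STAGES, amplitude_scale: float = 1.0) -> CompositeTransform:
    """The ground-truth deformation the network learns: t1 ∘ t2 ∘ t3 ∘ t4.

    Four B-spline stages on lattices of 2, 4, 8, 16 points per axis with
    amplitudes 6.4, 3.2, 1.6, 0.8 voxels; ``amplitude_scale`` shrinks them
    proportionally for reduced-resolution grids.
    """
    comps = [
        sample_bspline(g, a * amplitude_scale, extent, rng) for g, a in stages
    ]
    return CompositeTransform(comps)


def sample_augmentation_transform(extent, rng: np.random.Generator,
                                  max_angle: float = 0.1,
                                  max_translation: float = 12.8,
                                  bspline_grid: int = 2,
                                  bspline_amplitude: float = 6.4,
                                  amplitude_scale: float = 1.0) -> CompositeTransform:
    """Augmentation deformation: small random rigid motion plus a coarse B-spline.

    Angles ~ U(-0.1, 0.1) radians, translations ~ U(-12.8, 12.8) voxels,
    followed by a 2x2x2 B-spline of 6.4-voxel amplitude (all scalable).
    """
    angles = tuple(rng.uniform(-max_angle, max_angle, size=3))
    trans = tuple(rng.uniform(-max_translation * amplitude_scale,
                              max_translation * amplitude_scale, size=3))
    rigid = RigidTransform(angles=angles, translation=trans, extent=tuple(extent))
    bsp = sample_bspline(bspline_grid, bspline_amplitude * amplitude_scale, extent, rng)
    return CompositeTransform([rigid, bsp])


# ---------------------------------------------------------------------------
# Dense fields, composition, warping
# ---------------------------------------------------------------------------

def to_dense_field(t: Transform, grid) -> DisplacementField:
    """Evaluate ``u(x) = T(x) - x`` on every voxel of ``grid`` (dims triple).

    Composites are evaluated as the exact composed coordinate mapping, so the
    dense field incurs no intermediate resampling.
    """
    pts = _grid_points(grid)
    return DisplacementField(t.map(pts) - pts)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Dense-field composition under the pull convention.

    ``u12(x) = u_inner(x) + u_outer(x + u_inner(x))`` with the outer field
    interpolated linearly; warping once by the result equals warping by
    ``outer`` first and then by ``inner``.
    """
    if outer.grid_size != inner.grid_size:
        raise ShapeError("composed fields must share the grid")
    pts = _grid_points(inner.grid_size) + inner.u
    out = np.empty_like(inner.u)
    for comp in range(3):
        out[comp] = ndimage.map_coordinates(
            outer.u[comp], pts, order=1, mode="nearest"
        )
    return DisplacementField(out + inner.u)


def _as_field(t, grid) -> DisplacementField:
    if isinstance(t, DisplacementField):
        if t.grid_size != tuple(grid):
            raise ShapeError("field grid does not match the volume grid")
        return t
    return to_dense_field(t, grid)


def warp_image(v: Volume3D, t, order: int = 3, fill: float = 0.0) -> Volume3D:
    """Pull-warp an image: ``out(x) = in(x + u(x))`` with spline interpolation.

    Out-of-grid samples take ``fill``.  Masks must go through
    :func:`warp_mask` (order-0) instead.
    """
    if v.is_mask and order > 0:
        raise MaskTypeError("masks must be warped with warp_mask (nearest neighbor)")
    f = _as_field(t, v.data.shape)
    pts = _grid_points(v.data.shape) + f.u
    data = ndimage.map_coordinates(
        v.data.astype(np.float64), pts, order=order, mode="grid-constant",
        cval=fill,
    )
    return v.copy_with(data)


def warp_mask(m: Volume3D, t) -> Volume3D:
    """Pull-warp a binary mask with nearest-neighbor sampling; outside -> 0."""
    if not m.is_mask:
        raise MaskTypeError("warp_mask expects a mask volume")
    f = _as_field(t, m.data.shape)
    pts = _grid_points(m.data.shape) + f.u
    data = ndimage.map_coordinates(
        m.data.astype(np.float64), pts, order=0, mode="grid-constant", cval=0.0
    )
    return m.copy_with(data.astype(np.uint8))


def jacobian_determinant(f: DisplacementField) -> np.ndarray:
    """Per-voxel determinant of the Jacobian of ``x -> x + u(x)``.

    Gradients use central differences in the interior and one-sided
    differences on the faces, in voxel units; det < 1 is compression,
    det < 0 is folding.
    """
    if min(f.grid_size) < 3:
        raise ShapeError("Jacobian needs >= 3 voxels per axis")
    j = np.empty((3, 3) + tuple(f.grid_size))
    for comp in range(3):
        grads = np.gradient(f.u[comp], axis=(0, 1, 2))
        for ax in range(3):
            j[comp, ax] = grads[ax]
            if comp == ax:
                j[comp, ax] = j[comp, ax] + 1.0
    a, b, c = j[0]
    d, e, g = j[1]
    h, i, k = j[2]
    return a * (e * k - g * i) - b * (d * k - g * h) + c * (d * i - e * h)


def folding_fraction(f: DisplacementField, region: np.ndarray | Volume3D | None = None) -> float:
    """Percentage of voxels with a strictly negative Jacobian determinant."""
    det = jacobian_determinant(f)
    if region is None:
        sel = np.ones(det.shape, dtype=bool)
    else:
        reg = region.data if isinstance(region, Volume3D) else np.asarray(region)
        if reg.shape != det.shape:
            raise ShapeError("region grid does not match the field grid")
        sel = reg.astype(bool)
    n = int(sel.sum())
    if n == 0:
        raise RegionError("folding region is empty")
    return 100.0 * float((det[sel] < 0).sum()) / n
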