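"""Synthetic pelvic phantoms and training-pair manufacture.

No clinical scans ship with the package, so phantom "patients" stand in for
them: a bright ellipsoidal prostate-like target centered in the field of
view, a fluid-bright bladder analog superior-anterior to it, a dark rectum
analog posterior, band-limited background texture, and additive noise.  The
appearance only needs to give a registration network exploitable contrast at
the target boundary; it makes no attempt at MR physics.

Inter-fraction variation reuses the augmentation-scale random transforms
(small rigid motion plus a coarse free-form deformation) applied to the same
underlying anatomy, which is also how the clinical workflow this emulates
sees its day-to-day changes: one anatomy, smoothly deformed.

Training pairs follow the synthetic-supervision recipe: from a volume ``I``
with mask ``S``, draw an augmentation transform ``T_augm`` and a learned
transform ``T_learned``; the network sees ``I(T_augm)`` and
``I(T_augm ∘ T_learned)`` and must recover the dense field of ``T_learned``.
Both warps use the exact composed coordinate mapping, so each output image is
interpolated exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, special

from propnet.errors import InputError, SpecError
from propnet.transforms import (
    CompositeTransform,
    DisplacementField,
    _grid_points,
    sample_augmentation_transform,
    sample_learned_transform,
    warp_image,
    warp_mask,
)
from propnet.volume import Volume3D


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pelvic phantom.

    Defaults emulate the clinical network grid: 128^3 voxels over a
    200 x 200 x 120 mm3 field of view with the prostate-like target centered.
    """

    grid: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.5625, 1.5625, 0.9375)
    prostate_semiaxes: tuple[float, float, float] = (20.0, 17.0, 19.0)  # mm
    bladder: bool = True
    rectum: bool = True
    texture_scale: float = 12.0      # mm, correlation length of the background
    texture_amplitude: float = 0.15  # intensity fraction
    noise_sigma: float = 0.02        # intensity fraction
    prostate_intensity: float = 0.55
    background_intensity: float = 0.25
    edge_sharpness: float = 8.0      # steepness of the target's boundary profile

    def __post_init__(self):
        self.grid = tuple(int(n) for n in self.grid)
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        extent = [n * s for n, s in zip(self.grid, self.spacing)]
        for semi, e in zip(self.prostate_semiaxes, extent):
            if semi > e / 6.0:
                raise SpecError(
                    "prostate semiaxes must fit inside the central third of "
                    f"the grid (semiaxis {semi} mm vs extent {e} mm)"
                )

    @property
    def amplitude_scale(self) -> float:
        """Deformation amplitudes are stated on a 128-voxel grid; scale down
        proportionally on smaller grids so geometry is preserved."""
        return self.grid[0] / 128.0


@dataclass
class PatientRecord:
    """One phantom patient: a pretreatment scan plus daily fraction scans."""

    patient_id: str
    pretreatment: tuple[Volume3D, Volume3D]           # (image, CTV mask)
    fractions: list[tuple[Volume3D, Volume3D]]
    provenance: list[CompositeTransform] = field(default_factory=list)

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)


@dataclass
class TrainingSample:
    """One supervised registration problem manufactured from a volume pair."""

    moving_image: Volume3D   # I(T_augm), normalized
    fixed_image: Volume3D    # I(T_augm ∘ T_learned), normalized
    moving_mask: Volume3D    # S(T_augm)
    target_mask: Volume3D    # S(T_augm ∘ T_learned)
    target_field: DisplacementField  # dense field of T_learned, voxel units


def _ellipsoid_level(spec: PhantomSpec, center_mm, semiaxes_mm) -> np.ndarray:
    """Implicit ellipsoid value rho = sum(((p - c)/a)^2) on voxel centers."""
    axes = [
        (np.arange(n) * s - c)
        for n, s, c in zip(spec.grid, spec.spacing, center_mm)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    a, b, c = semiaxes_mm
    return (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2


def _soft_edge(rho: np.ndarray, sharpness: float) -> np.ndarray:
    """Smooth 1-inside/0-outside profile, exactly 0.5 on the surface rho=1."""
    return special.expit(sharpness * (1.0 - rho))


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> tuple[Volume3D, Volume3D]:
    """Generate one phantom image and its exact CTV mask.

    The image is clipped to [0, 1]; the mask is the strict-interior
    rasterization of the target ellipsoid on voxel centers.  Deterministic
    given the generator state.
    """
    center = [(n - 1) / 2.0 * s for n, s in zip(spec.grid, spec.spacing)]
    rho = _ellipsoid_level(spec, center, spec.prostate_semiaxes)
    mask = (rho < 1.0).astype(np.uint8)

    img = np.full(spec.grid, spec.background_intensity, dtype=np.float64)
    if spec.texture_amplitude > 0:
        noise = rng.standard_normal(spec.grid)
        sig = [spec.texture_scale / s for s in spec.spacing]
        tex = ndimage.gaussian_filter(noise, sig)
        std = tex.std()
        if std > 0:
            img += spec.texture_amplitude * tex / std

    img += spec.prostate_intensity * _soft_edge(rho, spec.edge_sharpness)

    if spec.bladder:
        # fluid-bright, superior and slightly anterior to the target
        bc = (
            center[0],
            center[1] + 0.20 * spec.grid[1] * spec.spacing[1],
            center[2] - 0.25 * spec.grid[2] * spec.spacing[2],
        )
        brho = _ellipsoid_level(spec, bc, tuple(1.4 * s for s in spec.prostate_semiaxes))
        img += 0.45 * _soft_edge(brho, spec.edge_sharpness / 2.0)
    if spec.rectum:
        # dark tube posterior to the target, running axially
        rc = (center[0], center[1] - 0.18 * spec.grid[1] * spec.spacing[1], center[2])
        rrho = _ellipsoid_level(
            spec, rc,
            (0.45 * spec.prostate_semiaxes[0], 0.45 * spec.prostate_semiaxes[1],
             0.48 * spec.grid[2] * spec.spacing[2]),
        )
        img -= 0.2 * _soft_edge(rrho, spec.edge_sharpness / 2.0)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.grid)

    img = np.clip(img, 0.0, 1.0)
    image = Volume3D(img, spacing=spec.spacing, is_mask=False)
    ctv = Volume3D(mask, spacing=spec.spacing, is_mask=True)
    return image, ctv


def generate_patient(spec: PhantomSpec, n_fractions: int,
                     rng: np.random.Generator, patient_id: str = "phantom") -> PatientRecord:
    """Generate a phantom patient: pretreatment scan plus deformed fractions.

    Each fraction warps the same anatomy by an independent augmentation-scale
    transform (rigid + coarse B-spline); provenance records the true
    transforms so experiments can reason about the ground truth motion.
    """
    if n_fractions < 1:
        raise SpecError("n_fractions must be >= 1")
    image, mask = generate_phantom(spec, rng)
    fractions, provenance = [], []
    scale = spec.amplitude_scale
    for _ in range(n_fractions):
        t = sample_augmentation_transform(spec.grid, rng, amplitude_scale=scale)
        fimg = warp_image(image, t, order=3)
        fimg = fimg.copy_with(np.clip(fimg.data, 0.0, 1.0))
        fmask = warp_mask(mask, t)
        fractions.append((fimg, fmask))
        provenance.append(t)
    return PatientRecord(
        patient_id=patient_id,
        pretreatment=(image, mask),
        fractions=fractions,
        provenance=provenance,
    )


def make_training_sample(image: Volume3D, mask: Volume3D, rng: np.random.Generator,
                         amplitude_scale: Optional[float] = None) -> TrainingSample:
    """Manufacture one supervised registration problem from (image, mask).

    Draws a fresh augmentation transform and learned transform per call so
    every training iteration sees a unique pair.  The fixed image is produced
    by the single-interpolation concatenation ``I(T_augm ∘ T_learned)``.
    """
    if image.data.min() < 0 or image.data.max() > 1:
        raise InputError("training images must be normalized to [0, 1]")
    if not mask.is_mask:
        raise InputError("training mask must be a binary mask volume")
    grid = image.data.shape
    if amplitude_scale is None:
        amplitude_scale = grid[0] / 128.0

    t_augm = sample_augmentation_transform(grid, rng, amplitude_scale=amplitude_scale)
    t_learned = sample_learned_transform(grid, rng, amplitude_scale=amplitude_scale)

    # One exact coordinate evaluation per output: the fixed image samples the
    # original anatomy at T_augm(T_learned(x)) = T_augm(x + u_learned(x)),
    # reusing the dense learned field that also supervises the network.
    pts = _grid_points(grid)
    target_field = DisplacementField(t_learned.map(pts) - pts)
    coords_moving = t_augm.map(pts)
    coords_fixed = t_augm.map(pts + target_field.u)

    img64 = image.data.astype(np.float64)
    moving = image.copy_with(np.clip(
        ndimage.map_coordinates(img64, coords_moving, order=3,
                                mode="grid-constant"), 0.0, 1.0))
    fixed = image.copy_with(np.clip(
        ndimage.map_coordinates(img64, coords_fixed, order=3,
                                mode="grid-constant"), 0.0, 1.0))
    moving_mask = mask.copy_with(ndimage.map_coordinates(
        mask.data.astype(np.float64), coords_moving, order=0,
        mode="grid-constant",
    ).astype(np.uint8))
    # The target mask is the moving mask pulled through the target field: the
    # supervision is then exactly achievable by a perfect field prediction.
    target_mask = warp_mask(moving_mask, target_field)
    return TrainingSample(
        moving_image=moving,
        fixed_image=fixed,
        moving_mask=moving_mask,
        target_mask=target_mask,
        target_field=target_field,
    )
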