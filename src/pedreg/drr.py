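"""Digitally reconstructed radiographs by exact-path raycasting.

A DRR is rendered by casting one virtual X-ray per detector pixel from
the source through the pixel centre and accumulating linear attenuation
along the ray (Beer-Lambert law):

    I = I0 * exp(-sum_i mu_i * l_i)

where ``l_i`` is the exact intersection length of the ray with voxel
``i`` (Siddon's radiological path, not fixed-step sampling) and the
attenuation coefficient of a voxel is derived from its CT number:

    mu = mu_water * (1000 + HU) / 1000, clamped at 0.

The default ``mu_water = 0.02 / mm`` corresponds to an effective CT
energy in the 60-80 keV range; it rescales all line integrals jointly
and therefore does not affect geometry-driven results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    CameraGeometry,
    Pose6D,
    pose_to_transform,
)

MU_WATER_DEFAULT = 0.02  # 1/mm

# Intensity semantics a ProjectionImage may carry.
LINE_INTEGRAL = "line_integral"
TRANSMITTED_FRACTION = "transmitted_fraction"
RADIOGRAPH_DISPLAY = "radiograph_display"


class DegenerateRayError(ValueError):
    """Raised for a zero-length ray."""


@dataclass
class CTVolume:
    """CT voxel grid in Hounsfield units.

    ``voxels[i, j, k]`` corresponds to world axes (x, y, z); ``origin``
    is the world position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def world_min(self) -> np.ndarray:
        """World coordinate of the lower corner of the voxel grid's bounding box."""
        return self.origin - self.spacing / 2.0

    @property
    def world_max(self) -> np.ndarray:
        return self.world_min + np.array(self.shape) * self.spacing

    @property
    def center(self) -> np.ndarray:
        return (self.world_min + self.world_max) / 2.0

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class ProjectionImage:
    """2D projection with explicit intensity semantics.

    ``pixels[v, u]`` (row = v, column = u).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    intensity_semantics: str = TRANSMITTED_FRACTION

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")


def hu_to_mu(hu, mu_water: float = MU_WATER_DEFAULT):
    """Linear attenuation coefficient (1/mm) from Hounsfield units.

    Water (0 HU) maps to ``mu_water``, air (-1000 HU) to 0; values below
    -1000 HU clamp to zero attenuation.
    """
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    hu = np.asarray(hu, dtype=float)
    mu = (1000.0 + hu) / 1000.0 * mu_water
    return np.maximum(mu, 0.0)


def _siddon_batch(
    mu: np.ndarray,
    world_min: np.ndarray,
    spacing: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact radiological path integrals for a batch of ray segments.

    Parameters are in the volume's world frame; ``p0``/``p1`` are
    ``(N, 3)`` segment endpoints.  Returns ``(integrals, chord_lengths)``
    where ``chord_lengths`` is the geometric length of each segment's
    intersection with the volume bounding box (Siddon conservation:
    the per-voxel lengths sum to the chord).
    """
    n_vox = np.array(mu.shape)
    d = p1 - p0
    seg_len = np.linalg.norm(d, axis=1)
    eps = 1e-12

    # Slab clipping of the parameter range [0, 1] to the volume box.
    amin = np.zeros(len(p0))
    amax = np.ones(len(p0))
    box_lo = world_min
    box_hi = world_min + n_vox * spacing
    for a in range(3):
        da = d[:, a]
        pa = p0[:, a]
        parallel = np.abs(da) < eps
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (box_lo[a] - pa) / da
            t1 = (box_hi[a] - pa) / da
        lo = np.minimum(t0, t1)
        hi = np.maximum(t0, t1)
        inside = (pa >= box_lo[a]) & (pa <= box_hi[a])
        lo = np.where(parallel, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(parallel, np.where(inside, np.inf, -np.inf), hi)
        amin = np.maximum(amin, lo)
        amax = np.minimum(amax, hi)

    hit = amax > amin + eps
    integrals = np.zeros(len(p0))
    chords = np.where(hit, (amax - amin) * seg_len, 0.0)
    if not np.any(hit):
        return integrals, chords

    idx = np.flatnonzero(hit)
    p0h, dh = p0[idx], d[idx]
    aminh, amaxh = amin[idx], amax[idx]

    # All boundary-plane crossings per axis, clipped into [amin, amax].
    parts = [aminh[:, None], amaxh[:, None]]
    for a in range(3):
        planes = box_lo[a] + spacing[a] * np.arange(n_vox[a] + 1)
        da = dh[:, a : a + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            al = (planes[None, :] - p0h[:, a : a + 1]) / da
        al = np.where(np.abs(da) < eps, aminh[:, None], al)
        al = np.clip(al, aminh[:, None], amaxh[:, None])
        parts.append(al)
    alphas = np.sort(np.concatenate(parts, axis=1), axis=1)

    lengths = np.diff(alphas, axis=1) * seg_len[idx, None]
    mids = alphas[:, :-1] + np.diff(alphas, axis=1) / 2.0
    # Voxel index of every segment midpoint.
    pts = p0h[:, None, :] + mids[:, :, None] * dh[:, None, :]
    vox = np.floor((pts - world_min) / spacing).astype(np.int64)
    valid = (lengths > eps) & np.all((vox >= 0) & (vox < n_vox), axis=2)
    vox = np.clip(vox, 0, n_vox - 1)
    mu_vals = mu[vox[..., 0], vox[..., 1], vox[..., 2]]
    integrals[idx] = np.sum(np.where(valid, mu_vals * lengths, 0.0), axis=1)
    return integrals, chords


def cast_ray(
    volume: CTVolume,
    entry,
    exit,
    mu_water: float = MU_WATER_DEFAULT,
) -> float:
    """Line integral ``sum_i mu_i l_i`` along the segment entry -> exit (mm).

    Points are in the volume's world frame.  Rays missing the volume
    return 0 (so the transmitted fraction is exactly ``I0``).
    """
    p0 = np.asarray(entry, dtype=float).reshape(1, 3)
    p1 = np.asarray(exit, dtype=float).reshape(1, 3)
    if np.linalg.norm(p1 - p0) < 1e-12:
        raise DegenerateRayError("zero-length ray")
    mu = hu_to_mu(volume.voxels, mu_water)
    integ, _ = _siddon_batch(mu, volume.world_min, volume.spacing, p0, p1)
    return float(integ[0])


def ray_chord_lengths(volume: CTVolume, p0, p1) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic helper: (path integral, bounding-box chord length) per ray."""
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    mu = hu_to_mu(volume.voxels)
    return _siddon_batch(mu, volume.world_min, volume.spacing, p0, p1)


def render_drr(
    volume: CTVolume,
    camera: CameraGeometry,
    pose: Pose6D = Pose6D(),
    rotation_center=None,
    mu_water: float = MU_WATER_DEFAULT,
    i0: float = 1.0,
    chunk_rays: int = 8192,
) -> ProjectionImage:
    """Render a DRR of ``volume`` posed by ``pose`` onto ``camera``.

    The pose moves the volume into the camera world frame; equivalently
    each ray (source -> pixel centre) is pulled back into the volume's
    native grid with the inverse transform, where the exact radiological
    path is accumulated.  Deterministic for fixed inputs.
    """
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    if rotation_center is None:
        rotation_center = volume.center
    T = pose_to_transform(pose, rotation_center)
    Tinv = T.inverse()

    nu, nv = camera.detector_size_u, camera.detector_size_v
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv))
    du = (uu.ravel() - camera.principal_pixel[0]) * camera.pixel_spacing_u
    dv = (vv.ravel() - camera.principal_pixel[1]) * camera.pixel_spacing_v
    det_pts = (
        camera.cop
        + du[:, None] * camera.detector_u_axis
        + dv[:, None] * camera.detector_v_axis
    )

    # Warn if the posed volume sits entirely behind the source plane.
    corners = np.array(
        [
            [x, y, z]
            for x in (volume.world_min[0], volume.world_max[0])
            for y in (volume.world_min[1], volume.world_max[1])
            for z in (volume.world_min[2], volume.world_max[2])
        ]
    )
    axis = camera.axis
    t_corners = (T.apply(corners) - camera.source) @ axis
    if np.all(t_corners <= 0):
        warnings.warn("volume entirely behind the X-ray source; DRR is uniform I0")
        return ProjectionImage(
            np.full((nv, nu), i0),
            (camera.pixel_spacing_u, camera.pixel_spacing_v),
            TRANSMITTED_FRACTION,
        )

    mu = hu_to_mu(volume.voxels, mu_water)
    src_vol = Tinv.apply(camera.source)
    integrals = np.empty(nu * nv)
    for lo in range(0, nu * nv, chunk_rays):
        hi = min(lo + chunk_rays, nu * nv)
        p1 = Tinv.apply(det_pts[lo:hi])
        p0 = np.broadcast_to(src_vol, p1.shape)
        integrals[lo:hi], _ = _siddon_batch(
            mu, volume.world_min, volume.spacing, np.ascontiguousarray(p0), p1
        )
    pixels = i0 * np.exp(-integrals).reshape(nv, nu)
    return ProjectionImage(
        pixels,
        (camera.pixel_spacing_u, camera.pixel_spacing_v),
        TRANSMITTED_FRACTION,
    )


def to_display(image: ProjectionImage, i0: float = 1.0) -> ProjectionImage:
    """Map transmitted fractions to a radiograph-style display in [0, 1].

    Applies ``-log(I / I0)`` (so denser tissue is brighter, as in the
    usual inverted fluoroscopy display) and rescales the maximum to 1.
    Order-reversing in ``I``; a uniform image maps to uniform zero.
    """
    if image.intensity_semantics != TRANSMITTED_FRACTION:
        raise ValueError("to_display expects transmitted_fraction semantics")
    li = -np.log(np.clip(image.pixels / i0, 1e-300, None))
    li -= li.min()
    top = li.max()
    if top > 0:
        li = li / top
    return ProjectionImage(li, image.pixel_spacing, RADIOGRAPH_DISPLAY)
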