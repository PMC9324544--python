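"""Synthetic digital vertebra phantom and two-view radiograph simulator.

No public clinical data accompany this problem, so every pipeline stage
is exercised against a geometric-primitive phantom: a vertebral body
(ellipsoid) with two pedicles (cylinders) and a spinous process (box)
embedded in a soft-tissue ellipsoid surrounded by air, all in Hounsfield
units.  A 30 mm radio-opaque linear marker is inserted along a planned
transverse-pedicular trajectory, and AP/lateral radiographs are
simulated at a known ground-truth pose, together with exact (optionally
noise-corrupted) 2D landmark and marker annotations.

The phantom carries the two landmark sets the clinical protocol uses:
pedicle centres, inferior spinous process and body centroid for the AP
view; the four vertebral body corners (midsagittal) and the body
centroid for the lateral view.

Annotation noise is injected in 2D only — imprecise landmark
identification on the radiographs is the dominant error source the
framework is exposed to — and is drawn per view from independent
seeded generators, so the AP and lateral errors are decorrelated as
they would be for two separately annotated radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drr import CTVolume, ProjectionImage, render_drr
from .geometry import (
    CameraGeometry,
    Pose6D,
    detector_point_to_pixel,
    make_camera,
    pose_to_transform,
    project_points,
)
from .registration import AP_PROTOCOL_LANDMARKS, LATERAL_PROTOCOL_LANDMARKS


class PhantomError(ValueError):
    """Phantom geometry does not fit the requested volume."""


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the digital vertebra.

    Distances in mm, intensities in HU.  Defaults produce an
    80 x 100 x 60 mm volume at 1 mm isotropic spacing with tissue values
    in standard ranges (trabecular/cortical bone mix ~ +700, soft tissue
    ~ +40, metal marker ~ +3000, air -1000).
    """

    shape: tuple = (80, 100, 60)
    spacing: tuple = (1.0, 1.0, 1.0)
    body_center: tuple = (40.0, 62.0, 30.0)
    body_semiaxes: tuple = (20.0, 16.0, 11.0)
    soft_semiaxes: tuple = (36.0, 46.0, 27.0)
    pedicle_radius: float = 5.0
    pedicle_length: float = 12.0
    pedicle_offset_x: float = 13.0
    tpa_deg: float = 10.0
    spinous_length: float = 18.0
    spinous_halfwidth: float = 3.0
    spinous_halfheight: float = 6.0
    hu_bone: float = 700.0
    hu_marker: float = 3000.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    marker_length: float = 30.0
    marker_radius: float = 1.5
    noise_sd_hu: float = 0.0
    seed: int = 0

    @property
    def pedicle_center_y(self) -> float:
        """Pedicles sit just posterior of the body's posterior surface."""
        return self.body_center[1] - self.body_semiaxes[1] - self.pedicle_length / 2.0

    def pedicle_center(self, side: str) -> np.ndarray:
        sign = -1.0 if side.upper() == "L" else 1.0
        return np.array(
            [
                self.body_center[0] + sign * self.pedicle_offset_x,
                self.pedicle_center_y,
                self.body_center[2],
            ]
        )


def _world_grids(spec: PhantomSpec):
    sx, sy, sz = spec.spacing
    nx, ny, nz = spec.shape
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def make_vertebra_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, dict]:
    """Build the phantom volume and its named 3D landmark set (CT frame, mm).

    Deterministic for a fixed spec (including its noise seed).
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    extent = np.array(spec.shape) * np.array(spec.spacing)
    cx, cy, cz = spec.body_center
    ax, ay, az = spec.body_semiaxes

    if (
        cx - ax < 0 or cx + ax > extent[0]
        or cy - ay < 0 or cy + ay > extent[1]
        or cz - az < 0 or cz + az > extent[2]
    ):
        raise PhantomError("vertebral body exceeds the volume extent")

    X, Y, Z = _world_grids(spec)
    vol = np.full(spec.shape, spec.hu_air)

    soft = (
        ((X - cx) / spec.soft_semiaxes[0]) ** 2
        + ((Y - cy + 10.0) / spec.soft_semiaxes[1]) ** 2
        + ((Z - cz) / spec.soft_semiaxes[2]) ** 2
    ) <= 1.0
    vol[soft] = spec.hu_soft

    body = (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2) <= 1.0
    vol[body] = spec.hu_bone

    y0 = spec.pedicle_center_y - spec.pedicle_length / 2.0
    y1 = spec.pedicle_center_y + spec.pedicle_length / 2.0
    for side in ("L", "R"):
        pc = spec.pedicle_center(side)
        if pc[0] - spec.pedicle_radius < 0 or pc[0] + spec.pedicle_radius > extent[0]:
            raise PhantomError("pedicle exceeds the volume extent")
        ped = (
            ((X - pc[0]) ** 2 + (Z - pc[2]) ** 2 <= spec.pedicle_radius**2)
            & (Y >= y0)
            & (Y <= y1)
        )
        vol[ped] = spec.hu_bone

    sp_y1 = y0
    sp_y0 = sp_y1 - spec.spinous_length
    if sp_y0 < 0:
        raise PhantomError("spinous process exceeds the volume extent")
    spin = (
        (np.abs(X - cx) <= spec.spinous_halfwidth)
        & (Y >= sp_y0)
        & (Y <= sp_y1)
        & (np.abs(Z - cz) <= spec.spinous_halfheight)
    )
    vol[spin] = spec.hu_bone

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=vol.shape)

    s2 = 1.0 / np.sqrt(2.0)
    landmarks = {
        "body_centroid": np.array([cx, cy, cz]),
        "pedicle_center_L": spec.pedicle_center("L"),
        "pedicle_center_R": spec.pedicle_center("R"),
        "spinous_inferior": np.array([cx, sp_y0 + 1.0, cz - spec.spinous_halfheight]),
        # Midsagittal body "corners" at 45 degrees on the (y, z) ellipse:
        # 1 = anterior-superior, 2 = anterior-inferior,
        # 3 = posterior-superior, 4 = posterior-inferior.
        "body_corner_1": np.array([cx, cy + ay * s2, cz + az * s2]),
        "body_corner_2": np.array([cx, cy + ay * s2, cz - az * s2]),
        "body_corner_3": np.array([cx, cy - ay * s2, cz + az * s2]),
        "body_corner_4": np.array([cx, cy - ay * s2, cz - az * s2]),
    }
    volume = CTVolume(vol, np.array(spec.spacing), np.zeros(3))
    return volume, landmarks


def plan_trajectory(
    spec: PhantomSpec, side: str = "L"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plan the screw axis: entry, pedicle cross point and target.

    The trajectory is a straight line through the pedicle centre (the
    pedicle cross point) at the transverse pedicular angle (TPA) in the
    axial plane, starting lateral-posterior and advancing anteromedially;
    it is kept parallel to the body endplates (zero craniocaudal tilt).
    """
    side = side.upper()
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    if abs(spec.tpa_deg) >= 45.0:
        raise PhantomError(f"TPA {spec.tpa_deg} deg incompatible with pedicle geometry")
    cross = spec.pedicle_center(side)
    medial = 1.0 if side == "L" else -1.0
    a = np.radians(spec.tpa_deg)
    direction = np.array([medial * np.sin(a), np.cos(a), 0.0])
    half = spec.marker_length / 2.0
    entry = cross - half * direction
    target = cross + half * direction
    return entry, cross, target


def insert_marker(
    volume: CTVolume,
    entry,
    direction,
    length: float = 30.0,
    radius: float = 1.5,
    hu: float = 3000.0,
) -> tuple[CTVolume, np.ndarray, np.ndarray]:
    """Paint a cylindrical radio-opaque marker into a copy of the volume.

    Returns the new volume and the exact head (entry) and tail
    coordinates; ``|head - tail|`` equals ``length`` by construction.
    """
    entry = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    head = entry
    tail = entry + length * d

    lo, hi = volume.world_min, volume.world_max
    for p in (head, tail):
        if np.any(p < lo + radius) or np.any(p > hi - radius):
            raise PhantomError(f"marker endpoint {p} outside the volume")

    nx, ny, nz = volume.shape
    xs = volume.origin[0] + np.arange(nx) * volume.spacing[0]
    ys = volume.origin[1] + np.arange(ny) * volume.spacing[1]
    zs = volume.origin[2] + np.arange(nz) * volume.spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    w = P - head
    s = np.clip(w @ d, 0.0, length)
    dist = np.linalg.norm(w - s[..., None] * d, axis=-1)
    vox = volume.voxels.copy()
    vox[dist <= radius] = hu
    return CTVolume(vox, volume.spacing.copy(), volume.origin.copy()), head, tail


@dataclass
class CArmRig:
    """A consistent two-view C-arm setup around one isocenter."""

    ap: CameraGeometry
    lat: CameraGeometry
    isocenter: np.ndarray

    def camera(self, view: str) -> CameraGeometry:
        return self.ap if view == "ap" else self.lat


def default_rig(
    isocenter,
    sdd_mm: float = 1000.0,
    source_to_iso_mm: float = 550.0,
    detector_size_px=(160, 160),
    pixel_spacing_mm=(1.6, 1.6),
) -> CArmRig:
    """AP + lateral rig with ~1.8x magnification at the isocenter."""
    iso = np.asarray(isocenter, dtype=float)
    ap = make_camera("ap", sdd_mm, source_to_iso_mm, detector_size_px, pixel_spacing_mm, iso)
    lat = make_camera("lat", sdd_mm, source_to_iso_mm, detector_size_px, pixel_spacing_mm, iso)
    return CArmRig(ap=ap, lat=lat, isocenter=iso)


@dataclass
class GroundTruth:
    """Exact simulation state: poses, 3D/2D landmarks and marker ends.

    Projecting the 3D entries at the true pose reproduces the exact 2D
    entries to numerical precision (before any annotation noise).
    """

    pose: dict  # view -> Pose6D (same physical patient position)
    rotation_center: np.ndarray
    landmarks3d: dict
    landmarks2d_exact: dict  # view -> {name: pixel}
    marker_head3d: np.ndarray
    marker_tail3d: np.ndarray
    marker2d_exact: dict  # view -> {"head": px, "tail": px}


@dataclass
class SimulatedCase:
    """One synthetic surgical case: volume, images, annotations, truth."""

    volume: CTVolume
    rig: CArmRig
    images: dict  # view -> ProjectionImage or None
    landmarks2d: dict  # view -> {name: pixel}, noise applied
    marker2d: dict  # view -> {"head": px, "tail": px}, noise applied
    truth: GroundTruth
    seed: int


def _project_to_pixels(points: dict, pose: Pose6D, camera, rotation_center) -> dict:
    T = pose_to_transform(pose, rotation_center)
    names = list(points)
    pts = T.apply(np.array([points[k] for k in names], dtype=float))
    proj, t = project_points(camera, pts)
    if np.any(t <= 0):
        raise PhantomError("simulated geometry places points behind the source")
    out = {}
    for i, k in enumerate(names):
        px, _ = detector_point_to_pixel(camera, proj[i])
        out[k] = px
    return out


def simulate_views(
    volume: CTVolume,
    landmarks3d: dict,
    marker_head3d,
    marker_tail3d,
    rig: CArmRig,
    true_pose: Pose6D = Pose6D(),
    rotation_center=None,
    landmark_noise_px: float = 0.0,
    seed: int = 0,
    render: bool = True,
) -> SimulatedCase:
    """Simulate the AP and lateral views of a posed phantom.

    The same rigid pose is applied for both views (one physical patient
    position seen by a consistent rig).  2D annotations are the exact
    projections of the 3D truth plus optional Gaussian pixel noise drawn
    independently per view.  Fully deterministic for a fixed seed.
    """
    marker_head3d = np.asarray(marker_head3d, dtype=float)
    marker_tail3d = np.asarray(marker_tail3d, dtype=float)
    if rotation_center is None:
        rotation_center = np.mean(
            [np.asarray(p, float) for p in landmarks3d.values()], axis=0
        )
    rotation_center = np.asarray(rotation_center, dtype=float)

    protocol = {"ap": AP_PROTOCOL_LANDMARKS, "lat": LATERAL_PROTOCOL_LANDMARKS}
    landmarks2d_exact, marker2d_exact = {}, {}
    images = {}
    for view in ("ap", "lat"):
        cam = rig.camera(view)
        sub3d = {k: landmarks3d[k] for k in protocol[view] if k in landmarks3d}
        landmarks2d_exact[view] = _project_to_pixels(
            sub3d, true_pose, cam, rotation_center
        )
        marker2d_exact[view] = _project_to_pixels(
            {"head": marker_head3d, "tail": marker_tail3d},
            true_pose,
            cam,
            rotation_center,
        )
        images[view] = (
            render_drr(volume, cam, true_pose, rotation_center) if render else None
        )

    landmarks2d, marker2d = {}, {}
    for i, view in enumerate(("ap", "lat")):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        landmarks2d[view] = {
            k: v + rng.normal(0.0, landmark_noise_px, 2) if landmark_noise_px > 0 else v.copy()
            for k, v in landmarks2d_exact[view].items()
        }
        marker2d[view] = {
            k: v + rng.normal(0.0, landmark_noise_px, 2) if landmark_noise_px > 0 else v.copy()
            for k, v in marker2d_exact[view].items()
        }

    truth = GroundTruth(
        pose={"ap": true_pose, "lat": true_pose},
        rotation_center=rotation_center,
        landmarks3d={k: np.asarray(v, float) for k, v in landmarks3d.items()},
        landmarks2d_exact=landmarks2d_exact,
        marker_head3d=marker_head3d,
        marker_tail3d=marker_tail3d,
        marker2d_exact=marker2d_exact,
    )
    return SimulatedCase(
        volume=volume,
        rig=rig,
        images=images,
        landmarks2d=landmarks2d,
        marker2d=marker2d,
        truth=truth,
        seed=seed,
    )


def make_case(
    spec: PhantomSpec | None = None,
    rig: CArmRig | None = None,
    true_pose: Pose6D = Pose6D(2.0, -3.0, 1.5, 4.0, -3.0, 2.0),
    landmark_noise_px: float = 0.0,
    seed: int = 0,
    side: str = "L",
    render: bool = False,
) -> SimulatedCase:
    """Convenience constructor: phantom + marker + simulated views."""
    spec = spec or PhantomSpec()
    volume, landmarks = make_vertebra_phantom(spec)
    entry, _, target = plan_trajectory(spec, side)
    direction = target - entry
    volume, head, tail = insert_marker(
        volume,
        entry,
        direction,
        length=spec.marker_length,
        radius=spec.marker_radius,
        hu=spec.hu_marker,
    )
    if rig is None:
        rig = default_rig(volume.center)
    return simulate_views(
        volume,
        landmarks,
        head,
        tail,
        rig,
        true_pose=true_pose,
        landmark_noise_px=landmark_noise_px,
        seed=seed,
        render=render,
    )
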