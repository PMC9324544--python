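"""Stage II: marker trajectory mapping from two registered views.

The head and tail ends of a 30 mm radio-opaque marker are annotated on
the AP and lateral radiographs.  Each annotation is back-projected into
the CT frame as a virtual X-ray (the line through the view's source and
the annotated detector point, pulled back by the inverse of that view's
registered pose).  Because the two single-view registrations are never
perfectly consistent, the AP and lateral rays for one marker end rarely
intersect; the corresponding 3D point is taken as the midpoint of the
shortest segment connecting the two rays, and the residual line-to-line
distance (the "gap") is reported per end as a registration quality cue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .drr import CTVolume
from .geometry import (
    CameraGeometry,
    Pose6D,
    detector_point_to_pixel,
    pixel_to_detector_point,
    pose_to_transform,
    project_point,
)


class DegenerateTriangulationError(ValueError):
    """Rays too close to parallel for a stable closest-point solution."""


@dataclass
class Ray3D:
    """Infinite line with unit direction, in the CT world frame."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("ray direction must be nonzero")
        self.direction = d / n

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction

    def distance_to_point(self, p) -> float:
        w = np.asarray(p, dtype=float) - self.origin
        return float(np.linalg.norm(w - (w @ self.direction) * self.direction))


@dataclass
class Trajectory3D:
    """Triangulated marker trajectory in CT world coordinates.

    ``head_gap``/``tail_gap`` are the shortest distances between the AP
    and lateral back-projection rays at each end.
    """

    head: np.ndarray
    tail: np.ndarray
    head_gap: float
    tail_gap: float

    def __post_init__(self):
        self.head = np.asarray(self.head, dtype=float).reshape(3)
        self.tail = np.asarray(self.tail, dtype=float).reshape(3)
        if self.head_gap < 0 or self.tail_gap < 0:
            raise ValueError("gaps must be non-negative")
        if np.linalg.norm(self.head - self.tail) <= 0:
            raise ValueError("trajectory must have positive length")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.head - self.tail))


def backproject_pixel(
    camera: CameraGeometry,
    pose: Pose6D,
    pixel,
    rotation_center,
) -> Ray3D:
    """Back-project a detector pixel into the CT frame as a virtual X-ray.

    The ray runs through the view's source and the pixel's detector
    point; both are pulled back by the inverse of the registered pose so
    that any CT point projecting to ``pixel`` lies on the ray.
    """
    T = pose_to_transform(pose, rotation_center)
    Tinv = T.inverse()
    det = pixel_to_detector_point(camera, pixel)
    origin = Tinv.apply(camera.source)
    direction = Tinv.rotation @ (det - camera.source)
    return Ray3D(origin, direction)


def closest_point_between_rays(
    ray_a: Ray3D, ray_b: Ray3D, min_angle_deg: float = 0.1
) -> tuple[np.ndarray, float]:
    """Midpoint of the shortest segment between two lines, and its length.

    Treats the rays as infinite lines; symmetric under argument swap.
    Near-parallel pairs (angle below ``min_angle_deg``) are rejected —
    the closest-point problem becomes ill-conditioned there.
    """
    d1, d2 = ray_a.direction, ray_b.direction
    cross = np.cross(d1, d2)
    angle = np.degrees(np.arctan2(np.linalg.norm(cross), abs(float(d1 @ d2))))
    if angle < min_angle_deg:
        raise DegenerateTriangulationError(
            f"rays nearly parallel ({angle:.4f} deg): "
            f"a=({ray_a.origin}, {ray_a.direction}), "
            f"b=({ray_b.origin}, {ray_b.direction})"
        )
    w0 = ray_a.origin - ray_b.origin
    b = float(d1 @ d2)
    d = float(d1 @ w0)
    e = float(d2 @ w0)
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    p1 = ray_a.point_at(s)
    p2 = ray_b.point_at(t)
    gap = float(np.linalg.norm(p1 - p2))
    return (p1 + p2) / 2.0, gap


def map_trajectory(
    ap_head_px,
    ap_tail_px,
    lat_head_px,
    lat_tail_px,
    ap_camera: CameraGeometry,
    lat_camera: CameraGeometry,
    ap_pose: Pose6D,
    lat_pose: Pose6D,
    ap_rotation_center,
    lat_rotation_center=None,
) -> Trajectory3D:
    """Triangulate the marker head and tail from two annotated views.

    Head/tail correspondence across views is by label; if swapping the
    lateral labels would shrink both gaps, a warning flags a likely
    annotation swap.
    """
    if lat_rotation_center is None:
        lat_rotation_center = ap_rotation_center
    ap_head = backproject_pixel(ap_camera, ap_pose, ap_head_px, ap_rotation_center)
    ap_tail = backproject_pixel(ap_camera, ap_pose, ap_tail_px, ap_rotation_center)
    lat_head = backproject_pixel(lat_camera, lat_pose, lat_head_px, lat_rotation_center)
    lat_tail = backproject_pixel(lat_camera, lat_pose, lat_tail_px, lat_rotation_center)

    head, head_gap = closest_point_between_rays(ap_head, lat_head)
    tail, tail_gap = closest_point_between_rays(ap_tail, lat_tail)

    try:
        _, g1 = closest_point_between_rays(ap_head, lat_tail)
        _, g2 = closest_point_between_rays(ap_tail, lat_head)
        if g1 < head_gap and g2 < tail_gap:
            warnings.warn(
                "swapping the lateral head/tail labels reduces both inter-ray "
                "gaps; the lateral annotations may be swapped"
            )
    except DegenerateTriangulationError:
        pass

    # Physical plausibility: the triangulated points should sit between
    # source and detector of both views (in each view's camera frame).
    for name, pt in (("head", head), ("tail", tail)):
        for cam, pose, ctr in (
            (ap_camera, ap_pose, ap_rotation_center),
            (lat_camera, lat_pose, lat_rotation_center),
        ):
            p_cam = pose_to_transform(pose, ctr).apply(pt)
            t = float((p_cam - cam.source) @ cam.axis) / cam.sdd
            if not 0.0 < t < 1.0:
                warnings.warn(
                    f"triangulated {name} lies outside the {cam.label or 'view'} "
                    f"source-detector span (t = {t:.3f})"
                )
    return Trajectory3D(head=head, tail=tail, head_gap=head_gap, tail_gap=tail_gap)


def reproject_trajectory(
    traj: Trajectory3D,
    camera: CameraGeometry,
    pose: Pose6D,
    rotation_center,
) -> np.ndarray:
    """Project a 3D trajectory back onto a view; returns ``[[head], [tail]]`` px.

    Raises :class:`pedreg.geometry.OutOfFrustumError` if an endpoint
    falls behind the source.
    """
    T = pose_to_transform(pose, rotation_center)
    out = []
    for pt in (traj.head, traj.tail):
        det = project_point(camera, T.apply(pt))
        px, _ = detector_point_to_pixel(camera, det)
        out.append(px)
    return np.array(out)


def cumulate_axial_slices(volume: CTVolume, z_range, mode: str = "sum") -> np.ndarray:
    """Collapse a range of axial slices into one 2D image for overlays.

    ``z_range`` is ``(k0, k1)`` inclusive voxel indices along z; the
    result is indexed ``[i, j]`` = (x, y).  Used to display a trajectory
    whose endpoints span multiple axial slices on a single image.
    """
    k0, k1 = int(z_range[0]), int(z_range[1])
    nz = volume.shape[2]
    if not (0 <= k0 <= k1 < nz):
        raise ValueError(f"z range ({k0}, {k1}) empty or outside volume (nz={nz})")
    block = volume.voxels[:, :, k0 : k1 + 1]
    if mode == "sum":
        return block.sum(axis=2)
    if mode == "mean":
        return block.mean(axis=2)
    raise ValueError(f"unknown mode {mode!r}; use 'sum' or 'mean'")
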