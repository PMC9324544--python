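"""Rigid transforms and the C-arm pinhole projection model.

The C-arm is modelled as an ideal point X-ray source ``S`` and a planar
detector.  The central ray from ``S`` meets the detector orthogonally at
the centre of projection (COP) ``P``; the distance ``|SP|`` is the
source-to-detector distance (SDD, the focal length of the projector).
A 3D object point ``O`` located between source and detector projects to

    P_proj = P - M * (D - O)

where ``D`` is the orthogonal projection of ``O`` onto the central axis
``S -> P`` and ``M = SDD / |SD|`` is the local magnification.  This is
algebraically the intersection of the line ``S -> O`` with the detector
plane, but it is implemented in exactly this axis/magnification form so
the magnification factor is available as a first-class quantity.

Conventions
-----------
* World frame: right-handed, millimetres, CT axes
  (x: left -> right, y: posterior -> anterior, z: inferior -> superior).
* Poses are six parameters: three rotations in degrees applied in
  intrinsic Z-Y-X order about an explicit rotation centre, followed by a
  translation in mm.
* Pixel coordinates are 0-based with the pixel-centre convention;
  ``u`` indexes detector columns, ``v`` detector rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Base class for projection-geometry failures."""


class DegenerateGeometryError(GeometryError):
    """Ray or configuration is degenerate (e.g. object point at the source)."""


class OutOfFrustumError(GeometryError):
    """Object point lies at or behind the X-ray source."""


def _vec3(x, name: str = "point") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class Pose6D:
    """Rigid pose as three rotations (degrees) and three translations (mm).

    Rotations are applied in intrinsic Z-Y-X order about a rotation centre
    supplied when the pose is converted to a :class:`RigidTransform`.
    """

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta_x, self.theta_y, self.theta_z, self.t_x, self.t_y, self.t_z]
        )

    @staticmethod
    def from_array(a) -> "Pose6D":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError("pose array must have 6 entries")
        return Pose6D(*a.tolist())

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation matrix for the intrinsic Z-Y-X Euler angles."""
        return Rotation.from_euler(
            "ZYX", [self.theta_z, self.theta_y, self.theta_x], degrees=True
        ).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation acting as ``x -> R x + t`` (homogeneous form)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _vec3(self.translation, "translation")
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points) -> np.ndarray:
        """Transform a point ``(3,)`` or an array of points ``(N, 3)``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other``, i.e. apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def pose_to_transform(pose: Pose6D, rotation_center) -> RigidTransform:
    """Build the rigid map ``x -> R (x - c) + c + t`` for rotation centre ``c``.

    The rotation centre is typically the centroid of the cropped vertebra
    (or of its landmark set) so that rotation and translation parameters
    stay well conditioned during optimization.
    """
    c = _vec3(rotation_center, "rotation_center")
    R = pose.rotation_matrix()
    t = np.array([pose.t_x, pose.t_y, pose.t_z])
    return RigidTransform(R, c + t - R @ c)


@dataclass
class CameraGeometry:
    """Calibrated C-arm projector.

    Attributes
    ----------
    source : (3,) mm
        X-ray point source ``S``.
    cop : (3,) mm
        Centre of projection ``P`` — the detector point hit by the central
        ray; ``S -> P`` is orthogonal to the detector plane and
        ``|S - P|`` is the source-to-detector distance.
    detector_u_axis, detector_v_axis : (3,) unit vectors
        In-plane detector axes (columns / rows).
    pixel_spacing_u, pixel_spacing_v : mm / pixel
    detector_size_u, detector_size_v : pixels
    principal_pixel : (2,)
        Pixel coordinate of the COP; defaults to the detector centre.
    label : str
        View name, e.g. ``"ap"`` or ``"lat"``.
    """

    source: np.ndarray
    cop: np.ndarray
    detector_u_axis: np.ndarray
    detector_v_axis: np.ndarray
    pixel_spacing_u: float
    pixel_spacing_v: float
    detector_size_u: int
    detector_size_v: int
    principal_pixel: np.ndarray = None
    label: str = ""

    def __post_init__(self):
        self.source = _vec3(self.source, "source")
        self.cop = _vec3(self.cop, "cop")
        self.detector_u_axis = _vec3(self.detector_u_axis, "detector_u_axis")
        self.detector_v_axis = _vec3(self.detector_v_axis, "detector_v_axis")
        if self.principal_pixel is None:
            self.principal_pixel = np.array(
                [(self.detector_size_u - 1) / 2.0, (self.detector_size_v - 1) / 2.0]
            )
        self.principal_pixel = np.asarray(self.principal_pixel, dtype=float)
        for name in ("detector_u_axis", "detector_v_axis"):
            ax = getattr(self, name)
            n = np.linalg.norm(ax)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise GeometryError(f"{name} must be a unit vector (norm {n:.3g})")
        if abs(self.detector_u_axis @ self.detector_v_axis) > 1e-6:
            raise GeometryError("detector axes must be orthogonal")
        axis = self.cop - self.source
        sdd = np.linalg.norm(axis)
        if sdd <= 0:
            raise GeometryError("source-to-detector distance must be positive")
        if (
            abs(axis @ self.detector_u_axis) > 1e-6 * sdd
            or abs(axis @ self.detector_v_axis) > 1e-6 * sdd
        ):
            raise GeometryError("central axis S->P must be orthogonal to the detector")
        if self.pixel_spacing_u <= 0 or self.pixel_spacing_v <= 0:
            raise GeometryError("pixel spacing must be positive")

    @property
    def sdd(self) -> float:
        """Source-to-detector distance (mm)."""
        return float(np.linalg.norm(self.cop - self.source))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the central ray S -> P."""
        a = self.cop - self.source
        return a / np.linalg.norm(a)


def make_camera(
    view: str,
    sdd_mm: float,
    source_to_iso_mm: float,
    detector_size_px,
    pixel_spacing_mm,
    isocenter_mm=(0.0, 0.0, 0.0),
    principal_pixel=None,
) -> CameraGeometry:
    """Place an AP or lateral C-arm camera around an isocenter.

    AP: source posterior of the patient, central ray along +y.
    Lateral: source on the patient's left, central ray along +x.
    """
    iso = _vec3(isocenter_mm, "isocenter")
    size = np.asarray(detector_size_px, dtype=int)
    spacing = np.asarray(pixel_spacing_mm, dtype=float)
    if np.isscalar(pixel_spacing_mm):
        spacing = np.array([pixel_spacing_mm, pixel_spacing_mm], dtype=float)
    view = view.lower()
    if view in ("ap", "pa"):
        axis = np.array([0.0, 1.0, 0.0])
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0])
    elif view in ("lat", "lateral"):
        axis = np.array([1.0, 0.0, 0.0])
        u = np.array([0.0, 1.0, 0.0])
        v = np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError(f"unknown view {view!r}; expected 'ap' or 'lat'")
    if not 0 < source_to_iso_mm < sdd_mm:
        raise GeometryError("need 0 < source_to_iso_mm < sdd_mm")
    source = iso - source_to_iso_mm * axis
    cop = source + sdd_mm * axis
    return CameraGeometry(
        source=source,
        cop=cop,
        detector_u_axis=u,
        detector_v_axis=v,
        pixel_spacing_u=float(spacing[0]),
        pixel_spacing_v=float(spacing[1]),
        detector_size_u=int(size[0]),
        detector_size_v=int(size[1]),
        principal_pixel=principal_pixel,
        label=view,
    )


def project_points(camera: CameraGeometry, points) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised projection of ``(N, 3)`` points onto the detector plane.

    Returns ``(projected, t)`` where ``projected`` is ``(N, 3)`` detector
    points (mm) and ``t`` the normalised axial coordinate of each point
    (0 at the source, 1 at the detector).  No validity checks are applied;
    callers decide how to treat ``t <= 0`` (behind the source) or
    ``t >= 1`` (beyond the detector).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    S, P = camera.source, camera.cop
    SP = P - S
    sdd2 = SP @ SP
    SO = pts - S
    t = SO @ SP / sdd2
    with np.errstate(divide="ignore", invalid="ignore"):
        D = S + t[:, None] * SP
        SOB = np.linalg.norm(D - S, axis=1)
        M = np.sqrt(sdd2) / SOB
        proj = P - M[:, None] * (D - pts)
    return proj, t


def project_point(camera: CameraGeometry, object_point) -> np.ndarray:
    """Project one 3D point onto the detector plane (mm).

    Raises
    ------
    DegenerateGeometryError
        If the object point coincides with the source.
    OutOfFrustumError
        If the point lies at or behind the source plane (``t <= 0``).
    """
    O = _vec3(object_point, "object_point")
    if np.linalg.norm(O - camera.source) < 1e-9:
        raise DegenerateGeometryError("object point coincides with the X-ray source")
    proj, t = project_points(camera, O)
    t = float(t[0])
    if t <= 0:
        raise OutOfFrustumError(f"object point behind the source (t = {t:.3g})")
    if t >= 1:
        warnings.warn(
            "object point beyond the detector plane (t >= 1); projection "
            "continued with magnification < 1",
            stacklevel=2,
        )
    return proj[0]


def magnification(camera: CameraGeometry, object_point) -> float:
    """Magnification ``M = SDD / |S -> D|`` of an object point.

    ``D`` is the orthogonal projection of the object point onto the
    central axis; ``M >= 1`` for points between source and detector.
    """
    O = _vec3(object_point, "object_point")
    S, P = camera.source, camera.cop
    SP = P - S
    t = (SP @ (O - S)) / (SP @ SP)
    if t <= 0:
        raise OutOfFrustumError(f"object point behind the source (t = {t:.3g})")
    D = S + t * SP
    return float(np.linalg.norm(SP) / np.linalg.norm(D - S))


def detector_point_to_pixel(
    camera: CameraGeometry, point
) -> tuple[np.ndarray, bool]:
    """Convert a detector-plane point (mm) to a pixel coordinate.

    Returns ``(pixel, in_bounds)``; points off the detector extent are
    returned with ``in_bounds = False`` rather than raising.
    """
    p = _vec3(point, "detector point")
    rel = p - camera.cop
    u_mm = rel @ camera.detector_u_axis
    v_mm = rel @ camera.detector_v_axis
    px = camera.principal_pixel + np.array(
        [u_mm / camera.pixel_spacing_u, v_mm / camera.pixel_spacing_v]
    )
    in_bounds = bool(
        -0.5 <= px[0] <= camera.detector_size_u - 0.5
        and -0.5 <= px[1] <= camera.detector_size_v - 0.5
    )
    return px, in_bounds


def pixel_to_detector_point(camera: CameraGeometry, pixel) -> np.ndarray:
    """Inverse of :func:`detector_point_to_pixel`: pixel -> 3D point (mm)."""
    px = np.asarray(pixel, dtype=float)
    if px.shape != (2,):
        raise ValueError("pixel must be a 2-vector (u, v)")
    du = (px[0] - camera.principal_pixel[0]) * camera.pixel_spacing_u
    dv = (px[1] - camera.principal_pixel[1]) * camera.pixel_spacing_v
    return camera.cop + du * camera.detector_u_axis + dv * camera.detector_v_axis
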