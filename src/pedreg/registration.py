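"""Stage I: per-vertebra pose estimation from anatomical landmarks.

A small set of corresponding landmarks is identified in the CT volume
(3D, mm) and on each radiograph (2D, px) — typically the pedicle
centroids, the inferior end of the spinous process and the vertebral
body centroid in the AP view, and the four vertebral body corners plus
the centroid in the lateral view.  The six rigid pose parameters are
then estimated by minimising the mean Projection Distance Error

    mPDE = (1/N) sum_k || project(T . P3D_k) - P2D_k ||

with CMA-ES (population 50, evaluation budget 2000 by default).  The
cost needs only N point projections per evaluation — no DRR is rendered
inside the optimisation loop, which is what makes the approach fast
enough for intraoperative use.

Single-view registration has a weakly identifiable depth component:
translations along the central ray change the projection only through
magnification.  Two-view consistency is therefore assessed downstream
when the marker trajectory is triangulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .drr import CTVolume
from .geometry import (
    CameraGeometry,
    Pose6D,
    detector_point_to_pixel,
    pixel_to_detector_point,
    pose_to_transform,
    project_points,
)
from .optim import cma_es_minimize

# Landmark sets the clinical protocol recommends per view (subject to
# end-on-view quality; any keyed correspondence set is accepted).
AP_PROTOCOL_LANDMARKS = (
    "pedicle_center_L",
    "pedicle_center_R",
    "spinous_inferior",
    "body_centroid",
)
LATERAL_PROTOCOL_LANDMARKS = (
    "body_corner_1",
    "body_corner_2",
    "body_corner_3",
    "body_corner_4",
    "body_centroid",
)

_FRUSTUM_PENALTY = 1.0e6


class CorrespondenceError(ValueError):
    """Projected and target landmark sets do not share the same keys."""


class UnderdeterminedError(ValueError):
    """Fewer than three landmark correspondences."""


@dataclass
class OptConfig:
    """CMA-ES settings for a registration run.

    ``search_halfwidth``, when set, gives the per-parameter search
    half-width (degrees for the three rotations, mm for the three
    translations); the initial step size is one third of it.  When left
    ``None`` the step size is chosen per case from the initial
    projection discrepancy (see :func:`derive_sigma0`), mirroring the
    clinical practice of sizing the search distribution by how far the
    initial projection is from the radiograph.  ``tol_mm`` implements
    the "zero mPDE" stopping rule — exact zero being unattainable in
    floating point.
    """

    popsize: int = 50
    max_evals: int = 2000
    tol_mm: float = 1e-3
    search_halfwidth: tuple | None = None
    seed: int = 0


@dataclass
class RegistrationResult:
    pose: Pose6D
    rotation_center: np.ndarray
    final_mpde: float
    n_evaluations: int
    converged: bool
    seed: int
    trace: list = field(default_factory=list)  # (eval_index, pose_params, mpde)

    def best_so_far(self) -> np.ndarray:
        """Running minimum of mPDE over the trace (non-increasing)."""
        vals = np.array([t[2] for t in self.trace])
        return np.minimum.accumulate(vals)


def crop_vertebra(volume: CTVolume, bounding_box) -> CTVolume:
    """Extract the sub-volume of one vertebra, preserving world coordinates.

    ``bounding_box`` is ``((i0, i1), (j0, j1), (k0, k1))`` half-open voxel
    index ranges.  The origin of the crop is shifted so every retained
    voxel keeps its world position — cropping therefore commutes with
    projection.
    """
    (i0, i1), (j0, j1), (k0, k1) = [(int(a), int(b)) for a, b in bounding_box]
    shape = volume.shape
    if not (0 <= i0 < i1 <= shape[0] and 0 <= j0 < j1 <= shape[1] and 0 <= k0 < k1 <= shape[2]):
        raise ValueError(f"bounding box {bounding_box} empty or outside volume {shape}")
    sub = volume.voxels[i0:i1, j0:j1, k0:k1].copy()
    origin = volume.voxel_center((i0, j0, k0))
    return CTVolume(sub, volume.spacing.copy(), origin)


def mpde(projected: dict, target: dict) -> float:
    """Mean Projection Distance Error between two keyed 2D point sets (mm)."""
    if set(projected) != set(target):
        raise CorrespondenceError(
            f"key mismatch: {sorted(set(projected) ^ set(target))}"
        )
    if not projected:
        raise CorrespondenceError("empty landmark sets")
    d = [
        np.linalg.norm(np.asarray(projected[k], float) - np.asarray(target[k], float))
        for k in projected
    ]
    return float(np.mean(d))


def project_landmarks(
    landmarks3d: dict,
    pose: Pose6D,
    camera: CameraGeometry,
    rotation_center=None,
) -> dict:
    """Pose then project a keyed 3D landmark set; returns pixels per key.

    Landmarks that fall at or behind the source are excluded with a
    warning rather than raising, so a partial set can still be displayed.
    """
    if rotation_center is None:
        rotation_center = np.mean([np.asarray(p, float) for p in landmarks3d.values()], axis=0)
    T = pose_to_transform(pose, rotation_center)
    names = list(landmarks3d)
    pts = T.apply(np.array([landmarks3d[k] for k in names], dtype=float))
    proj, t = project_points(camera, pts)
    out = {}
    for i, name in enumerate(names):
        if t[i] <= 0:
            warnings.warn(f"landmark {name!r} out of frustum (t={t[i]:.3g}); excluded")
            continue
        px, _ = detector_point_to_pixel(camera, proj[i])
        out[name] = px
    return out


def _target_detector_points(landmarks2d: dict, camera: CameraGeometry) -> dict:
    return {k: pixel_to_detector_point(camera, v) for k, v in landmarks2d.items()}


def _make_cost(landmarks3d, landmarks2d, camera, rotation_center):
    """mPDE (detector mm) as a function of the 6 pose parameters.

    Poses that throw any landmark behind the source get a large penalty
    that grows with the violation, steering the optimizer back into the
    frustum.
    """
    names = sorted(landmarks2d)
    p3 = np.array([landmarks3d[k] for k in names], dtype=float)
    p2 = np.array(
        [pixel_to_detector_point(camera, landmarks2d[k]) for k in names], dtype=float
    )
    center = np.asarray(rotation_center, dtype=float)

    def cost(x: np.ndarray) -> float:
        T = pose_to_transform(Pose6D.from_array(x), center)
        proj, t = project_points(camera, T.apply(p3))
        if np.any(t <= 1e-6):
            return _FRUSTUM_PENALTY + float(np.sum(np.clip(1e-6 - t, 0, None)))
        return float(np.mean(np.linalg.norm(proj - p2, axis=1)))

    return cost, names


def initialize_pose(
    landmarks3d: dict,
    landmarks2d: dict,
    camera: CameraGeometry,
    rotation_center,
) -> Pose6D:
    """Data-driven starting pose: match landmark centroids and spreads.

    Mirrors the clinical initialisation step in which the starting point
    is chosen so the initial projection already shows the anatomy as in
    the radiograph.  The in-plane translation aligns the projected 3D
    landmark centroid with the 2D annotation centroid (divided by the
    local magnification); the translation along the viewing axis matches
    the RMS spreads of the two point clouds (magnification ratio).
    Rotations start at zero.
    """
    names = sorted(set(landmarks2d) & set(landmarks3d))
    if len(names) < 2:
        return Pose6D()
    center = np.asarray(rotation_center, dtype=float)
    p3 = np.array([landmarks3d[k] for k in names], dtype=float)
    p2 = np.array(
        [pixel_to_detector_point(camera, landmarks2d[k]) for k in names], dtype=float
    )
    proj, t = project_points(camera, p3)
    if np.any(t <= 0):
        return Pose6D()
    axis = camera.axis
    sdd = camera.sdd
    d_axis = float((center - camera.source) @ axis)
    M = sdd / d_axis

    # Depth from the magnification ratio implied by the 2D/projected spreads.
    s_proj = np.sqrt(np.mean(np.sum((proj - proj.mean(0)) ** 2, axis=1)))
    s_targ = np.sqrt(np.mean(np.sum((p2 - p2.mean(0)) ** 2, axis=1)))
    t_depth = 0.0
    if s_proj > 1e-9 and s_targ > 1e-9:
        M_new = M * s_targ / s_proj
        t_depth = sdd / M_new - d_axis

    # In-plane translation from the centroid mismatch, demagnified.
    delta = (p2.mean(axis=0) - proj.mean(axis=0)) / M
    du = float(delta @ camera.detector_u_axis)
    dv = float(delta @ camera.detector_v_axis)
    t_vec = du * camera.detector_u_axis + dv * camera.detector_v_axis + t_depth * axis
    return Pose6D(0.0, 0.0, 0.0, *t_vec.tolist())


def derive_sigma0(
    f0_mm: float,
    landmarks3d: dict,
    landmark_names,
    camera: CameraGeometry,
    rotation_center,
) -> np.ndarray:
    """Per-parameter initial CMA-ES step size from the initial mPDE.

    An initial projection discrepancy of ``f0`` mm on the detector
    corresponds to roughly ``f0 / M`` mm of rigid motion at the object
    (``M`` = magnification at the rotation centre), and to
    ``f0 * 180 / (pi * M * rho)`` degrees of rotation for a landmark
    cloud of RMS radius ``rho`` about the rotation centre.  Step sizes
    are clipped to [0.3, 5] mm and [0.3, 10/3] degrees so a tiny or a
    huge initial discrepancy still yields a workable search.
    """
    center = np.asarray(rotation_center, dtype=float)
    axis = camera.axis
    M = camera.sdd / max(float((center - camera.source) @ axis), 1e-6)
    pts = np.array([landmarks3d[k] for k in landmark_names], dtype=float)
    rho = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
    sig_t = float(np.clip(f0_mm / M, 0.3, 5.0))
    sig_r = float(np.clip(np.degrees(f0_mm / (M * max(rho, 1e-6))), 0.3, 10.0 / 3.0))
    return np.array([sig_r, sig_r, sig_r, sig_t, sig_t, sig_t])


def register_view(
    landmarks3d: dict,
    landmarks2d: dict,
    camera: CameraGeometry,
    init: Pose6D = Pose6D(),
    config: OptConfig | None = None,
    rotation_center=None,
) -> RegistrationResult:
    """Estimate the 6-dof pose of one view by minimising mPDE with CMA-ES.

    ``landmarks2d`` keys select which entries of ``landmarks3d`` take
    part; at least three correspondences are required.  The initial pose
    should place the anatomy inside the frustum (mirroring the clinical
    practice of starting from a DRR that already shows the major
    anatomy).  The full per-evaluation trace is kept for convergence
    plots; runs are deterministic given ``config.seed``.
    """
    config = config or OptConfig()
    missing = set(landmarks2d) - set(landmarks3d)
    if missing:
        raise CorrespondenceError(f"2D landmarks without 3D partner: {sorted(missing)}")
    if len(landmarks2d) < 3:
        raise UnderdeterminedError(
            f"need at least 3 landmark correspondences, got {len(landmarks2d)}"
        )
    if rotation_center is None:
        rotation_center = np.mean(
            [np.asarray(landmarks3d[k], float) for k in landmarks2d], axis=0
        )
    rotation_center = np.asarray(rotation_center, dtype=float)

    cost, _ = _make_cost(landmarks3d, landmarks2d, camera, rotation_center)
    x0 = init.as_array()
    f0 = cost(x0)
    if f0 >= _FRUSTUM_PENALTY:
        warnings.warn("initial pose places landmarks outside the frustum")
    if config.search_halfwidth is not None:
        sigma0 = np.asarray(config.search_halfwidth, dtype=float) / 3.0
    else:
        sigma0 = derive_sigma0(
            f0, landmarks3d, sorted(landmarks2d), camera, rotation_center
        )
    res = cma_es_minimize(
        cost,
        x0,
        sigma0,
        popsize=config.popsize,
        max_evals=config.max_evals,
        target_f=config.tol_mm,
        seed=config.seed,
    )
    if res.fun > f0:
        warnings.warn("registration did not improve on the initial pose")
    return RegistrationResult(
        pose=Pose6D.from_array(res.x),
        rotation_center=rotation_center,
        final_mpde=res.fun,
        n_evaluations=res.n_evaluations,
        converged=res.converged,
        seed=config.seed,
        trace=[(i, x, f) for (i, x, f) in res.history],
    )


def register_vertebra(
    landmarks3d: dict,
    ap_landmarks2d: dict,
    lat_landmarks2d: dict,
    ap_camera: CameraGeometry,
    lat_camera: CameraGeometry,
    inits: tuple[Pose6D, Pose6D] | None = None,
    config: OptConfig | None = None,
    rotation_center=None,
    mode: str = "independent",
) -> tuple[RegistrationResult, RegistrationResult]:
    """Register one vertebra against its AP and lateral radiographs.

    ``mode="independent"`` (the clinical procedure) runs one single-view
    registration per view; their solutions may disagree, which is what
    produces nonzero inter-ray gaps at triangulation.  ``mode="joint"``
    estimates a single shared pose minimising the summed mPDE of both
    views.  When ``inits`` is omitted each view starts from
    :func:`initialize_pose`.
    """
    config = config or OptConfig()
    if rotation_center is None:
        keys = set(ap_landmarks2d) | set(lat_landmarks2d)
        rotation_center = np.mean(
            [np.asarray(landmarks3d[k], float) for k in keys if k in landmarks3d],
            axis=0,
        )
    rotation_center = np.asarray(rotation_center, dtype=float)
    if inits is None:
        inits = (
            initialize_pose(landmarks3d, ap_landmarks2d, ap_camera, rotation_center),
            initialize_pose(landmarks3d, lat_landmarks2d, lat_camera, rotation_center),
        )

    if mode == "independent":
        cfg_ap = OptConfig(**{**config.__dict__})
        cfg_lat = OptConfig(**{**config.__dict__, "seed": config.seed + 1})
        ap = register_view(
            landmarks3d, ap_landmarks2d, ap_camera, inits[0], cfg_ap, rotation_center
        )
        lat = register_view(
            landmarks3d, lat_landmarks2d, lat_camera, inits[1], cfg_lat, rotation_center
        )
        return ap, lat
    if mode != "joint":
        raise ValueError(f"unknown mode {mode!r}")

    cost_ap, _ = _make_cost(landmarks3d, ap_landmarks2d, ap_camera, rotation_center)
    cost_lat, _ = _make_cost(landmarks3d, lat_landmarks2d, lat_camera, rotation_center)

    def cost(x):
        return cost_ap(x) + cost_lat(x)

    if config.search_halfwidth is not None:
        sigma0 = np.asarray(config.search_halfwidth, dtype=float) / 3.0
    else:
        f0 = cost(inits[0].as_array()) / 2.0
        sigma0 = derive_sigma0(
            f0,
            landmarks3d,
            sorted(set(ap_landmarks2d) | set(lat_landmarks2d)),
            ap_camera,
            rotation_center,
        )
    res = cma_es_minimize(
        cost,
        inits[0].as_array(),
        sigma0,
        popsize=config.popsize,
        max_evals=config.max_evals,
        target_f=config.tol_mm,
        seed=config.seed,
    )
    pose = Pose6D.from_array(res.x)
    results = []
    for c in (cost_ap, cost_lat):
        results.append(
            RegistrationResult(
                pose=pose,
                rotation_center=rotation_center,
                final_mpde=float(c(res.x)),
                n_evaluations=res.n_evaluations,
                converged=res.converged,
                seed=config.seed,
                trace=[(i, x, f) for (i, x, f) in res.history],
            )
        )
    return results[0], results[1]
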