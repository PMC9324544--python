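"""File formats: volumes, landmark CSVs, rig configs, images, reports.

Conventions stated in every file this module writes: 3D coordinates are
mm in the CT world frame; 2D annotations are 0-based pixel coordinates.

* Volumes: NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``)
  through SimpleITK.  Any stored rescale slope/intercept is applied on
  read, so voxel values are Hounsfield units in memory.
* Landmarks: CSV with columns ``name, view, x, y, z`` — ``view`` is
  ``ct`` (3D, mm) or a 2D view label (``ap``/``lat``, pixels, empty z).
* Rig: YAML/JSON describing both views (SDD, source-to-isocenter
  distance, detector size, pixel spacing) plus the isocenter.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .drr import CTVolume, ProjectionImage, RADIOGRAPH_DISPLAY, to_display
from .geometry import Pose6D, make_camera
from .phantom import CArmRig

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    pass


def _check_suffix(path: Path):
    name = path.name.lower()
    if not any(name.endswith(s) for s in VOLUME_SUFFIXES):
        raise FormatError(
            f"unknown volume format {path.name!r}; expected one of {VOLUME_SUFFIXES}"
        )


def read_volume(path) -> CTVolume:
    """Read a NIfTI or MetaImage volume into a :class:`CTVolume` (HU)."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    direction = np.array(img.GetDirection()).reshape(3, 3)
    diag = np.diagonal(direction)
    if not np.allclose(direction, np.diag(diag), atol=1e-6) or not np.allclose(
        np.abs(diag), 1.0, atol=1e-6
    ):
        raise FormatError(
            "oblique direction matrices are not supported; resample the "
            "volume to an axis-aligned grid first"
        )
    # SimpleITK arrays are indexed (z, y, x); transpose to (x, y, z).
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    if np.any(spacing <= 0):
        raise FormatError("volume is missing a positive voxel spacing")
    origin = np.array(img.GetOrigin())
    # Fold axis flips (e.g. the RAS/LPS sign convention) into the array so
    # voxel index increases along +x, +y, +z in world coordinates.
    for a in range(3):
        if diag[a] < 0:
            voxels = np.flip(voxels, axis=a)
            origin[a] = origin[a] - (voxels.shape[a] - 1) * spacing[a]
    return CTVolume(np.ascontiguousarray(voxels, dtype=float), spacing, origin)


def write_volume(volume: CTVolume, path) -> Path:
    """Write a volume as NIfTI or MetaImage (by extension)."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))
    return path


def read_landmarks(path) -> tuple[dict, dict]:
    """Read a landmark CSV into ``(landmarks3d, {view: landmarks2d})``.

    Raises with the offending line number on malformed rows or duplicate
    ``(name, view)`` keys.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"name", "view", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"landmark CSV must have columns {sorted(required)} [, z]")
    l3d: dict = {}
    l2d: dict = {}
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        name = str(row["name"])
        view = str(row["view"]).lower()
        key = (name, view)
        if key in seen:
            raise FormatError(f"line {line}: duplicate landmark {name!r} for view {view!r}")
        seen.add(key)
        try:
            x, y = float(row["x"]), float(row["y"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"line {line}: non-numeric coordinate") from exc
        if view == "ct":
            z = row.get("z", np.nan)
            if pd.isna(z):
                raise FormatError(f"line {line}: CT landmark {name!r} missing z")
            l3d[name] = np.array([x, y, float(z)])
        else:
            if "z" in df.columns and not pd.isna(row["z"]):
                raise FormatError(f"line {line}: 2D landmark {name!r} must not set z")
            l2d.setdefault(view, {})[name] = np.array([x, y])
    return l3d, l2d


def write_landmarks(path, landmarks3d: dict, landmarks2d: dict | None = None) -> Path:
    """Write landmarks to CSV (3D in mm / CT frame, 2D in px per view)."""
    rows = [
        {"name": k, "view": "ct", "x": v[0], "y": v[1], "z": v[2]}
        for k, v in landmarks3d.items()
    ]
    for view, lms in (landmarks2d or {}).items():
        rows += [
            {"name": k, "view": view, "x": v[0], "y": v[1], "z": np.nan}
            for k, v in lms.items()
        ]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# 3D rows (view=ct): mm, CT world frame; 2D rows: 0-based pixels\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path


def rig_to_config(rig: CArmRig) -> dict:
    def cam_cfg(cam):
        return {
            "view": cam.label,
            "sdd_mm": cam.sdd,
            "source_to_iso_mm": float(
                np.linalg.norm(np.asarray(rig.isocenter) - cam.source)
            ),
            "detector_size_px": [cam.detector_size_u, cam.detector_size_v],
            "pixel_spacing_mm": [cam.pixel_spacing_u, cam.pixel_spacing_v],
            "principal_pixel": list(map(float, cam.principal_pixel)),
        }

    return {
        "isocenter_mm": list(map(float, rig.isocenter)),
        "views": {"ap": cam_cfg(rig.ap), "lat": cam_cfg(rig.lat)},
    }


def rig_from_config(cfg: dict) -> CArmRig:
    iso = np.asarray(cfg["isocenter_mm"], dtype=float)
    cams = {}
    for view in ("ap", "lat"):
        c = cfg["views"][view]
        cams[view] = make_camera(
            c.get("view", view),
            c["sdd_mm"],
            c["source_to_iso_mm"],
            c["detector_size_px"],
            c["pixel_spacing_mm"],
            iso,
            principal_pixel=c.get("principal_pixel"),
        )
    return CArmRig(ap=cams["ap"], lat=cams["lat"], isocenter=iso)


def read_rig(path) -> CArmRig:
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return rig_from_config(cfg)


def write_rig(rig: CArmRig, path) -> Path:
    path = Path(path)
    cfg = rig_to_config(rig)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh)
    return path


def write_projection_png(image: ProjectionImage, path, sidecar: dict | None = None) -> Path:
    """Write a projection as 16-bit PNG plus a JSON sidecar.

    The sidecar records pixel spacing, intensity semantics and whatever
    extra metadata (pose, camera) the caller supplies.
    """
    path = Path(path)
    img = image if image.intensity_semantics == RADIOGRAPH_DISPLAY else to_display(image)
    data = np.clip(img.pixels, 0.0, 1.0)
    iio.imwrite(path, (data * 65535).astype(np.uint16))
    meta = {
        "pixel_spacing_mm": list(map(float, image.pixel_spacing)),
        "intensity_semantics": image.intensity_semantics,
    }
    meta.update(sidecar or {})
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=_jsonable)
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Pose6D):
        return obj.as_array().tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(report: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable, sort_keys=True)
    return path
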