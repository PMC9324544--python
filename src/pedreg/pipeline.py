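"""End-to-end case execution: register -> map -> reproject -> evaluate.

A "case" is one vertebra with a CT volume, AP and lateral radiographs,
a keyed landmark file (3D anatomical landmarks plus 2D landmark and
marker-end annotations per view) and a rig description.  ``run_case``
executes the full pipeline and writes a JSON report, a metrics CSV row
and optional validation DRRs / overlay images, reproducibly for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .drr import render_drr, to_display
from .metrics import Segment2D, evaluate_vertebra
from .phantom import SimulatedCase
from .registration import OptConfig, crop_vertebra, register_vertebra
from .trajectory import cumulate_axial_slices, map_trajectory, reproject_trajectory

MARKER_KEYS = ("marker_head", "marker_tail")


@dataclass
class CaseConfig:
    """Paths and options driving one pipeline run."""

    volume: str
    landmarks: str
    rig: str
    out_dir: str = "."
    seed: int = 0
    popsize: int = 50
    max_evals: int = 2000
    tol_mm: float = 1e-3
    marker_length_mm: float = 30.0
    crop_bbox: tuple | None = None
    render_validation_drr: bool = False
    report_decimals: int = 2

    @staticmethod
    def from_yaml(path) -> "CaseConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cc = CaseConfig(**cfg)
        base = Path(path).parent
        for attr in ("volume", "landmarks", "rig"):
            p = Path(getattr(cc, attr))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
            setattr(cc, attr, str(p))
        if cc.popsize <= 0 or cc.max_evals <= 0:
            raise ValueError("popsize and max_evals must be positive")
        return cc


def _segments(marker2d: dict, spacing: dict) -> dict:
    return {
        view: Segment2D(
            head=marker2d[view]["head"] if "head" in marker2d[view] else marker2d[view]["marker_head"],
            tail=marker2d[view]["tail"] if "tail" in marker2d[view] else marker2d[view]["marker_tail"],
            view=view,
            pixel_spacing=spacing[view],
        )
        for view in ("ap", "lat")
    }


def run_case(config: CaseConfig) -> dict:
    """Execute crop -> register (AP, lateral) -> map -> reproject -> metrics.

    Returns the report dictionary (also written to ``out_dir``); stage
    failures raise with the stage name prefixed, preserving any outputs
    already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        volume = pio.read_volume(config.volume)
        landmarks3d, landmarks2d = pio.read_landmarks(config.landmarks)
        rig = pio.read_rig(config.rig)

        stage = "crop"
        if config.crop_bbox is not None:
            volume = crop_vertebra(volume, config.crop_bbox)

        stage = "register"
        anatomical2d = {
            view: {k: v for k, v in landmarks2d.get(view, {}).items() if k not in MARKER_KEYS}
            for view in ("ap", "lat")
        }
        rotation_center = np.mean(
            [v for k, v in landmarks3d.items() if k not in MARKER_KEYS], axis=0
        )
        opt = OptConfig(
            popsize=config.popsize,
            max_evals=config.max_evals,
            tol_mm=config.tol_mm,
            seed=config.seed,
        )
        ap_res, lat_res = register_vertebra(
            landmarks3d,
            anatomical2d["ap"],
            anatomical2d["lat"],
            rig.ap,
            rig.lat,
            config=opt,
            rotation_center=rotation_center,
        )

        stage = "render"
        if config.render_validation_drr:
            for view, res in (("ap", ap_res), ("lat", lat_res)):
                img = render_drr(volume, rig.camera(view), res.pose, res.rotation_center)
                pio.write_projection_png(
                    to_display(img),
                    out / f"validation_drr_{view}.png",
                    sidecar={"pose": res.pose, "view": view, "final_mpde_mm": res.final_mpde},
                )

        stage = "map"
        marker = {
            view: {
                "head": landmarks2d[view]["marker_head"],
                "tail": landmarks2d[view]["marker_tail"],
            }
            for view in ("ap", "lat")
        }
        traj = map_trajectory(
            marker["ap"]["head"],
            marker["ap"]["tail"],
            marker["lat"]["head"],
            marker["lat"]["tail"],
            rig.ap,
            rig.lat,
            ap_res.pose,
            lat_res.pose,
            ap_res.rotation_center,
            lat_res.rotation_center,
        )

        stage = "evaluate"
        spacing = {"ap": rig.ap.pixel_spacing_u, "lat": rig.lat.pixel_spacing_u}
        actual = _segments(marker, spacing)
        reproj = {}
        for view, res in (("ap", ap_res), ("lat", lat_res)):
            seg_px = reproject_trajectory(traj, rig.camera(view), res.pose, res.rotation_center)
            reproj[view] = Segment2D(seg_px[0], seg_px[1], view, spacing[view])
        vm = evaluate_vertebra(
            actual["ap"], reproj["ap"], actual["lat"], reproj["lat"], traj,
            marker_length=config.marker_length_mm,
        )

        stage = "report"
        report = {
            "seed": config.seed,
            "registration": {
                view: {
                    "pose": res.pose,
                    "rotation_center_mm": res.rotation_center,
                    "final_mpde_mm": res.final_mpde,
                    "n_evaluations": res.n_evaluations,
                    "converged": res.converged,
                }
                for view, res in (("ap", ap_res), ("lat", lat_res))
            },
            "trajectory": {
                "head_mm": traj.head,
                "tail_mm": traj.tail,
                "head_gap_mm": traj.head_gap,
                "tail_gap_mm": traj.tail_gap,
                "length_mm": traj.length,
            },
            "metrics": {k: round(float(v), 6) for k, v in zip(vm.field_names(), vm.as_array())},
        }
        pio.write_report(report, out / "report.json")
        for view, res in (("ap", ap_res), ("lat", lat_res)):
            np.savetxt(
                out / f"trace_{view}.csv",
                np.array([[i, *x, f] for i, x, f in res.trace]),
                delimiter=",",
                header="evaluation,theta_x,theta_y,theta_z,t_x,t_y,t_z,mpde_mm",
                comments="",
            )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_case_dir(case: SimulatedCase, out_dir) -> Path:
    """Persist a simulated case as a self-contained directory.

    Contents: ``volume.nii.gz``, per-view radiograph PNGs (if rendered),
    ``landmarks.csv`` (3D anatomy + noisy 2D annotations + marker ends),
    ``rig.yaml``, ``truth.json`` and a ready-to-run ``case.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_volume(case.volume, out / "volume.nii.gz")
    landmarks2d = {
        view: {
            **case.landmarks2d[view],
            "marker_head": case.marker2d[view]["head"],
            "marker_tail": case.marker2d[view]["tail"],
        }
        for view in ("ap", "lat")
    }
    pio.write_landmarks(out / "landmarks.csv", case.truth.landmarks3d, landmarks2d)
    pio.write_rig(case.rig, out / "rig.yaml")
    for view, img in case.images.items():
        if img is not None:
            pio.write_projection_png(img, out / f"radiograph_{view}.png", {"view": view})
    pio.write_report(
        {
            "true_pose": {v: p for v, p in case.truth.pose.items()},
            "rotation_center_mm": case.truth.rotation_center,
            "marker_head3d_mm": case.truth.marker_head3d,
            "marker_tail3d_mm": case.truth.marker_tail3d,
            "marker2d_exact_px": {
                v: {k: p for k, p in d.items()} for v, d in case.truth.marker2d_exact.items()
            },
            "seed": case.seed,
        },
        out / "truth.json",
    )
    with open(out / "case.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "volume": "volume.nii.gz",
                "landmarks": "landmarks.csv",
                "rig": "rig.yaml",
                "out_dir": str(out / "results"),
                "seed": case.seed,
            },
            fh,
        )
    return out


def overlay_axial(case_volume, traj, out_path, z_pad: int = 1):
    """Cumulate the axial slices spanning the trajectory and overlay it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spacing = case_volume.spacing
    k_head = int(round((traj.head[2] - case_volume.origin[2]) / spacing[2]))
    k_tail = int(round((traj.tail[2] - case_volume.origin[2]) / spacing[2]))
    k0 = max(0, min(k_head, k_tail) - z_pad)
    k1 = min(case_volume.shape[2] - 1, max(k_head, k_tail) + z_pad)
    img = cumulate_axial_slices(case_volume, (k0, k1), mode="mean")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img.T, cmap="gray", origin="lower")
    xs = [
        (traj.head[0] - case_volume.origin[0]) / spacing[0],
        (traj.tail[0] - case_volume.origin[0]) / spacing[0],
    ]
    ys = [
        (traj.head[1] - case_volume.origin[1]) / spacing[1],
        (traj.tail[1] - case_volume.origin[1]) / spacing[1],
    ]
    ax.plot(xs, ys, "r-", lw=1.5)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(out_path)
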