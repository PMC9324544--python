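"""2D evaluation of a registered trajectory against its radiograph annotations.

In the absence of fiducial- or tracker-based 3D ground truth, accuracy
is assessed on the radiographic planes: the mapped 3D trajectory is
reprojected onto each view and compared with the annotated marker.
Seven metrics are reported per vertebra — head and tail endpoint
displacements and a directional angle error in both the AP and lateral
planes, plus the absolute difference between the triangulated trajectory
length and the marker's known physical length (30 mm).  On globally
optimal registration all seven are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .trajectory import Trajectory3D

MARKER_LENGTH_MM = 30.0


class MetricsError(ValueError):
    pass


@dataclass
class Segment2D:
    """Marker axis on one radiograph: head/tail pixels plus pixel size."""

    head: np.ndarray
    tail: np.ndarray
    view: str
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.head = np.asarray(self.head, dtype=float).reshape(2)
        self.tail = np.asarray(self.tail, dtype=float).reshape(2)
        if np.allclose(self.head, self.tail):
            raise MetricsError("segment head and tail coincide")
        if self.pixel_spacing <= 0:
            raise MetricsError("pixel spacing must be positive")

    @property
    def direction(self) -> np.ndarray:
        d = self.tail - self.head
        return d / np.linalg.norm(d)


@dataclass
class VertebraMetrics:
    """The seven per-vertebra trajectory registration errors."""

    ap_head_mm: float
    ap_tail_mm: float
    ap_angle_deg: float
    lat_head_mm: float
    lat_tail_mm: float
    lat_angle_deg: float
    length_error_mm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @staticmethod
    def field_names() -> list[str]:
        return [f.name for f in fields(VertebraMetrics)]


def endpoint_displacement(
    actual: Segment2D, reprojected: Segment2D
) -> tuple[float, float]:
    """Per-end Euclidean distance in mm between two same-view segments."""
    if actual.view != reprojected.view:
        raise MetricsError(
            f"view mismatch: {actual.view!r} vs {reprojected.view!r}"
        )
    if not np.isclose(actual.pixel_spacing, reprojected.pixel_spacing):
        raise MetricsError("segments have different pixel spacings")
    s = actual.pixel_spacing
    head = float(np.linalg.norm(actual.head - reprojected.head)) * s
    tail = float(np.linalg.norm(actual.tail - reprojected.tail)) * s
    return head, tail


def angle_error(actual: Segment2D, reprojected: Segment2D) -> float:
    """Unsigned acute angle (degrees, in [0, 90]) between segment directions.

    Directions are treated as undirected lines, so a head/tail flip does
    not register as a 180-degree error.
    """
    c = abs(float(actual.direction @ reprojected.direction))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def length_error(traj, marker_length: float = MARKER_LENGTH_MM) -> float:
    """| triangulated length - physical marker length | in mm."""
    if marker_length <= 0:
        raise MetricsError("marker length must be positive")
    length = traj.length if isinstance(traj, Trajectory3D) else float(traj)
    return abs(length - marker_length)


def evaluate_vertebra(
    actual_ap: Segment2D,
    reproj_ap: Segment2D,
    actual_lat: Segment2D,
    reproj_lat: Segment2D,
    traj: Trajectory3D,
    marker_length: float = MARKER_LENGTH_MM,
) -> VertebraMetrics:
    """Assemble all seven metrics for one vertebra."""
    ap_head, ap_tail = endpoint_displacement(actual_ap, reproj_ap)
    lat_head, lat_tail = endpoint_displacement(actual_lat, reproj_lat)
    return VertebraMetrics(
        ap_head_mm=ap_head,
        ap_tail_mm=ap_tail,
        ap_angle_deg=angle_error(actual_ap, reproj_ap),
        lat_head_mm=lat_head,
        lat_tail_mm=lat_tail,
        lat_angle_deg=angle_error(actual_lat, reproj_lat),
        length_error_mm=length_error(traj, marker_length),
    )


def aggregate(metrics: list, exclude=()) -> VertebraMetrics:
    """Per-field arithmetic mean over vertebrae.

    ``exclude`` removes entries by index before averaging — useful when
    a vertebra with known poor landmark visibility is to be left out of
    a summary.  No case is excluded by default.
    """
    rows = [m for i, m in enumerate(metrics) if i not in set(exclude)]
    if not rows:
        raise MetricsError("no metrics rows to aggregate")
    mean = np.mean([m.as_array() for m in rows], axis=0)
    return VertebraMetrics(*mean.tolist())


def metrics_table(metrics: list, labels=None, decimals: int = 2) -> pd.DataFrame:
    """Per-vertebra metrics plus a summary mean row, as a DataFrame.

    Column layout mirrors the clinical reporting convention: AP
    head/tail/angle, lateral head/tail/angle, trajectory length error.
    """
    if labels is None:
        labels = [f"case_{i + 1}" for i in range(len(metrics))]
    if len(labels) != len(metrics):
        raise MetricsError("labels and metrics length mismatch")
    cols = VertebraMetrics.field_names()
    df = pd.DataFrame(
        [m.as_array() for m in metrics], index=list(labels), columns=cols
    )
    df.loc["mean"] = aggregate(metrics).as_array()
    df.index.name = "vertebra"
    return df.round(decimals)
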