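"""Pinhole back-projection of foreground blobs into 3-D point clouds.

Coordinates are right-handed and sensor-centred: the origin sits at the
depth camera, Z points down the optical axis toward the floor, X right
and Y down in the image.  For a pixel (u, v) with depth Z (mm):

    X = (u - cx) * Z / fx,   Y = (v - cy) * Z / fy

Default intrinsics are Kinect-v1-like for a 640x480 grid and scale
linearly with resolution; they are configuration-overridable because the
true calibration of any particular device differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ForegroundBlob

__all__ = ["CameraModel", "PointCloud", "to_point_cloud", "head_distance_mm"]


@dataclass(frozen=True)
class CameraModel:
    fx: float = 585.0
    fy: float = 585.0
    cx: float = 319.5
    cy: float = 239.5
    sensor_height_mm: float = 3000.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @classmethod
    def scaled(cls, scale: float, sensor_height_mm: float = 3000.0) -> "CameraModel":
        """Intrinsics for a frame downscaled from the 640x480 reference."""
        return cls(
            fx=585.0 * scale,
            fy=585.0 * scale,
            cx=(640.0 * scale) / 2.0 - 0.5,
            cy=(480.0 * scale) / 2.0 - 0.5,
            sensor_height_mm=sensor_height_mm,
        )

    def project(self, points: np.ndarray) -> np.ndarray:
        """World (N,3) mm -> pixel (N,2) (u,v)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        u = pts[:, 0] * self.fx / pts[:, 2] + self.cx
        v = pts[:, 1] * self.fy / pts[:, 2] + self.cy
        return np.column_stack([u, v])


@dataclass
class PointCloud:
    """3-D point set (mm) with the source pixel of every point retained."""

    points: np.ndarray  # (N, 3) float, columns X, Y, Z
    pixels: np.ndarray  # (N, 2) int, columns u, v

    def __len__(self) -> int:
        return len(self.points)


def to_point_cloud(blob: ForegroundBlob, cam: CameraModel) -> PointCloud:
    """Back-project every blob pixel through the intrinsics.

    One 3-D point per blob pixel; a zero depth under the mask means the
    hole-filling contract upstream was violated and raises.
    """
    ys, xs = np.nonzero(blob.mask)
    z = blob.depth_mm[ys, xs].astype(float)
    if np.any(z <= 0):
        raise ValueError("blob contains non-positive depth; frames must be hole-filled")
    x = (xs - cam.cx) * z / cam.fx
    y = (ys - cam.cy) * z / cam.fy
    return PointCloud(
        points=np.column_stack([x, y, z]),
        pixels=np.column_stack([xs, ys]).astype(int),
    )


def head_distance_mm(blob: ForegroundBlob) -> float:
    """Sensor-to-head distance: the minimum depth under the blob mask.

    The closest surface of a person seen from the ceiling is the top of
    the head, so the blob minimum is the head height measurement used by
    the sitting classifier.
    """
    depths = blob.depths
    if depths.size == 0:
        raise ValueError("empty blob has no head distance")
    return float(depths.min())
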