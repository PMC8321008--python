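"""YAML pipeline configuration.

One file carries four sections mapping onto the parameter dataclasses:

.. code-block:: yaml

    camera:    {fx: 585.0, fy: 585.0, cx: 319.5, cy: 239.5, sensor_height_mm: 3000}
    preprocess: {min_diff_mm: 100, median_window: 5}
    session:   {dist_px: 45, ratio: 0.3, hand_gap_mm: 200, hand_area_px: 300,
                table_rect: [360, 140, 580, 340]}
    tracker:   {fusion_dist_mm: 200, fusion_frames: 150}
    actions:   {action_dist_mm: 200, dwell_min_frames: 150}

Absent keys keep their defaults.  The ``preprocess`` keys are folded
into the session config, which owns the per-frame chain thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .intake_counter import ActionParams
from .pointcloud import CameraModel
from .session_detector import SessionConfig
from .som_tracker import TrackerParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    session: SessionConfig = field(default_factory=SessionConfig)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    actions: ActionParams = field(default_factory=ActionParams)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    session_kwargs = dict(doc.get("session", {}))
    if "table_rect" in session_kwargs:
        session_kwargs["table_rect"] = tuple(session_kwargs["table_rect"])
    session_kwargs.update(doc.get("preprocess", {}))
    return PipelineConfig(
        camera=CameraModel(**doc.get("camera", {})),
        session=replace(SessionConfig(), **session_kwargs),
        tracker=replace(TrackerParams(), **doc.get("tracker", {})),
        actions=replace(ActionParams(), **doc.get("actions", {})),
    )
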