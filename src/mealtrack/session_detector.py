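"""Automatic start-/end-of-meal detection.

Per frame an ordered, short-circuiting checklist runs:

1. a person blob is present in the background-subtracted frame;
2. the head midpoint lies within the table box expanded by ``dist_px``;
3. the sitting test fires: the head-to-sensor distance has grown by the
   ``ratio`` fraction relative to the standing baseline (the running
   minimum of the head-distance history while not seated);
4. at least one hand blob rests on the table: foreground over the table
   mask within ``hand_gap_mm`` of the table top and larger than
   ``hand_area_px``.

The start frame (SF) is the first frame passing all four checks; the end
frame (EF) is the last frame the sitting condition held before a
confirmed departure (the person out of the table box or absent for
``absence_frames``), or before the end of the file.  Brief departures
followed by re-seating open a new (SF, EF) segment of the same meal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .pointcloud import head_distance_mm
from .preprocess import ForegroundBlob, _CONN8, fill_holes, median_denoise, subtract_background
from .types import DepthFrame, Segment, SessionTable

__all__ = [
    "SessionConfig",
    "HeightHistory",
    "FrameState",
    "near_table",
    "is_sitting",
    "hands_on_table",
    "run_checklist",
    "detect_sessions",
    "rollover",
]


@dataclass(frozen=True)
class SessionConfig:
    """Thresholds of the SF/EF state machine.

    Pixel-valued defaults refer to a 640x480 grid; use :meth:`scaled`
    for other resolutions (lengths scale linearly, areas quadratically).
    """

    dist_px: float = 45.0
    ratio: float = 0.3
    hand_gap_mm: float = 200.0
    hand_area_px: float = 300.0
    table_rect: tuple[int, int, int, int] = (360, 140, 580, 340)
    table_top_mm: float = 2100.0
    absence_frames: int = 90  # 3 s of confirmed departure at 30 fps
    rollover_frames: int = 27000  # 15 min at 30 fps
    min_diff_mm: float = 100.0
    person_min_area_px: float = 300.0
    median_window: int = 5
    min_segment_frames: int = 30
    sitting_dialect: str = "threshold-on-seated"  # or "threshold-on-standing"

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if min(self.dist_px, self.hand_gap_mm, self.hand_area_px) <= 0:
            raise ValueError("dist_px, hand_gap_mm and hand_area_px must be positive")
        if self.sitting_dialect not in ("threshold-on-seated", "threshold-on-standing"):
            raise ValueError(f"unknown sitting dialect {self.sitting_dialect!r}")

    @classmethod
    def scaled(cls, scale: float, **overrides) -> "SessionConfig":
        cfg = cls(
            dist_px=45.0 * scale,
            hand_area_px=300.0 * scale**2,
            table_rect=tuple(int(round(c * scale)) for c in (360, 140, 580, 340)),
            person_min_area_px=300.0 * scale**2,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class HeightHistory:
    """Per-frame head distances plus the running standing baseline.

    The baseline is the minimum head distance observed on frames not
    classified as sitting — the closest the head ever came to the
    sensor while upright.
    """

    distances: list[float] = field(default_factory=list)
    baseline: float | None = None

    def record(self, distance_mm: float, sitting: bool) -> None:
        self.distances.append(distance_mm)
        if not sitting:
            self.baseline = (
                distance_mm if self.baseline is None else min(self.baseline, distance_mm)
            )


def near_table(blob: ForegroundBlob, cfg: SessionConfig) -> bool:
    """Head midpoint within the table rectangle expanded by dist_px (inclusive)."""
    x, y, _ = blob.max_height_point
    x0, y0, x1, y1 = cfg.table_rect
    d = cfg.dist_px
    return (x0 - d) <= x <= (x1 - 1 + d) and (y0 - d) <= y <= (y1 - 1 + d)


def is_sitting(history: HeightHistory, current_mm: float, cfg: SessionConfig) -> bool:
    """Sitting test against the standing baseline.

    Default dialect (``threshold-on-seated``): sitting when the baseline
    lies at least ``ratio`` *of the current distance* below it, i.e.,
    ``current * (1 - ratio) >= baseline`` — a 1700 mm seated reading
    against ratio 0.3 yields the 1190 mm standing threshold.  The
    alternative dialect thresholds on the standing value instead:
    ``current >= baseline * (1 + ratio)``.

    With no baseline yet (no standing frame observed) the test is
    pending and returns False.
    """
    if history.baseline is None:
        return False
    if cfg.sitting_dialect == "threshold-on-seated":
        return current_mm * (1.0 - cfg.ratio) >= history.baseline
    return current_mm >= history.baseline * (1.0 + cfg.ratio)


def _table_mask(cfg: SessionConfig, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    x0, y0, x1, y1 = cfg.table_rect
    mask[y0:y1, x0:x1] = True
    return mask


def hands_on_table(
    frame: DepthFrame, fg_mask: np.ndarray, cfg: SessionConfig
) -> list[ForegroundBlob]:
    """Hand blobs resting on the table.

    Foreground pixels over the table mask whose height above the table
    top is positive but below ``hand_gap_mm`` (a protruding trunk sits
    far higher and is rejected), grouped 8-connected, kept above
    ``hand_area_px``.
    """
    depth = np.asarray(frame.values, dtype=np.int64)
    height_above = cfg.table_top_mm - depth
    candidates = (
        fg_mask
        & _table_mask(cfg, depth.shape)
        & (height_above > 0)
        & (height_above < cfg.hand_gap_mm)
    )
    labels, n = ndi.label(candidates, structure=_CONN8)
    blobs: list[ForegroundBlob] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area <= cfg.hand_area_px:
            continue
        ys, xs = np.nonzero(mask)
        depths = depth[ys, xs]
        top = int(np.argmin(depths))
        blobs.append(
            ForegroundBlob(
                mask=mask,
                depth_mm=depth,
                centroid_px=(float(xs.mean()), float(ys.mean())),
                area_px=area,
                max_height_point=(int(xs[top]), int(ys[top]), int(depths[top])),
            )
        )
    blobs.sort(key=lambda b: b.area_px, reverse=True)
    return blobs


@dataclass
class FrameState:
    """Audit record of the checklist on one frame (0-based index)."""

    frame: int
    present: bool
    near: bool | None = None  # None: check never reached (short-circuit)
    sitting: bool | None = None
    hands: bool | None = None
    head_mm: float | None = None
    baseline_mm: float | None = None

    @property
    def passed(self) -> bool:
        return bool(self.present and self.near and self.sitting and self.hands)


def run_checklist(
    frames: list[DepthFrame],
    background: DepthFrame,
    cfg: SessionConfig,
    preprocessed: bool = False,
) -> list[FrameState]:
    """Run the four ordered checks on every frame.

    Checks short-circuit: a failed check leaves the later ones
    unevaluated (None in the state record).  The standing baseline
    updates only on frames where the person is present and not
    classified sitting.

    A sequence whose very first frame already shows the person at the
    table with a hand resting on it (no standing baseline can ever
    form) is treated as seated from frame one; that mode ends when the
    head distance drops by the ratio fraction below the seated
    reference, which then seeds the baseline.
    """
    def clean(f: DepthFrame) -> DepthFrame:
        return f if preprocessed else median_denoise(fill_holes(f), cfg.median_window)

    bg = clean(background)
    history = HeightHistory()
    states: list[FrameState] = []
    seated_at_start = False
    seated_ref: float | None = None  # running max head distance in that mode
    for idx, raw in enumerate(frames):
        frame = clean(raw)
        blobs = subtract_background(frame, bg, cfg.min_diff_mm, int(cfg.person_min_area_px))
        if not blobs:
            states.append(FrameState(idx, present=False))
            continue
        person = blobs[0]
        head_mm = head_distance_mm(person)
        state = FrameState(idx, present=True, head_mm=head_mm, baseline_mm=history.baseline)
        if not near_table(person, cfg):
            state.near = False
            history.record(head_mm, sitting=False)
            states.append(state)
            continue
        state.near = True
        fg_mask = _foreground_mask(frame, bg, cfg)
        if seated_at_start:
            seated_ref = max(seated_ref or head_mm, head_mm)
            if head_mm <= seated_ref * (1.0 - cfg.ratio):
                seated_at_start = False  # the person finally rose
                sitting = False
            else:
                sitting = True
        else:
            sitting = is_sitting(history, head_mm, cfg)
            if (
                idx == 0
                and history.baseline is None
                and not sitting
                and hands_on_table(frame, fg_mask, cfg)
            ):
                seated_at_start = True
                seated_ref = head_mm
                sitting = True
        state.sitting = sitting
        history.record(head_mm, sitting)
        state.baseline_mm = history.baseline
        if not sitting:
            states.append(state)
            continue
        state.hands = bool(hands_on_table(frame, fg_mask, cfg))
        states.append(state)
    return states


def _foreground_mask(
    frame: DepthFrame, background: DepthFrame, cfg: SessionConfig
) -> np.ndarray:
    f = np.asarray(frame.values, dtype=np.int64)
    b = np.asarray(background.values, dtype=np.int64)
    return (b - f) > cfg.min_diff_mm


def detect_sessions(
    frames: list[DepthFrame],
    background: DepthFrame,
    cfg: SessionConfig,
    test_number: int = 1,
    states: list[FrameState] | None = None,
    preprocessed: bool = False,
) -> SessionTable:
    """Extract the SetParam segments of one sequence.

    Returns an empty table (not an error) when no frame ever satisfies
    the checklist.  Pass precomputed ``states`` to avoid re-running the
    per-frame checks.  Segments shorter than ``min_segment_frames`` are
    dropped as flicker.
    """
    if states is None:
        states = run_checklist(frames, background, cfg, preprocessed=preprocessed)
    segments: list[Segment] = []
    open_sf: int | None = None
    last_sit: int | None = None
    away = 0
    for st in states:
        if st.passed:
            if open_sf is None:
                open_sf = st.frame
            last_sit = st.frame
            away = 0
            continue
        if open_sf is None:
            continue
        if (not st.present) or (st.near is False):
            away += 1
            if away >= cfg.absence_frames:
                segments.append(Segment(test_number, open_sf + 1, last_sit + 1))
                open_sf, last_sit, away = None, None, 0
        else:
            away = 0
    if open_sf is not None:
        segments.append(Segment(test_number, open_sf + 1, last_sit + 1))
    segments = [s for s in segments if s.ef - s.sf + 1 >= cfg.min_segment_frames]
    return SessionTable(segments)


def rollover(frames: list[DepthFrame], rollover_frames: int = 27000) -> list[list[DepthFrame]]:
    """Split a sequence into acquisition files of ``rollover_frames`` each
    (15 min at 30 fps by default); the last chunk may be short."""
    if rollover_frames <= 0:
        raise ValueError("rollover_frames must be positive")
    return [
        frames[i : i + rollover_frames] for i in range(0, len(frames), rollover_frames)
    ]


def states_to_frame(states: list[FrameState]) -> pd.DataFrame:
    """State-machine audit log as a data frame (for the CLI CSV output)."""
    return pd.DataFrame(
        {
            "frame": [s.frame + 1 for s in states],
            "present": [s.present for s in states],
            "near": [s.near for s in states],
            "sitting": [s.sitting for s in states],
            "hands": [s.hands for s in states],
            "head_mm": [s.head_mm for s in states],
            "baseline_mm": [s.baseline_mm for s in states],
            "passed": [s.passed for s in states],
        }
    )
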