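"""Counting food-intake actions from the joint track.

An intake action is a maximal interval during which a hand joint stays
within ``action_dist_mm`` of the head joint for at least the dwell
window (5 s, i.e., 150 frames at 30 fps) — the dwell excludes shorter
hand-to-mouth gestures that are not eating or drinking.  Runs of the
two hands that overlap are one action performed with both hands; runs
separated by less than the refractory gap are one action interrupted
(e.g., by a tracker reset, which fires on the same 5-s window and is
allowed only after the action has already qualified).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud import CameraModel
from .session_detector import SessionConfig, detect_sessions
from .som_tracker import JointTrack, TrackerParams, track_sequence
from .types import DepthFrame, SessionTable

__all__ = ["ActionParams", "ActionEvent", "count_actions", "evaluate_session"]


@dataclass(frozen=True)
class ActionParams:
    action_dist_mm: float = 200.0
    dwell_min_frames: int = 150  # 5 s at 30 fps
    refractory_frames: int = 30
    space: str = "metric"  # "image" measures the head-hand gap in pixels

    def __post_init__(self) -> None:
        if self.dwell_min_frames < 1:
            raise ValueError("dwell_min_frames must be >= 1")
        if self.refractory_frames < 0:
            raise ValueError("refractory_frames must be >= 0")

    @property
    def threshold(self) -> float:
        return self.action_dist_mm


@dataclass(frozen=True)
class ActionEvent:
    start_frame: int  # track frame numbers (1-based)
    end_frame: int
    hand: str  # left / right / both
    min_distance_mm: float


def _runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) index pairs, inclusive."""
    padded = np.r_[False, below, False]
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def _merge_close(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def count_actions(track: JointTrack, params: ActionParams) -> list[ActionEvent]:
    """Scan the per-hand head-hand distance series for intake actions.

    Per hand: maximal sub-threshold runs, close runs merged (refractory),
    runs shorter than the dwell dropped.  Left/right events overlapping
    by at least half of the shorter one merge into a single ``both``
    event.  Deterministic given the track and parameters.
    """
    if len(track) == 0:
        raise ValueError("empty joint track")
    frames = np.asarray(track.frames)
    per_hand: dict[str, list[tuple[int, int]]] = {}
    for hand in ("left", "right"):
        dist = track.distances(hand, params.space)
        below = np.where(np.isnan(dist), False, dist < params.threshold)
        runs = _merge_close(_runs(below), params.refractory_frames)
        per_hand[hand] = [(s, e) for s, e in runs if e - s + 1 >= params.dwell_min_frames]

    events: list[tuple[int, int, str]] = []
    left = list(per_hand["left"])
    right = list(per_hand["right"])
    for ls, le in left:
        matched = None
        for k, (rs, re) in enumerate(right):
            overlap = min(le, re) - max(ls, rs) + 1
            shorter = min(le - ls, re - rs) + 1
            if overlap >= 0.5 * shorter:
                matched = k
                break
        if matched is not None:
            rs, re = right.pop(matched)
            events.append((min(ls, rs), max(le, re), "both"))
        else:
            events.append((ls, le, "left"))
    events.extend((rs, re, "right") for rs, re in right)
    events.sort()

    out: list[ActionEvent] = []
    for s, e, hand in events:
        if hand == "both":
            dmin = float(
                np.nanmin(
                    np.r_[
                        track.distances("left", params.space)[s : e + 1],
                        track.distances("right", params.space)[s : e + 1],
                    ]
                )
            )
        else:
            dmin = float(np.nanmin(track.distances(hand, params.space)[s : e + 1]))
        out.append(ActionEvent(int(frames[s]), int(frames[e]), hand, dmin))
    return out


def evaluate_session(
    frames: list[DepthFrame],
    background: DepthFrame,
    cfg: SessionConfig,
    tracker_params: TrackerParams,
    action_params: ActionParams,
    *,
    camera: CameraModel,
    test_number: int = 1,
) -> tuple[SessionTable, list[int]]:
    """Full pipeline on one sequence: segments plus action count per segment.

    Hole filling and median denoising run once per frame here and are
    skipped inside the detector and tracker stages.
    """
    from .preprocess import fill_holes, median_denoise

    clean = [median_denoise(fill_holes(f), cfg.median_window) for f in frames]
    bg = median_denoise(fill_holes(background), cfg.median_window)
    table = detect_sessions(clean, bg, cfg, test_number, preprocessed=True)
    counts: list[int] = []
    for seg in table:
        track = track_sequence(
            clean,
            seg.sf,
            seg.ef,
            tracker_params,
            background=bg,
            camera=camera,
            min_diff_mm=cfg.min_diff_mm,
            min_area_px=int(cfg.person_min_area_px),
            median_window=cfg.median_window,
            preprocessed=True,
        )
        counts.append(len(count_actions(track, action_params)))
    return table, counts
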