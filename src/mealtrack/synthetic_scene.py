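"""Synthetic top-down depth scenes with known ground truth.

Emulates what a ceiling depth sensor sees during a meal: a person enters
the field of view, walks to a table, sits down (head-to-sensor distance
grows by a configurable fraction), places the hands on the table and
periodically brings one hand to the mouth.  The person is modelled as a
2.5-D stack of flat discs and ellipses (head above shoulders above
torso, arm capsules to the hands) — the downstream pipeline only ever
consumes the depth silhouette, so no mesh is needed.

Sensor artefacts follow the behaviour of structured-light depth cameras:
zero-mean Gaussian noise in mm everywhere plus "hole" dropout (value 0)
concentrated within two pixels of depth discontinuities, where such
sensors genuinely fail.

Every render is deterministic given the script's seed, and with the
noise turned off a frame minus the rendered background recovers exactly
the person's silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage as ndi

from .pointcloud import CameraModel
from .types import DepthFrame

__all__ = [
    "ActionSpec",
    "Visit",
    "SceneScript",
    "SceneTruth",
    "render_background",
    "render_sequence",
    "scripted_meal",
    "scripted_leave_and_return",
    "script_to_yaml",
    "script_from_yaml",
    "SENSOR_NOISE",
]

# Sensor-level noise used for "realistic acquisition" scenes: Kinect-v1
# class depth error at 2-3 m plus heavy dropout at depth jumps.
SENSOR_NOISE = {"noise_sigma_mm": 10.0, "hole_rate": 0.3}

# Anthropometric rendering constants (mm).
HEAD_RADIUS = 100.0
SHOULDER_HALF = 220.0  # half shoulder width
TORSO_HALF = 150.0  # half torso depth (front-back)
TORSO_BACK_OFFSET = 120.0  # seated torso centre sits behind the head
SHOULDER_DROP = 280.0  # shoulder surface below the head top
ARM_RADIUS = 35.0
HAND_RADIUS = 60.0
REST_HAND_ABOVE_TABLE = 120.0  # resting hand height over the table top
HAND_INSET = 100.0  # resting hand reach past the table edge
HAND_LATERAL = 110.0  # resting hand sideways offset from the head axis
# The eating hand must protrude beyond the head rim to stay visible from
# above (the head disc occludes anything straight under it), so the mouth
# pose sits just outside the 100 mm head radius; 3-D head-hand gap 147 mm.
MOUTH_FORWARD = 120.0  # mouth offset from the head centre, toward the table
MOUTH_DROP = 85.0  # mouth below the head top
RAISE_FRAMES = 20  # hand travel table -> mouth
LOWER_FRAMES = 20  # and back
SIT_TRANSITION = 15  # frames to change posture
STAND_TRANSITION = 15
# Scripted subjects are drawn from the taller adult band: with the table
# top 900 mm above the floor and a 0.3 sitting ratio, only subjects above
# ~1830 mm can show the required seated head drop while keeping shoulders
# and forearms above the table plane.  Shorter subjects reproduce the
# known sitting-test failure mode and can be requested explicitly.
HEIGHT_RANGE_MM = (1830.0, 1970.0)

DISCONTINUITY_MM = 200.0  # depth jump that attracts dropout
HOLE_DILATE_PX = 2


@dataclass(frozen=True)
class ActionSpec:
    """One hand-to-mouth action: hand held at the mouth for ``duration`` frames
    starting at 0-based frame ``start`` (travel frames lie outside the window)."""

    start: int
    duration: int
    hand: str = "right"


@dataclass(frozen=True)
class Visit:
    """One contiguous presence of the person, 0-based frame times."""

    enter: int
    sit: int  # first frame fully seated
    hands_on_table: int  # first frame with hands resting on the table
    stand: int  # first frame of rising
    leave: int  # last frame in the scene is leave-1
    actions: tuple[ActionSpec, ...] = ()

    def __post_init__(self) -> None:
        times = (self.enter, self.sit, self.hands_on_table, self.stand, self.leave)
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError(f"visit event times must be strictly increasing: {times}")
        prev_end = self.hands_on_table
        for act in self.actions:
            if act.start - RAISE_FRAMES < prev_end:
                raise ValueError("action windows overlap or start before hands-on-table")
            if act.start + act.duration + LOWER_FRAMES > self.stand:
                raise ValueError("action window extends past the stand event")
            prev_end = act.start + act.duration


@dataclass
class SceneScript:
    """Full description of a synthetic meal scene."""

    width: int = 640
    height: int = 480
    fps: float = 30.0
    sensor_height_mm: float = 3000.0
    table_top_mm: float = 2100.0
    table_rect: tuple[int, int, int, int] = (360, 140, 580, 340)  # x0, y0, x1, y1
    person_height_mm: float = 1880.0
    sit_drop: float = 0.45  # fractional head-distance increase when seated
    visits: tuple[Visit, ...] = ()
    n_frames: int = 300
    noise_sigma_mm: float = 0.0
    hole_rate: float = 0.0
    seed: int = 0
    camera: CameraModel | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.hole_rate < 1:
            raise ValueError("hole_rate must be in [0, 1)")
        if self.person_height_mm >= self.sensor_height_mm:
            raise ValueError("person taller than the sensor height")
        if self.table_top_mm >= self.sensor_height_mm:
            raise ValueError("table must be above the floor")
        x0, y0, x1, y1 = self.table_rect
        if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
            raise ValueError(f"table_rect {self.table_rect} outside the frame")
        prev = -1
        for v in self.visits:
            if v.enter <= prev:
                raise ValueError("visits must be ordered and non-overlapping")
            prev = v.leave
        if self.camera is None:
            self.camera = CameraModel.scaled(
                self.width / 640.0, sensor_height_mm=self.sensor_height_mm
            )

    @property
    def standing_head_mm(self) -> float:
        return self.sensor_height_mm - self.person_height_mm

    @property
    def seated_head_mm(self) -> float:
        return self.standing_head_mm * (1.0 + self.sit_drop)


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a rendered sequence (1-based frames)."""

    sf_true: int
    ef_true: int
    action_windows: list[tuple[int, int]]
    standing_distance_mm: float
    sitting_distance_mm: float
    visit_bounds: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# painting primitives (pixel grids, mm depths; nearer surface wins)


def _paint_disc(depth, cx, cy, r_px, z):
    h, w = depth.shape
    x0, x1 = max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, w)
    y0, y1 = max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    region = depth[y0:y1, x0:x1]
    region[mask] = np.minimum(region[mask], z)


def _paint_ellipse(depth, cx, cy, ax_px, ay_px, z):
    h, w = depth.shape
    x0, x1 = max(int(cx - ax_px) - 1, 0), min(int(cx + ax_px) + 2, w)
    y0, y1 = max(int(cy - ay_px) - 1, 0), min(int(cy + ay_px) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((xx - cx) / ax_px) ** 2 + ((yy - cy) / ay_px) ** 2 <= 1.0
    region = depth[y0:y1, x0:x1]
    region[mask] = np.minimum(region[mask], z)


def _paint_capsule(depth, p0, z0, p1, z1, r_px):
    """Arm segment from p0 (depth z0) to p1 (depth z1), linear depth."""
    h, w = depth.shape
    xmin = max(int(min(p0[0], p1[0]) - r_px) - 1, 0)
    xmax = min(int(max(p0[0], p1[0]) + r_px) + 2, w)
    ymin = max(int(min(p0[1], p1[1]) - r_px) - 1, 0)
    ymax = min(int(max(p0[1], p1[1]) + r_px) + 2, h)
    if xmin >= xmax or ymin >= ymax:
        return
    yy, xx = np.mgrid[ymin:ymax, xmin:xmax]
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    denom = dx * dx + dy * dy
    if denom == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - p0[0]) * dx + (yy - p0[1]) * dy) / denom, 0.0, 1.0)
    px, py = p0[0] + t * dx, p0[1] + t * dy
    mask = (xx - px) ** 2 + (yy - py) ** 2 <= r_px**2
    region = depth[ymin:ymax, xmin:xmax]
    zline = z0 + t * (z1 - z0)
    region[mask] = np.minimum(region[mask], zline[mask])


def _mm_to_px(mm: float, z: float, cam: CameraModel) -> float:
    return mm * cam.fx / z


# ---------------------------------------------------------------------------


class _Renderer:
    """Stateless per-frame renderer for one scene script."""

    def __init__(self, script: SceneScript):
        self.s = script
        self.cam = script.camera
        x0, y0, x1, y1 = script.table_rect
        self.seat_cy = (y0 + y1) / 2.0
        head_r_seated = _mm_to_px(HEAD_RADIUS, script.seated_head_mm, self.cam)
        # head centre just outside the table edge; forearms reach over it
        self.seat_cx = x0 - 0.8 * head_r_seated
        self.entry = (script.width * 0.08, script.height * 0.10)

    # -- scalar helpers -----------------------------------------------------

    def _posture(self, v: Visit, i: int) -> tuple[float, tuple[float, float]]:
        """(head depth mm, head centre px) for frame i of visit v."""
        s = self.s
        stand_d, sit_d = s.standing_head_mm, s.seated_head_mm
        seat = (self.seat_cx, self.seat_cy)
        sit_start = max(v.sit - SIT_TRANSITION, v.enter)
        if i < sit_start:  # walking in
            t = (i - v.enter) / max(sit_start - v.enter, 1)
            pos = (
                self.entry[0] + t * (seat[0] - self.entry[0]),
                self.entry[1] + t * (seat[1] - self.entry[1]),
            )
            return stand_d, pos
        if i < v.sit:  # sitting down
            t = (i - sit_start) / max(v.sit - sit_start, 1)
            return stand_d + t * (sit_d - stand_d), seat
        if i < v.stand:  # seated
            return sit_d, seat
        rise_end = min(v.stand + STAND_TRANSITION, v.leave)
        if i < rise_end:  # rising
            t = (i - v.stand) / max(rise_end - v.stand, 1)
            return sit_d + t * (stand_d - sit_d), seat
        # walking out
        t = (i - rise_end) / max(v.leave - rise_end, 1)
        pos = (
            seat[0] + t * (self.entry[0] - seat[0]),
            seat[1] + t * (self.entry[1] - seat[1]),
        )
        return stand_d, pos

    def _hand_pose(
        self, v: Visit, i: int, side: str, head: tuple[float, float], head_d: float
    ) -> tuple[tuple[float, float], float] | None:
        """Resting / travelling / at-mouth pose of one hand, or None."""
        s = self.s
        if not (v.hands_on_table <= i < v.stand):
            return None
        sign = 1.0 if side == "right" else -1.0
        table_z = s.table_top_mm - REST_HAND_ABOVE_TABLE
        rest_x = s.table_rect[0] + _mm_to_px(HAND_INSET, table_z, self.cam)
        rest_y = head[1] + sign * _mm_to_px(HAND_LATERAL, table_z, self.cam)
        rest = ((rest_x, rest_y), table_z)
        mouth_z = head_d + MOUTH_DROP
        mouth = (
            (head[0] + _mm_to_px(MOUTH_FORWARD, mouth_z, self.cam), head[1]),
            mouth_z,
        )
        for act in v.actions:
            if act.hand != side:
                continue
            lo, hi = act.start - RAISE_FRAMES, act.start + act.duration + LOWER_FRAMES
            if not (lo <= i < hi):
                continue
            if i < act.start:  # raising
                t = (i - lo) / RAISE_FRAMES
            elif i < act.start + act.duration:  # at the mouth
                t = 1.0
            else:  # lowering
                t = 1.0 - (i - act.start - act.duration) / LOWER_FRAMES
            pos = (
                rest[0][0] + t * (mouth[0][0] - rest[0][0]),
                rest[0][1] + t * (mouth[0][1] - rest[0][1]),
            )
            return (pos, rest[1] + t * (mouth[1] - rest[1]))
        return rest

    # -- frame rendering ----------------------------------------------------

    def background(self) -> np.ndarray:
        s = self.s
        depth = np.full((s.height, s.width), s.sensor_height_mm, dtype=float)
        x0, y0, x1, y1 = s.table_rect
        depth[y0:y1, x0:x1] = s.table_top_mm
        return depth

    def frame(self, i: int) -> np.ndarray:
        depth = self.background()
        visit = next((v for v in self.s.visits if v.enter <= i < v.leave), None)
        if visit is None:
            return depth
        head_d, head = self._posture(visit, i)
        cam = self.cam
        seated = visit.sit <= i < visit.stand
        # torso / shoulders
        torso_d = head_d + SHOULDER_DROP
        torso_cx = head[0] - (
            _mm_to_px(TORSO_BACK_OFFSET, torso_d, cam) if seated else 0.0
        )
        _paint_ellipse(
            depth,
            torso_cx,
            head[1],
            _mm_to_px(TORSO_HALF, torso_d, cam),
            _mm_to_px(SHOULDER_HALF, torso_d, cam),
            torso_d,
        )
        # arms + hands, only once they rest on (or move over) the table
        for side in ("left", "right"):
            pose = self._hand_pose(visit, i, side, head, head_d)
            if pose is None:
                continue
            (hx, hy), hz = pose
            sign = 1.0 if side == "right" else -1.0
            shoulder = (torso_cx, head[1] + sign * _mm_to_px(SHOULDER_HALF * 0.8, torso_d, cam))
            _paint_capsule(
                depth, shoulder, torso_d, (hx, hy), hz, _mm_to_px(ARM_RADIUS, hz, cam)
            )
            _paint_disc(depth, hx, hy, _mm_to_px(HAND_RADIUS, hz, cam), hz)
        # head painted last: the closest surface must be the head top
        _paint_disc(depth, head[0], head[1], _mm_to_px(HEAD_RADIUS, head_d, cam), head_d)
        return depth

    def corrupt(self, depth: np.ndarray, frame_index: int) -> np.ndarray:
        """Apply Gaussian mm noise plus hole dropout at depth discontinuities."""
        s = self.s
        if s.noise_sigma_mm == 0 and s.hole_rate == 0:
            return np.rint(depth).astype(np.int64)
        rng = np.random.default_rng((s.seed, frame_index + 1))
        out = depth.copy()
        if s.noise_sigma_mm > 0:
            out += rng.normal(0.0, s.noise_sigma_mm, size=out.shape)
        out = np.rint(out)
        np.clip(out, 1, None, out=out)
        if s.hole_rate > 0:
            jump = ndi.maximum_filter(depth, 3) - ndi.minimum_filter(depth, 3)
            near_edge = ndi.binary_dilation(
                jump > DISCONTINUITY_MM, iterations=HOLE_DILATE_PX
            )
            drop = near_edge & (rng.random(out.shape) < s.hole_rate)
            out[drop] = 0
        return out.astype(np.int64)


def render_background(script: SceneScript) -> DepthFrame:
    """Render the person-free reference frame (floor plus table)."""
    r = _Renderer(script)
    return DepthFrame(r.corrupt(r.background(), frame_index=-1), frame_index=0)


def render_sequence(script: SceneScript) -> tuple[list[DepthFrame], SceneTruth]:
    """Render the full scripted sequence and its ground truth."""
    r = _Renderer(script)
    frames = [
        DepthFrame(r.corrupt(r.frame(i), i), frame_index=i)
        for i in range(script.n_frames)
    ]
    windows = [
        (a.start + 1, a.start + a.duration)
        for v in script.visits
        for a in v.actions
    ]
    bounds = [(v.hands_on_table + 1, v.stand) for v in script.visits]
    truth = SceneTruth(
        sf_true=bounds[0][0] if bounds else 0,
        ef_true=bounds[-1][1] if bounds else 0,
        action_windows=windows,
        standing_distance_mm=script.standing_head_mm,
        sitting_distance_mm=script.seated_head_mm,
        visit_bounds=bounds,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# script factories


def _scaled_geometry(scale: float) -> dict:
    return {
        "width": int(round(640 * scale)),
        "height": int(round(480 * scale)),
        "table_rect": tuple(int(round(c * scale)) for c in (360, 140, 580, 340)),
    }


def _meal_visit(
    rng: np.random.Generator,
    n_actions: int,
    enter: int,
    dwell_frames: int = 160,
) -> Visit:
    """A standard visit: walk in, sit, eat ``n_actions`` times, rise, walk out."""
    sit = enter + 60 + SIT_TRANSITION
    hands = sit + 5
    cursor = hands + 10 + RAISE_FRAMES
    actions = []
    for _ in range(n_actions):
        duration = dwell_frames + int(rng.integers(-5, 16))
        actions.append(ActionSpec(start=cursor, duration=duration))
        cursor += duration + LOWER_FRAMES + int(rng.integers(50, 81)) + RAISE_FRAMES
    stand = cursor - RAISE_FRAMES + 10
    leave = stand + STAND_TRANSITION + 40
    return Visit(enter, sit, hands, stand, leave, tuple(actions))


def scripted_meal(
    n_actions: int,
    *,
    scale: float = 1.0,
    seed: int = 0,
    noise_sigma_mm: float = 0.0,
    hole_rate: float = 0.0,
    person_height_mm: float | None = None,
    dwell_frames: int = 160,
) -> SceneScript:
    """A single-visit meal scene with ``n_actions`` hand-to-mouth actions.

    Heights are drawn from the adult range 1620-1970 mm unless given.
    """
    rng = np.random.default_rng(seed)
    if person_height_mm is None:
        person_height_mm = float(rng.uniform(*HEIGHT_RANGE_MM))
    visit = _meal_visit(rng, n_actions, enter=10, dwell_frames=dwell_frames)
    return SceneScript(
        **_scaled_geometry(scale),
        person_height_mm=person_height_mm,
        visits=(visit,),
        n_frames=visit.leave + 30,
        noise_sigma_mm=noise_sigma_mm,
        hole_rate=hole_rate,
        seed=seed,
    )


def scripted_leave_and_return(
    n_actions: tuple[int, int] = (3, 3),
    *,
    scale: float = 1.0,
    seed: int = 0,
    away_frames: int = 200,
    noise_sigma_mm: float = 0.0,
    hole_rate: float = 0.0,
) -> SceneScript:
    """Two visits separated by a genuine departure, i.e., one meal that
    contributes two (SF, EF) segments."""
    rng = np.random.default_rng(seed)
    person_height_mm = float(rng.uniform(*HEIGHT_RANGE_MM))
    first = _meal_visit(rng, n_actions[0], enter=10)
    second = _meal_visit(rng, n_actions[1], enter=first.leave + away_frames)
    return SceneScript(
        **_scaled_geometry(scale),
        person_height_mm=person_height_mm,
        visits=(first, second),
        n_frames=second.leave + 30,
        noise_sigma_mm=noise_sigma_mm,
        hole_rate=hole_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML round-trip for the CLI


def script_to_yaml(script: SceneScript) -> str:
    doc = {
        "width": script.width,
        "height": script.height,
        "fps": script.fps,
        "sensor_height_mm": script.sensor_height_mm,
        "table_top_mm": script.table_top_mm,
        "table_rect": list(script.table_rect),
        "person_height_mm": script.person_height_mm,
        "sit_drop": script.sit_drop,
        "n_frames": script.n_frames,
        "noise_sigma_mm": script.noise_sigma_mm,
        "hole_rate": script.hole_rate,
        "seed": script.seed,
        "visits": [
            {
                "enter": v.enter,
                "sit": v.sit,
                "hands_on_table": v.hands_on_table,
                "stand": v.stand,
                "leave": v.leave,
                "actions": [
                    {"start": a.start, "duration": a.duration, "hand": a.hand}
                    for a in v.actions
                ],
            }
            for v in script.visits
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def script_from_yaml(text: str) -> SceneScript:
    doc = yaml.safe_load(text)
    visits = tuple(
        Visit(
            enter=v["enter"],
            sit=v["sit"],
            hands_on_table=v["hands_on_table"],
            stand=v["stand"],
            leave=v["leave"],
            actions=tuple(
                ActionSpec(a["start"], a["duration"], a.get("hand", "right"))
                for a in v.get("actions", [])
            ),
        )
        for v in doc.pop("visits", [])
    )
    doc["table_rect"] = tuple(doc.get("table_rect", (360, 140, 580, 340)))
    return SceneScript(visits=visits, **doc)
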