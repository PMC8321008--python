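"""Adaptive 50-node skeleton tracking by self-organizing-map fitting.

The body model is a Kohonen-style network of 50 nodes with a fixed
topology: a 9-node head group (centre + ring), a 5x7 torso lattice with
the two front corners replaced by shoulder attachments, and two 4-node
arm chains whose extremities are the hand joints.  Three designated
joints drive all downstream logic: Jhd (head centre), Jhl and Jhr (left
and right hands).  The remaining 47 nodes each anchor one local surface
patch ("plane") of the body model.

Per frame the node set is warm-started from the previous frame and
adapted to the person's point cloud by competitive learning: every
sampled point elects its nearest node (lowest index on ties) and nodes
move toward the neighbourhood-weighted mean of their electorate, with
learning rate and topological neighbourhood radius decaying linearly
over the frame's iterations.  An iteration is only accepted if the fit
energy (mean node-to-nearest-point distance) does not increase.

Long runs expose a failure mode where a hand node collapses onto the
head ("joint fusion").  It is detected as a sustained sub-threshold
head-hand distance — less than ~200 mm (equivalently ~300 px in the
image) for more than five seconds, i.e., 150 frames at 30 fps — and
repaired by re-initialising the model on the current cloud, which
restores separated joints instantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from scipy.sparse.csgraph import shortest_path

from .pointcloud import CameraModel, PointCloud, to_point_cloud
from .preprocess import fill_holes, median_denoise, subtract_background
from .types import DepthFrame

__all__ = [
    "SkeletonModel",
    "TrackerParams",
    "JointTrack",
    "build_topology",
    "init_model",
    "estimate_orientation",
    "fit_frame",
    "detect_fusion",
    "reset_model",
    "track_sequence",
]

N_NODES = 50
N_HEAD = 9
JHD, JHL, JHR = 0, 45, 49
TORSO_ROWS, TORSO_COLS = 7, 5
_LEFT_CHAIN = list(range(42, 46))
_RIGHT_CHAIN = list(range(46, 50))


def _torso_layout() -> tuple[dict[tuple[int, int], int], list[tuple[int, int]]]:
    """Torso (row, col) -> node id, skipping the two front corners."""
    mapping: dict[tuple[int, int], int] = {}
    nid = N_HEAD
    for r in range(TORSO_ROWS):
        for c in range(TORSO_COLS):
            if r == 0 and c in (0, TORSO_COLS - 1):
                continue  # replaced by the arm-chain attachments
            mapping[(r, c)] = nid
            nid += 1
    edges = []
    for (r, c), i in mapping.items():
        for rr, cc in ((r + 1, c), (r, c + 1)):
            j = mapping.get((rr, cc))
            if j is not None:
                edges.append((i, j))
    return mapping, edges


def build_topology() -> tuple[list[tuple[int, int]], dict[tuple[int, int], int]]:
    """Fixed 50-node edge list (defined once; unit-tested for the counts)."""
    edges: list[tuple[int, int]] = []
    ring = list(range(1, N_HEAD))
    for a, b in zip(ring, ring[1:] + ring[:1]):  # head ring cycle
        edges.append((a, b))
    edges += [(JHD, k) for k in ring]  # spokes to the head centre
    torso_map, torso_edges = _torso_layout()
    edges += torso_edges
    edges.append((JHD, torso_map[(0, TORSO_COLS // 2)]))  # neck
    left = list(range(42, 46))
    right = list(range(46, 50))
    edges.append((torso_map[(1, 0)], left[0]))
    edges += list(zip(left, left[1:]))
    edges.append((torso_map[(1, TORSO_COLS - 1)], right[0]))
    edges += list(zip(right, right[1:]))
    return edges, torso_map


_EDGES, _TORSO_MAP = build_topology()


def _hop_matrix() -> np.ndarray:
    rows, cols = zip(*_EDGES)
    data = np.ones(len(_EDGES))
    adj = csr_matrix(
        (np.r_[data, data], (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(N_NODES, N_NODES),
    )
    return shortest_path(adj, method="D", unweighted=True)


_HOPS = _hop_matrix()


@dataclass
class SkeletonModel:
    """50-node adaptive skeleton; geometry in sensor-centred mm."""

    nodes: np.ndarray  # (50, 3)
    orientation_deg: float = 0.0

    jhd_index = JHD
    jhl_index = JHL
    jhr_index = JHR

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (N_NODES, 3):
            raise ValueError(f"model requires {N_NODES} nodes, got {self.nodes.shape}")

    @property
    def head_indices(self) -> range:
        return range(N_HEAD)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(_EDGES)

    @property
    def plane_count(self) -> int:
        # every node except the three designated joints anchors one local
        # surface patch of the body model
        return N_NODES - 3

    @property
    def jhd(self) -> np.ndarray:
        return self.nodes[JHD]

    @property
    def jhl(self) -> np.ndarray:
        return self.nodes[JHL]

    @property
    def jhr(self) -> np.ndarray:
        return self.nodes[JHR]

    def copy(self) -> "SkeletonModel":
        return SkeletonModel(self.nodes.copy(), self.orientation_deg)


@dataclass(frozen=True)
class TrackerParams:
    """Schedules and thresholds of the per-frame SOM fit."""

    iterations_per_frame: int = 4
    lr_initial: float = 0.6
    lr_final: float = 0.2
    radius_initial: float = 1.5  # topology hops
    radius_final: float = 0.8  # keeps arm chains glued to their shoulders
    fusion_dist_mm: float = 200.0
    fusion_dist_px: float = 300.0
    fusion_frames: int = 150  # round(5 s * fps)
    fps: float = 30.0
    fusion_space: str = "metric"  # or "image"
    subsample: int = 2000  # seeded PC cap per frame; None = full cloud
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_final > self.lr_initial or self.radius_final > self.radius_initial:
            raise ValueError("schedules must be non-increasing")
        if min(self.lr_final, self.radius_final) <= 0:
            raise ValueError("schedules must stay positive")
        if self.fusion_space not in ("metric", "image"):
            raise ValueError("fusion_space must be 'metric' or 'image'")

    @property
    def fusion_threshold(self) -> float:
        return self.fusion_dist_mm if self.fusion_space == "metric" else self.fusion_dist_px


# ---------------------------------------------------------------------------
# model initialisation


def estimate_orientation(pc: PointCloud) -> float:
    """Facing direction (degrees in the X-Y plane) from the cloud shape.

    Seen from the ceiling, the arms reaching onto the table are the
    points farthest from the body centroid, so the facing direction is
    the mean direction of the top few percent of points by radial X-Y
    distance.  (The principal axis is useless here: the widest body
    spread is the shoulder line, perpendicular to facing.)
    """
    xy = pc.points[:, :2]
    rel = xy - xy.mean(axis=0)
    radius = np.linalg.norm(rel, axis=1)
    cut = np.percentile(radius, 95)
    tip = rel[radius >= cut].mean(axis=0)
    return float(np.degrees(np.arctan2(tip[1], tip[0])))


def init_model(pc: PointCloud, orientation_deg: float = 0.0) -> SkeletonModel:
    """Place the initial skeleton on a point cloud.

    Head nodes ring the cloud's highest (minimum-Z) region, the torso
    lattice spans the cloud's extent behind the head, rotated to the
    person's orientation, and the arm chains reach forward toward the
    table side.  Deterministic; raises on clouds too small to constrain
    the 50 nodes.
    """
    if len(pc) == 0:
        raise ValueError("cannot initialise on an empty point cloud")
    if len(pc) < N_NODES:
        raise ValueError(f"point cloud has {len(pc)} points; need >= {N_NODES}")
    pts = pc.points
    top = pts[int(np.argmin(pts[:, 2]))]
    theta = np.radians(orientation_deg)
    fwd = np.array([np.cos(theta), np.sin(theta)])  # facing (table) direction
    side = np.array([-np.sin(theta), np.cos(theta)])

    rel = pts[:, :2] - top[:2]
    back = -(rel @ fwd)
    back_extent = float(np.clip(np.percentile(back, 95), 200.0, 600.0))
    side_extent = float(np.clip(np.percentile(np.abs(rel @ side), 95), 150.0, 350.0))
    z_torso = float(np.percentile(pts[:, 2], 60))
    z_hand = float(np.percentile(pts[:, 2], 90))

    nodes = np.zeros((N_NODES, 3))
    nodes[JHD] = top + [0.0, 0.0, 10.0]
    ring_angles = np.linspace(0.0, 2 * np.pi, N_HEAD - 1, endpoint=False)
    for k, ang in zip(range(1, N_HEAD), ring_angles):
        offset = 80.0 * (np.cos(ang) * fwd + np.sin(ang) * side)
        nodes[k, :2] = top[:2] + offset
        nodes[k, 2] = top[2] + 40.0

    row_pos = np.linspace(60.0, back_extent, TORSO_ROWS)
    col_pos = np.linspace(-side_extent, side_extent, TORSO_COLS)
    for (r, c), nid in _TORSO_MAP.items():
        xy = top[:2] - row_pos[r] * fwd + col_pos[c] * side
        nodes[nid, :2] = xy
        nodes[nid, 2] = z_torso

    for chain, sgn in ((range(42, 46), -1.0), (range(46, 50), 1.0)):
        shoulder_xy = top[:2] - row_pos[1] * fwd + sgn * side_extent * side
        for k, nid in enumerate(chain):
            reach = 80.0 + 90.0 * (k + 1)
            nodes[nid, :2] = shoulder_xy + reach * fwd
            t = (k + 1) / len(chain)
            nodes[nid, 2] = z_torso + t * (z_hand - z_torso)

    model = SkeletonModel(nodes, orientation_deg)
    _ensure_joint_separation(model)
    return model


def _ensure_joint_separation(model: SkeletonModel, min_dist: float = 250.0) -> None:
    """Push an arm chain forward if its hand initialised too close to Jhd."""
    theta = np.radians(model.orientation_deg)
    fwd = np.array([np.cos(theta), np.sin(theta), 0.0])
    for hand in (JHL, JHR):
        gap = np.linalg.norm(model.nodes[hand] - model.nodes[JHD])
        if gap < min_dist:
            chain = range(42, 46) if hand == JHL else range(46, 50)
            model.nodes[list(chain)] += (min_dist - gap + 50.0) * fwd


# ---------------------------------------------------------------------------
# per-frame fitting


def _fit_energy(nodes: np.ndarray, pts: np.ndarray, tree: cKDTree | None = None) -> float:
    """Mean node-to-nearest-point distance (the fit energy)."""
    if tree is None:
        tree = cKDTree(pts)
    dist, _ = tree.query(nodes, k=1)
    return float(dist.mean())


def _subsample(pts: np.ndarray, cap: int | None, rng: np.random.Generator) -> np.ndarray:
    if cap is None or len(pts) <= cap:
        return pts
    idx = rng.choice(len(pts), size=cap, replace=False)
    return pts[idx]


def fit_frame(
    model: SkeletonModel,
    pc: PointCloud,
    params: TrackerParams,
    rng: np.random.Generator | None = None,
) -> SkeletonModel:
    """Adapt the model to one frame's point cloud.

    Warm-started competitive learning with monotone fit-energy descent:
    an iteration whose update would increase the energy is rejected and
    the fit stops early.  Nodes are finally confined to the cloud's
    bounding box inflated by 100 mm (a projection that can only decrease
    node-to-point distances).
    """
    if len(pc) == 0:
        raise ValueError("cannot fit an empty point cloud")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pts = _subsample(pc.points, params.subsample, rng)
    nodes = model.nodes.copy()
    lo = pts.min(axis=0) - 100.0
    hi = pts.max(axis=0) + 100.0
    nodes = np.clip(nodes, lo, hi)
    tree = cKDTree(pts)
    energy = _fit_energy(nodes, pts, tree)
    n_it = max(params.iterations_per_frame, 1)
    for it in range(n_it):
        frac = it / max(n_it - 1, 1)
        lr = params.lr_initial + frac * (params.lr_final - params.lr_initial)
        radius = params.radius_initial + frac * (params.radius_final - params.radius_initial)
        d2 = ((pts[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
        winners = np.argmin(d2, axis=1)  # ties -> lowest node index
        weights = np.exp(-(_HOPS**2) / (2.0 * radius**2))[:, winners]  # (nodes, pts)
        mass = weights.sum(axis=1)
        active = mass > 1e-12
        target = nodes.copy()
        target[active] = (weights[active] @ pts) / mass[active, None]
        candidate = np.clip(nodes + lr * (target - nodes), lo, hi)
        cand_energy = _fit_energy(candidate, pts, tree)
        if cand_energy > energy:
            continue  # reject this radius/rate step, try the tighter next one
        nodes, energy = candidate, cand_energy
    return SkeletonModel(nodes, model.orientation_deg)


def reset_model(model: SkeletonModel, pc: PointCloud) -> SkeletonModel:
    """Repair a joint fusion by re-initialising on the current cloud.

    The returned model has both head-hand separations above the fusion
    threshold by construction; repeated resets on an unchanged cloud are
    idempotent.
    """
    return init_model(pc, model.orientation_deg)


# ---------------------------------------------------------------------------
# joint track & fusion detection


@dataclass
class JointTrack:
    """Per-frame joint positions and head-hand distances (frames 1-based)."""

    frames: list[int] = field(default_factory=list)
    jhd: list[np.ndarray] = field(default_factory=list)
    jhl: list[np.ndarray] = field(default_factory=list)
    jhr: list[np.ndarray] = field(default_factory=list)
    dist_left_mm: list[float] = field(default_factory=list)
    dist_right_mm: list[float] = field(default_factory=list)
    dist_left_px: list[float] = field(default_factory=list)
    dist_right_px: list[float] = field(default_factory=list)
    reset_flag: list[bool] = field(default_factory=list)
    absent: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def append(
        self,
        frame: int,
        model: SkeletonModel | None,
        camera: CameraModel | None = None,
        reset: bool = False,
    ) -> None:
        if model is None:
            self.frames.append(frame)
            for lst in (self.jhd, self.jhl, self.jhr):
                lst.append(np.full(3, np.nan))
            for lst in (
                self.dist_left_mm,
                self.dist_right_mm,
                self.dist_left_px,
                self.dist_right_px,
            ):
                lst.append(np.nan)
            self.reset_flag.append(False)
            self.absent.append(True)
            return
        jhd, jhl, jhr = model.jhd, model.jhl, model.jhr
        self.frames.append(frame)
        self.jhd.append(jhd.copy())
        self.jhl.append(jhl.copy())
        self.jhr.append(jhr.copy())
        self.dist_left_mm.append(float(np.linalg.norm(jhl - jhd)))
        self.dist_right_mm.append(float(np.linalg.norm(jhr - jhd)))
        if camera is not None:
            px = camera.project(np.stack([jhd, jhl, jhr]))
            self.dist_left_px.append(float(np.linalg.norm(px[1] - px[0])))
            self.dist_right_px.append(float(np.linalg.norm(px[2] - px[0])))
        else:
            self.dist_left_px.append(np.nan)
            self.dist_right_px.append(np.nan)
        self.reset_flag.append(reset)
        self.absent.append(False)

    def distances(self, hand: str, space: str = "metric") -> np.ndarray:
        series = {
            ("left", "metric"): self.dist_left_mm,
            ("right", "metric"): self.dist_right_mm,
            ("left", "image"): self.dist_left_px,
            ("right", "image"): self.dist_right_px,
        }[(hand, space)]
        return np.asarray(series, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        def col(stack, j):
            return [p[j] for p in stack]

        return pd.DataFrame(
            {
                "frame": self.frames,
                "jhd_x": col(self.jhd, 0),
                "jhd_y": col(self.jhd, 1),
                "jhd_z": col(self.jhd, 2),
                "jhl_x": col(self.jhl, 0),
                "jhl_y": col(self.jhl, 1),
                "jhl_z": col(self.jhl, 2),
                "jhr_x": col(self.jhr, 0),
                "jhr_y": col(self.jhr, 1),
                "jhr_z": col(self.jhr, 2),
                "dist_left_mm": self.dist_left_mm,
                "dist_right_mm": self.dist_right_mm,
                "dist_left_px": self.dist_left_px,
                "dist_right_px": self.dist_right_px,
                "reset": self.reset_flag,
                "absent": self.absent,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "JointTrack":
        track = cls()
        track.frames = [int(f) for f in df["frame"]]
        track.jhd = [np.array(p) for p in df[["jhd_x", "jhd_y", "jhd_z"]].to_numpy()]
        track.jhl = [np.array(p) for p in df[["jhl_x", "jhl_y", "jhl_z"]].to_numpy()]
        track.jhr = [np.array(p) for p in df[["jhr_x", "jhr_y", "jhr_z"]].to_numpy()]
        track.dist_left_mm = list(df["dist_left_mm"].astype(float))
        track.dist_right_mm = list(df["dist_right_mm"].astype(float))
        track.dist_left_px = list(df["dist_left_px"].astype(float))
        track.dist_right_px = list(df["dist_right_px"].astype(float))
        track.reset_flag = list(df["reset"].astype(bool))
        track.absent = list(df["absent"].astype(bool))
        return track


def detect_fusion(track: JointTrack, params: TrackerParams) -> str:
    """Report a fused hand: head-hand distance below the threshold for the
    last ``fusion_frames`` consecutive recorded frames.

    Returns ``"left"``, ``"right"`` or ``"none"``.
    """
    n = params.fusion_frames
    if len(track) < n:
        return "none"
    for hand in ("left", "right"):
        tail = track.distances(hand, params.fusion_space)[-n:]
        if np.all(tail < params.fusion_threshold):
            return hand
    return "none"


# ---------------------------------------------------------------------------
# sequence tracking


def track_sequence(
    frames: list[DepthFrame],
    sf: int,
    ef: int,
    params: TrackerParams,
    *,
    background: DepthFrame,
    camera: CameraModel,
    min_diff_mm: float = 100.0,
    min_area_px: int = 300,
    median_window: int = 5,
    preprocessed: bool = False,
) -> JointTrack:
    """Track the skeleton over the meal segment [sf, ef] (1-based, inclusive).

    Per frame: preprocess, fit the warm-started model, log the joints,
    and reset the model whenever a joint fusion is recognised (the reset
    frame carries ``reset_flag``).  Frames without a person blob are
    logged as absent with the model frozen; absence breaks a fusion
    streak.
    """
    if not 1 <= sf <= ef <= len(frames):
        raise ValueError(f"require 1 <= sf ({sf}) <= ef ({ef}) <= {len(frames)}")
    def clean(f: DepthFrame) -> DepthFrame:
        return f if preprocessed else median_denoise(fill_holes(f), median_window)

    bg = clean(background)
    track = JointTrack()
    model: SkeletonModel | None = None
    streak = {"left": 0, "right": 0}
    for idx in range(sf - 1, ef):
        frame = clean(frames[idx])
        blobs = subtract_background(frame, bg, min_diff_mm, min_area_px)
        if not blobs:
            track.append(idx + 1, None)
            streak = {"left": 0, "right": 0}
            continue
        pc = to_point_cloud(blobs[0], camera)
        if len(pc) < N_NODES:
            track.append(idx + 1, None)
            streak = {"left": 0, "right": 0}
            continue
        rng = np.random.default_rng((params.seed, idx))
        if model is None:
            model = init_model(pc, estimate_orientation(pc))
        model = fit_frame(model, pc, params, rng)
        dists = {
            "left": float(np.linalg.norm(model.jhl - model.jhd)),
            "right": float(np.linalg.norm(model.jhr - model.jhd)),
        }
        if params.fusion_space == "image":
            px = camera.project(np.stack([model.jhd, model.jhl, model.jhr]))
            dists = {
                "left": float(np.linalg.norm(px[1] - px[0])),
                "right": float(np.linalg.norm(px[2] - px[0])),
            }
        for hand in streak:
            streak[hand] = streak[hand] + 1 if dists[hand] < params.fusion_threshold else 0
        fused = [h for h in ("left", "right") if streak[h] >= params.fusion_frames]
        track.append(idx + 1, model, camera, reset=bool(fused))
        if fused:
            # joint-preserving reset: re-initialise, but keep the chain of a
            # hand that was tracking fine — otherwise both fresh chains
            # compete for the one visible resting hand and can swap sides
            fresh = reset_model(model, pc)
            for hand, chain in (("left", _LEFT_CHAIN), ("right", _RIGHT_CHAIN)):
                if hand not in fused:
                    fresh.nodes[chain] = model.nodes[chain]
            model = fresh
            streak = {"left": 0, "right": 0}
    return track
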