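"""Shared independent oracles and synthetic inputs used across test modules."""

import numpy as np

from mealtrack.pointcloud import PointCloud
from mealtrack.som_tracker import JointTrack, SkeletonModel


def brute_force_nearest_fill(values):
    """Per hole pixel, the set of valid values at minimum Euclidean distance."""
    h, w = values.shape
    valid = [(y, x) for y in range(h) for x in range(w) if values[y, x] != 0]
    out = {}
    for y in range(h):
        for x in range(w):
            if values[y, x] != 0:
                continue
            d2 = [(vy - y) ** 2 + (vx - x) ** 2 for vy, vx in valid]
            best = min(d2)
            out[(y, x)] = {values[vy, vx] for (vy, vx), d in zip(valid, d2) if d == best}
    return out


def brute_force_median(values, window):
    """Per-pixel sorted-window median with edge-replicated borders."""
    h, w = values.shape
    r = window // 2
    padded = np.pad(values, r, mode="edge")
    out = np.empty_like(values)
    for y in range(h):
        for x in range(w):
            out[y, x] = np.median(padded[y : y + window, x : x + window])
    return out


def oracle_count(series, threshold, dwell, refractory):
    """Single-hand action-count oracle: iterative run scan, close-gap merge,
    dwell filter."""
    runs = []
    start = None
    for i, d in enumerate(series):
        if d < threshold and start is None:
            start = i
        elif d >= threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(series) - 1))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return sum(1 for s, e in merged if e - s + 1 >= dwell)


def make_distance_track(right, left=None):
    """JointTrack whose per-hand head-hand distances are given directly."""
    right = list(right)
    left = [500.0] * len(right) if left is None else list(left)
    track = JointTrack()
    for i, (dl, dr) in enumerate(zip(left, right)):
        model = SkeletonModel(np.zeros((50, 3)))
        model.nodes[model.jhl_index] = [dl, 0.0, 0.0]
        model.nodes[model.jhr_index] = [dr, 0.0, 0.0]
        track.append(i + 1, model)
    return track


def body_cloud(rng, n=800, facing_deg=0.0):
    """Standing-person-like cloud: head disc, torso slab, two arm strips."""
    theta = np.radians(facing_deg)
    fwd = np.array([np.cos(theta), np.sin(theta)])
    side = np.array([-np.sin(theta), np.cos(theta)])

    def at(f, s, z, jitter=15.0):
        xy = f * fwd + s * side + rng.normal(0, jitter, size=2)
        return [xy[0], xy[1], z + rng.normal(0, 5)]

    pts = []
    for _ in range(n // 4):
        pts.append(at(rng.uniform(-80, 80), rng.uniform(-80, 80), 1500))
    for _ in range(n // 2):
        pts.append(at(rng.uniform(-400, -60), rng.uniform(-220, 220), 1800))
    for _ in range(n // 8):
        f = rng.uniform(0, 300)
        pts.append(at(f, -180, 1800 + 0.6 * f))
    for _ in range(n // 8):
        f = rng.uniform(0, 300)
        pts.append(at(f, 180, 1800 + 0.6 * f))
    pts = np.asarray(pts, dtype=float)
    return PointCloud(points=pts, pixels=np.zeros((len(pts), 2), dtype=int))
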