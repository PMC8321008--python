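"""On-disk formats for depth sequences, SetParam tables and annotations.

Depth sequences are stored as a directory of lexicographically ordered
16-bit single-channel PNG files (mm as unsigned integer — lossless over
the whole Kinect-v1 range) plus a ``meta.yaml`` sidecar holding fps,
sensor height and a free-text source label.

The SetParam table is delimited text laid out like the reference tables:
three rows labelled TN, SF, EF and one column per detected segment.
Annotations are ordinary CSV with one row per test.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .types import DepthFrame, GroundTruth, Segment, SequenceMeta, SessionTable

__all__ = [
    "read_depth_sequence",
    "write_depth_sequence",
    "write_setparam",
    "read_setparam",
    "read_annotations",
    "write_annotations",
    "load_reference_table",
]

_META_NAME = "meta.yaml"


def write_depth_sequence(
    frames: list[DepthFrame], meta: SequenceMeta, path: str | Path
) -> None:
    """Write a depth sequence as a 16-bit PNG stack plus metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digits = max(6, len(str(max(len(frames) - 1, 0))))
    for i, frame in enumerate(frames):
        values = np.asarray(frame.values)
        if values.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError(f"frame {i}: depth exceeds 16-bit range")
        iio.imwrite(path / f"depth_{i:0{digits}d}.png", values.astype(np.uint16))
    meta_doc = {
        "fps": float(meta.fps),
        "sensor_height_mm": float(meta.sensor_height_mm),
        "frame_count": len(frames),
        "source_id": meta.source_id,
    }
    (path / _META_NAME).write_text(yaml.safe_dump(meta_doc, sort_keys=False))


def read_depth_sequence(path: str | Path) -> tuple[list[DepthFrame], SequenceMeta]:
    """Read a depth sequence directory written by :func:`write_depth_sequence`.

    Frames are ordered lexicographically by filename and re-indexed 0..N-1.
    A missing metadata sidecar or inconsistent frame dimensions are hard
    errors; an empty directory raises ``no frames found``.
    """
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.is_file():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    doc = yaml.safe_load(meta_path.read_text()) or {}
    meta = SequenceMeta(
        fps=float(doc.get("fps", 30.0)),
        sensor_height_mm=float(doc.get("sensor_height_mm", 3000.0)),
        frame_count=int(doc.get("frame_count", 0)),
        source_id=str(doc.get("source_id", "")),
    )
    png_files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not png_files:
        raise FileNotFoundError(f"no frames found in {path}")
    frames: list[DepthFrame] = []
    shape: tuple[int, int] | None = None
    for i, png in enumerate(png_files):
        values = np.asarray(iio.imread(png))
        if values.ndim != 2:
            raise ValueError(f"{png.name}: expected single-channel depth image")
        if shape is None:
            shape = values.shape  # type: ignore[assignment]
        elif values.shape != shape:
            raise ValueError(
                f"{png.name}: frame dimensions {values.shape} differ from {shape}"
            )
        frames.append(DepthFrame(values.astype(np.int64), frame_index=i))
    meta.frame_count = len(frames)
    return frames, meta


def write_setparam(table: SessionTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a SessionTable as a 3-row (TN/SF/EF) delimited text file."""
    path = Path(path)
    rows = [
        ["TN"] + [str(s.test_number) for s in table],
        ["SF"] + [str(s.sf) for s in table],
        ["EF"] + [str(s.ef) for s in table],
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerows(rows)


def read_setparam(path: str | Path, delimiter: str = ",") -> SessionTable:
    """Read a SetParam file back into a SessionTable."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    if len(rows) != 3 or [r[0] for r in rows] != ["TN", "SF", "EF"]:
        raise ValueError(f"{path}: expected three rows labelled TN, SF, EF")
    tn, sf, ef = (row[1:] for row in rows)
    if not (len(tn) == len(sf) == len(ef)):
        raise ValueError(f"{path}: ragged SetParam columns")
    return SessionTable(
        [Segment(int(t), int(s), int(e)) for t, s, e in zip(tn, sf, ef)]
    )


def read_annotations(path: str | Path) -> list[GroundTruth]:
    """Read ground-truth annotations (test_number, sf_gt, ef_gt, actions_gt).

    Accepts comma- or whitespace-delimited text with a header; 1-based
    frame indices are preserved.  A row with SF > EF is a validation error.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    required = ["test_number", "sf_gt", "ef_gt", "actions_gt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    return [
        GroundTruth(int(r.test_number), int(r.sf_gt), int(r.ef_gt), int(r.actions_gt))
        for r in df.itertuples()
    ]


def write_annotations(records: list[GroundTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "test_number": g.test_number,
                "sf_gt": g.sf_gt,
                "ef_gt": g.ef_gt,
                "actions_gt": g.actions_gt,
            }
            for g in records
        ],
        columns=["test_number", "sf_gt", "ef_gt", "actions_gt"],
    ).to_csv(path, index=False)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a bundled reference-results table.

    Available tables, transcribed from a 33-test / 7-subject top-view meal
    monitoring campaign:

    - ``tests_ratio03``: automatic/manual/ground-truth SF & EF at Ratio=0.3
    - ``tests_ratio02``: same at Ratio=0.2 (contains ND = not detected)
    - ``actions``: detected vs ground-truth intake-action counts
    """
    fname = {
        "tests_ratio03": "reference_tests_ratio03.csv",
        "tests_ratio02": "reference_tests_ratio02.csv",
        "actions": "reference_actions.csv",
    }.get(name)
    if fname is None:
        raise KeyError(f"unknown reference table {name!r}")
    with resources.files("mealtrack.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)
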