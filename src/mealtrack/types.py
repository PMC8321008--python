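"""Core value types shared across the pipeline.

All depth values are sensor-to-surface distances in integer millimetres;
a value of 0 marks an invalid ("hole") pixel.  Frame indices are 0-based
inside the library; the on-disk SetParam and annotation formats use the
1-based convention of the reference tables, and the conversion happens
only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "DepthFrame",
    "SequenceMeta",
    "GroundTruth",
    "Segment",
    "SessionTable",
]


@dataclass
class DepthFrame:
    """A single top-down depth image.

    Parameters
    ----------
    values
        2-D integer array of sensor-to-surface distances in mm.
        0 encodes an invalid measurement (hole).
    frame_index
        0-based position of the frame in its sequence.
    """

    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"depth frame must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative (0 marks a hole)")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "DepthFrame":
        return DepthFrame(self.values.copy(), self.frame_index)


@dataclass
class SequenceMeta:
    """Acquisition metadata for a depth sequence."""

    fps: float = 30.0
    sensor_height_mm: float = 3000.0
    frame_count: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.sensor_height_mm <= 0:
            raise ValueError("sensor_height_mm must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Reference annotation for one test: meal bounds and action count.

    Frame indices are 1-based, matching the annotation file format.
    """

    test_number: int
    sf_gt: int
    ef_gt: int
    actions_gt: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.sf_gt <= self.ef_gt):
            raise ValueError(
                f"test {self.test_number}: require 1 <= SF ({self.sf_gt}) "
                f"<= EF ({self.ef_gt})"
            )
        if self.actions_gt < 0:
            raise ValueError("actions_gt must be >= 0")


@dataclass(frozen=True)
class Segment:
    """One detected meal segment: (test number, start frame, end frame), 1-based."""

    test_number: int
    sf: int
    ef: int

    def __post_init__(self) -> None:
        if self.sf > self.ef:
            raise ValueError(f"segment SF ({self.sf}) > EF ({self.ef})")


@dataclass
class SessionTable:
    """The SetParam structure: an ordered list of meal segments.

    A single meal contributes several segments when the subject briefly
    leaves the table and returns; segments of the same test are ordered
    and non-overlapping.
    """

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_test: dict[int, int] = {}
        for seg in self.segments:
            prev_ef = by_test.get(seg.test_number)
            if prev_ef is not None and seg.sf <= prev_ef:
                raise ValueError(
                    f"test {seg.test_number}: segments overlap or are out of order"
                )
            by_test[seg.test_number] = seg.ef

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def append(self, segment: Segment) -> None:
        self.segments.append(segment)
        self.__post_init__()

    def for_test(self, test_number: int) -> list[Segment]:
        return [s for s in self.segments if s.test_number == test_number]
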