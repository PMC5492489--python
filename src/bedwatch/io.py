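"""Data model and on-disk formats for thermal/ultrasonic recordings.

A recording is a 1 Hz sequence of frames.  Each frame carries a 60-row by
80-column grid of integer temperature counts (one count = 0.05 degC) from a
ceiling-mounted long-wave infrared array, plus a single ultrasonic distance
reading in centimetres (ceiling to nearest reflecting object).

Conventions enforced everywhere in the package:

* grids are row-major ``numpy`` arrays of shape ``(60, 80)``; a point
  ``(x, y)`` means ``(column, row)``, 0-based;
* distance readings are valid on ``[25, 220]`` cm; anything the device
  reports outside that range is stored as the sentinel ``221`` ("beyond
  range").

File dialects (all plain UTF-8 text):

* frame CSV: one frame per line, ``index,distance_cm,v0,...,v4799`` with the
  4800 grid values row-major; an optional header line is tolerated;
* frame JSON-lines: one object per line with keys ``index``,
  ``distance_cm`` and ``grid`` (flat list of 4800 ints, row-major);
* bed-mask CSV: 60 lines of 80 comma-separated 0/1 values;
* label CSV: ``index,location,posture``;
* event CSV: ``type,frame_index,hazard_flag``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

import numpy as np

GRID_ROWS = 60
GRID_COLS = 80
GRID_SIZE = GRID_ROWS * GRID_COLS

DISTANCE_MIN = 25
DISTANCE_MAX = 220
#: Sentinel for "no echo / beyond usable range".
DISTANCE_BEYOND = 221


class FormatError(ValueError):
    """Raised when an on-disk record does not match its dialect."""


class Location(str, Enum):
    NONE = "None"
    BED = "Bed"
    BEDRAIL = "Bedrail"
    FLOOR = "Floor"


class Posture(str, Enum):
    NONE = "None"
    LAYING = "Laying"
    SITTING = "Sitting"
    STANDING = "Standing"


class EventType(str, Enum):
    FALL = "Fall"
    BED_ENTRY = "BedEntry"
    BED_EXIT = "BedExit"
    AREA_ENTRY = "AreaEntry"
    AREA_EXIT = "AreaExit"


#: Fixed class orders, used for deterministic tie-breaking in classifiers.
LOCATION_ORDER = (Location.NONE, Location.BED, Location.BEDRAIL, Location.FLOOR)
POSTURE_ORDER = (Posture.NONE, Posture.LAYING, Posture.SITTING, Posture.STANDING)


def encode_distance(raw_cm: int) -> int:
    """Map a raw distance reading onto the stored representation.

    Readings inside the usable [25, 220] cm range pass through; anything
    else becomes the DISTANCE_BEYOND sentinel.
    """
    raw_cm = int(raw_cm)
    if DISTANCE_MIN <= raw_cm <= DISTANCE_MAX:
        return raw_cm
    return DISTANCE_BEYOND


@dataclass(frozen=True)
class ThermalFrame:
    """One time step: thermal grid, distance reading and frame index."""

    index: int
    grid: np.ndarray
    distance_cm: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be non-negative, got {self.index}")
        grid = np.asarray(self.grid)
        if grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(
                f"grid must have shape ({GRID_ROWS}, {GRID_COLS}), got {grid.shape}"
            )
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(f"grid must be integer-valued, got dtype {grid.dtype}")
        if (grid < 0).any():
            raise ValueError("grid values must be non-negative")
        if not (
            DISTANCE_MIN <= self.distance_cm <= DISTANCE_MAX
            or self.distance_cm == DISTANCE_BEYOND
        ):
            raise ValueError(
                f"distance_cm must be in [{DISTANCE_MIN}, {DISTANCE_MAX}] or "
                f"{DISTANCE_BEYOND}, got {self.distance_cm}"
            )
        object.__setattr__(self, "grid", grid)


@dataclass
class FrameSequence:
    """Ordered frames with strictly increasing indices (nominal 1 s period)."""

    frames: List[ThermalFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ThermalFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class BedMask:
    """Boolean 60x80 grid; True marks pixels inside the bed boundary."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(
                f"bed mask must have shape ({GRID_ROWS}, {GRID_COLS}), got {mask.shape}"
            )
        if not mask.any():
            raise ValueError("mask has no bed pixels")
        if mask.all():
            raise ValueError("mask has no non-bed pixels")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class FrameLabel:
    """Ground-truth (location, posture) for one frame."""

    index: int
    location: Location
    posture: Posture

    def __post_init__(self) -> None:
        if (
            self.location in (Location.BED, Location.BEDRAIL)
            and self.posture is Posture.STANDING
        ):
            raise ValueError(
                f"({self.location.value}, Standing) is not an admissible pose"
            )


@dataclass(frozen=True)
class EventRecord:
    """A typed event anchored at the frame where its stable state confirmed."""

    type: EventType
    frame_index: int
    hazard_flag: bool = False


def _parse_enum(token: str, enum_cls, kind: str):
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise FormatError(
            f"unknown {kind} token {token!r}; allowed: {allowed}"
        ) from None


def _frame_from_fields(fields: Sequence[str], row: int) -> ThermalFrame:
    if len(fields) != 2 + GRID_SIZE:
        raise FormatError(
            f"row {row}: expected {2 + GRID_SIZE} values "
            f"(index, distance, {GRID_SIZE} readings), got {len(fields)}"
        )
    try:
        values = [int(v) for v in fields]
    except ValueError as exc:
        raise FormatError(f"row {row}: non-integer cell ({exc})") from None
    grid = np.array(values[2:], dtype=np.int64).reshape(GRID_ROWS, GRID_COLS)
    return ThermalFrame(index=values[0], grid=grid, distance_cm=encode_distance(values[1]))


def read_frames(path: Union[str, Path], dialect: str = "csv") -> FrameSequence:
    """Read a frame sequence from ``path`` in the given dialect.

    Malformed rows raise :class:`FormatError` naming the 1-based row.
    """
    path = Path(path)
    frames: List[ThermalFrame] = []
    if dialect == "csv":
        with path.open("r", encoding="utf-8") as fh:
            for row, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split(",")
                if row == 1 and not _is_int(fields[0]):
                    continue  # header line
                frames.append(_frame_from_fields(fields, row))
    elif dialect == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for row, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"row {row}: invalid JSON ({exc})") from None
                grid = obj.get("grid")
                if grid is None or len(grid) != GRID_SIZE:
                    n = 0 if grid is None else len(grid)
                    raise FormatError(
                        f"row {row}: expected {GRID_SIZE} grid values, got {n}"
                    )
                fields = [obj.get("index", 0), obj.get("distance_cm", 0), *grid]
                frames.append(_frame_from_fields([str(v) for v in fields], row))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return FrameSequence(frames)


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def write_frames(seq: FrameSequence, path: Union[str, Path], dialect: str = "csv") -> None:
    """Write a frame sequence losslessly in the given dialect."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", encoding="utf-8") as fh:
            for f in seq:
                flat = ",".join(str(int(v)) for v in f.grid.ravel())
                fh.write(f"{f.index},{f.distance_cm},{flat}\n")
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for f in seq:
                fh.write(
                    json.dumps(
                        {
                            "index": f.index,
                            "distance_cm": f.distance_cm,
                            "grid": [int(v) for v in f.grid.ravel()],
                        }
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_bed_mask(path: Union[str, Path]) -> BedMask:
    rows = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for row, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != GRID_COLS:
                raise FormatError(
                    f"row {row}: expected {GRID_COLS} values, got {len(fields)}"
                )
            try:
                rows.append([int(v) for v in fields])
            except ValueError:
                raise FormatError(f"row {row}: non-integer cell") from None
    arr = np.array(rows, dtype=int)
    if arr.shape != (GRID_ROWS, GRID_COLS):
        raise FormatError(
            f"mask must be {GRID_ROWS}x{GRID_COLS}, got {arr.shape[0]}x"
            f"{arr.shape[1] if arr.ndim == 2 else 0}"
        )
    return BedMask(arr.astype(bool))


def write_bed_mask(bed: BedMask, path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for row in bed.mask:
            fh.write(",".join("1" if v else "0" for v in row) + "\n")


def read_labels(path: Union[str, Path]) -> List[FrameLabel]:
    labels: List[FrameLabel] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for row, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if row == 1 and not _is_int(fields[0]):
                continue
            if len(fields) != 3:
                raise FormatError(f"row {row}: expected index,location,posture")
            labels.append(
                FrameLabel(
                    index=int(fields[0]),
                    location=_parse_enum(fields[1], Location, "location"),
                    posture=_parse_enum(fields[2], Posture, "posture"),
                )
            )
    return labels


def write_labels(labels: Iterable[FrameLabel], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("index,location,posture\n")
        for lab in labels:
            fh.write(f"{lab.index},{lab.location.value},{lab.posture.value}\n")


def read_events(path: Union[str, Path]) -> List[EventRecord]:
    events: List[EventRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for row, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if row == 1 and fields[0] == "type":
                continue
            if len(fields) != 3:
                raise FormatError(f"row {row}: expected type,frame_index,hazard_flag")
            events.append(
                EventRecord(
                    type=_parse_enum(fields[0], EventType, "event type"),
                    frame_index=int(fields[1]),
                    hazard_flag=fields[2].strip().lower() in ("1", "true"),
                )
            )
    return events


def write_events(events: Iterable[EventRecord], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("type,frame_index,hazard_flag\n")
        for ev in events:
            fh.write(f"{ev.type.value},{ev.frame_index},{int(ev.hazard_flag)}\n")
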