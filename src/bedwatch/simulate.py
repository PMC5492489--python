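"""Seeded simulator of ceiling-view thermal + ultrasonic recordings.

The simulator emulates the sensing geometry of a ceiling-mounted 80x60
long-wave infrared array co-located with a narrow-cone ultrasonic ranger
over a hospital-style bed: an ambient-temperature room, a rectangular bed
region, a single person rendered as a warm blob, residual heat left on
vacated contact surfaces, iid Gaussian sensor noise, and a distance reading
equal to the ceiling-to-nearest-surface range inside the ultrasonic cone.

The body is modelled as two overlapping axis-aligned Gaussian heat sources
(torso + head) added to ambient; the silhouette is where the combined
amplitude exceeds the imprint threshold.  Posture controls the torso spread
(Standing: a compact head-and-shoulders blob of roughly 40 px, Sitting
roughly 120 px, Laying an elongated footprint of roughly 260 px) and the
head hotspot always carries the maximum temperature.  Vacated contact
pixels keep a residual amplitude that decays exponentially to ambient with
a configurable time constant.

Scenarios are scripts of (location, posture, position, duration) segments
sampled at 1 Hz.  Ground-truth frame labels follow the script directly;
ground-truth events are derived from segment transitions with the same
transition taxonomy the event engine uses, anchored at the frame where the
corresponding stable-state window completes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .events import WindowConfig, transition_events
from .io import (
    DISTANCE_BEYOND,
    GRID_COLS,
    GRID_ROWS,
    BedMask,
    EventRecord,
    FrameLabel,
    FrameSequence,
    Location,
    Posture,
    ThermalFrame,
    encode_distance,
)

#: Torso/head Gaussian spreads (sigma_row, sigma_col) per posture, in pixels.
_TORSO_SIGMA: Dict[Posture, Tuple[float, float]] = {
    Posture.STANDING: (1.8, 1.8),
    Posture.SITTING: (3.1, 3.1),
    Posture.LAYING: (3.2, 6.4),
}
#: Head-centre offset (rows, cols) from the torso centre per posture.
_HEAD_OFFSET: Dict[Posture, Tuple[float, float]] = {
    Posture.STANDING: (0.0, 0.0),
    Posture.SITTING: (0.0, 2.0),
    Posture.LAYING: (0.0, 8.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Room, sensor and body parameters (temperatures in sensor counts)."""

    ambient: int = 420                       # 21.0 degC
    bed_rect: Tuple[int, int, int, int] = (15, 45, 10, 45)  # rows/cols, half-open
    cone_center: Tuple[int, int] = (30, 32)  # (row, col) under the device
    cone_radius: float = 26.0                # pixels
    floor_distance: int = 220                # cm, ceiling to floor
    bed_surface_distance: int = 180          # cm, ceiling to empty bed
    body_amp: float = 150.0                  # torso amplitude over ambient
    head_amp: float = 120.0                  # extra head-hotspot amplitude
    contact_amp: float = 80.0                # residual amplitude at departure
    decay_tau: float = 20.0                  # residual decay constant, s
    noise_sigma: float = 2.0                 # counts (0.1 degC)
    silhouette_level: float = 20.0           # amplitude delimiting body pixels
    distance_jitter: int = 2                 # +- cm uniform jitter

    #: ceiling-to-body-top distance (cm) per posture when inside the cone
    standing_distance: int = 75
    sitting_distance: int = 130
    laying_bed_distance: int = 160
    laying_floor_distance: int = 195


@dataclass(frozen=True)
class Segment:
    location: Location
    posture: Posture
    position: Tuple[int, int]  # (row, col) torso centre; ignored for None
    duration_s: int

    def __post_init__(self) -> None:
        if self.duration_s < 1:
            raise ValueError("segment duration must be >= 1 s")
        if (
            self.location in (Location.BED, Location.BEDRAIL)
            and self.posture is Posture.STANDING
        ):
            raise ValueError("(Bed|Bedrail, Standing) poses cannot be scripted")
        if (self.location is Location.NONE) != (self.posture is Posture.NONE):
            raise ValueError("location and posture must be None together")


@dataclass(frozen=True)
class ScenarioScript:
    segments: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.location is b.location and a.posture is b.posture:
                raise ValueError("consecutive segments must differ")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def n_frames(self) -> int:
        return sum(s.duration_s for s in self.segments)


def bed_mask(scene: SceneConfig) -> BedMask:
    r0, r1, c0, c1 = scene.bed_rect
    mask = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
    mask[r0:r1, c0:c1] = True
    return BedMask(mask)


def _body_field(scene: SceneConfig, seg: Segment) -> np.ndarray:
    """Amplitude-over-ambient field of the body for one segment."""
    rows = np.arange(GRID_ROWS)[:, None]
    cols = np.arange(GRID_COLS)[None, :]
    r, c = seg.position
    sr, sc = _TORSO_SIGMA[seg.posture]
    torso = np.exp(-(((rows - r) ** 2) / (2 * sr**2) + ((cols - c) ** 2) / (2 * sc**2)))
    hr, hc = _HEAD_OFFSET[seg.posture]
    head = np.exp(
        -(((rows - r - hr) ** 2) + ((cols - c - hc) ** 2)) / (2 * 1.8**2)
    )
    return scene.body_amp * torso + scene.head_amp * head


def _check_in_grid(scene: SceneConfig, seg: Segment) -> None:
    field_ = _body_field(scene, seg)
    sil = field_ > scene.silhouette_level
    if not sil.any():
        raise ValueError(f"segment at {seg.position} renders no body pixels")
    # silhouette touching the border means part of the body is off-grid
    if sil[0, :].any() or sil[-1, :].any() or sil[:, 0].any() or sil[:, -1].any():
        raise ValueError(f"segment at {seg.position} places the body outside the grid")


def _distance_for(scene: SceneConfig, seg: Segment) -> int:
    """Nearest-surface range inside the ultrasonic cone, in cm."""
    if seg.location is Location.NONE:
        return scene.bed_surface_distance
    rr = seg.position[0] - scene.cone_center[0]
    cc = seg.position[1] - scene.cone_center[1]
    in_cone = rr * rr + cc * cc <= scene.cone_radius**2
    if seg.posture is Posture.STANDING:
        body_top = scene.standing_distance
    elif seg.posture is Posture.SITTING:
        body_top = scene.sitting_distance
    elif seg.location is Location.FLOOR:
        body_top = scene.laying_floor_distance
    else:
        body_top = scene.laying_bed_distance
    if in_cone:
        return min(body_top, scene.bed_surface_distance)
    return scene.bed_surface_distance


def script_labels(script: ScenarioScript, start_index: int = 0) -> List[FrameLabel]:
    """Per-frame ground-truth labels implied by the script."""
    labels: List[FrameLabel] = []
    idx = start_index
    for seg in script.segments:
        for _ in range(seg.duration_s):
            labels.append(FrameLabel(idx, seg.location, seg.posture))
            idx += 1
    return labels


def script_events(
    script: ScenarioScript,
    cfg: Optional[WindowConfig] = None,
    start_index: int = 0,
) -> List[EventRecord]:
    """Ground-truth events implied by segment transitions.

    Each event is anchored at the frame where a stable-state window of its
    length completes, i.e. N - 1 frames into the new segment.
    """
    cfg = cfg or WindowConfig()
    events: List[EventRecord] = []
    idx = start_index
    prev: Optional[Segment] = None
    for seg in script.segments:
        if prev is not None:
            old = (prev.location, prev.posture)
            new = (seg.location, seg.posture)
            hazard = new == (Location.BEDRAIL, Posture.LAYING)
            for ev_type, n_req in transition_events(old, new, cfg):
                events.append(EventRecord(ev_type, idx + n_req - 1, hazard_flag=hazard))
        idx += seg.duration_s
        prev = seg
    return sorted(events, key=lambda e: (e.frame_index, e.type.value))


def render_sequence(
    scene: SceneConfig,
    script: ScenarioScript,
    seed: int,
    start_index: int = 0,
) -> Tuple[FrameSequence, List[FrameLabel], List[EventRecord]]:
    """Render a scripted scenario into frames, labels and ground-truth events.

    Deterministic per seed: identical (scene, script, seed) triples yield
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    for seg in script.segments:
        if seg.location is not Location.NONE:
            _check_in_grid(scene, seg)

    decay = float(np.exp(-1.0 / scene.decay_tau))
    residual = np.zeros((GRID_ROWS, GRID_COLS), dtype=float)
    frames: List[ThermalFrame] = []
    idx = start_index
    for seg in script.segments:
        if seg.location is Location.NONE:
            body = np.zeros((GRID_ROWS, GRID_COLS), dtype=float)
            sil = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
        else:
            body = _body_field(scene, seg)
            sil = body > scene.silhouette_level
        base_distance = _distance_for(scene, seg)
        for _ in range(seg.duration_s):
            residual *= decay
            residual[residual < 1.0] = 0.0
            # contact surfaces under the body are re-warmed every frame
            residual[sil] = scene.contact_amp
            amp = np.where(sil, np.maximum(body, residual), residual)
            noise = rng.normal(0.0, scene.noise_sigma, size=amp.shape)
            grid = np.rint(scene.ambient + amp + noise).astype(np.int64)
            np.clip(grid, 0, None, out=grid)
            jitter = int(rng.integers(-scene.distance_jitter, scene.distance_jitter + 1))
            frames.append(
                ThermalFrame(
                    index=idx,
                    grid=grid,
                    distance_cm=encode_distance(base_distance + jitter),
                )
            )
            idx += 1
    labels = script_labels(script, start_index)
    events = script_events(script, start_index=start_index)
    return FrameSequence(frames), labels, events


def body_silhouettes(
    scene: SceneConfig, script: ScenarioScript
) -> List[np.ndarray]:
    """Per-frame ground-truth body silhouette masks (noise-free)."""
    out: List[np.ndarray] = []
    for seg in script.segments:
        if seg.location is Location.NONE:
            sil = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
        else:
            sil = _body_field(scene, seg) > scene.silhouette_level
        out.extend([sil] * seg.duration_s)
    return out


# -- scenario construction ----------------------------------------------


def _jitter_pos(rng: np.random.Generator, pos: Tuple[int, int], r: int = 2) -> Tuple[int, int]:
    return (
        int(pos[0] + rng.integers(-r, r + 1)),
        int(pos[1] + rng.integers(-r, r + 1)),
    )


def _dur(rng: np.random.Generator, lo: int = 12, hi: int = 18) -> int:
    return int(rng.integers(lo, hi + 1))


#: Nominal torso-centre positions for the default scene geometry.
POSITIONS = {
    "bed": (30, 26),
    "bedrail": (30, 44),
    "floor_stand": (30, 55),
    "floor_sit": (33, 55),
    "floor_lay": (50, 58),
}


def training_script(rng: np.random.Generator, lead_in: int = 12) -> ScenarioScript:
    """A long scenario visiting every (location, posture) class.

    Starts with an empty-room segment of ``lead_in`` frames usable for
    background estimation.
    """
    p = {k: _jitter_pos(rng, v) for k, v in POSITIONS.items()}
    segs = [
        Segment(Location.NONE, Posture.NONE, (0, 0), lead_in),
        Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)),
        Segment(Location.FLOOR, Posture.SITTING, p["floor_sit"], _dur(rng)),
        Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)),
        Segment(Location.BEDRAIL, Posture.SITTING, p["bedrail"], _dur(rng)),
        Segment(Location.BED, Posture.LAYING, p["bed"], _dur(rng, 15, 22)),
        Segment(Location.BED, Posture.SITTING, p["bed"], _dur(rng)),
        Segment(Location.BEDRAIL, Posture.LAYING, p["bedrail"], _dur(rng)),
        Segment(Location.BED, Posture.LAYING, p["bed"], _dur(rng, 15, 22)),
        Segment(Location.FLOOR, Posture.LAYING, p["floor_lay"], _dur(rng, 15, 22)),
        Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)),
        Segment(Location.NONE, Posture.NONE, (0, 0), _dur(rng)),
    ]
    return ScenarioScript(tuple(segs))


def fall_script(rng: np.random.Generator, lead_in: int = 12, from_bed: bool = True) -> ScenarioScript:
    """Enter the area, get into bed (or stand), fall to the floor, exit."""
    p = {k: _jitter_pos(rng, v) for k, v in POSITIONS.items()}
    segs = [Segment(Location.NONE, Posture.NONE, (0, 0), lead_in)]
    segs.append(Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)))
    if from_bed:
        segs.append(Segment(Location.BED, Posture.SITTING, p["bed"], _dur(rng)))
        segs.append(Segment(Location.BED, Posture.LAYING, p["bed"], _dur(rng, 15, 22)))
    segs.append(Segment(Location.FLOOR, Posture.LAYING, p["floor_lay"], _dur(rng, 15, 22)))
    segs.append(Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)))
    segs.append(Segment(Location.NONE, Posture.NONE, (0, 0), _dur(rng)))
    return ScenarioScript(tuple(segs))


def bed_visit_script(rng: np.random.Generator, lead_in: int = 12) -> ScenarioScript:
    """Enter the area, sit on the bedrail, lie in bed, leave without falling."""
    p = {k: _jitter_pos(rng, v) for k, v in POSITIONS.items()}
    segs = [
        Segment(Location.NONE, Posture.NONE, (0, 0), lead_in),
        Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)),
        Segment(Location.BEDRAIL, Posture.SITTING, p["bedrail"], _dur(rng)),
        Segment(Location.BED, Posture.LAYING, p["bed"], _dur(rng, 15, 22)),
        Segment(Location.FLOOR, Posture.STANDING, p["floor_stand"], _dur(rng)),
        Segment(Location.NONE, Posture.NONE, (0, 0), _dur(rng)),
    ]
    return ScenarioScript(tuple(segs))


def scenario_suite(n: int, seed: int) -> List[ScenarioScript]:
    """``n`` varied seeded scenarios cycling through the script templates."""
    rng = np.random.default_rng(seed)
    makers = [
        lambda r: fall_script(r, from_bed=True),
        bed_visit_script,
        lambda r: fall_script(r, from_bed=False),
        training_script,
    ]
    return [makers[i % len(makers)](rng) for i in range(n)]


# -- scenario JSON ------------------------------------------------------


def script_from_json(text: str) -> Tuple[ScenarioScript, SceneConfig]:
    """Parse a scenario document: {"scene": {...}, "segments": [...]}."""
    doc = json.loads(text)
    scene_doc = doc.get("scene", {})
    scene = replace(SceneConfig(), **{
        k: tuple(v) if isinstance(v, list) else v for k, v in scene_doc.items()
    })
    segments = []
    for s in doc["segments"]:
        segments.append(
            Segment(
                location=Location(s["location"]),
                posture=Posture(s["posture"]),
                position=tuple(s.get("position", (0, 0))),
                duration_s=int(s["duration_s"]),
            )
        )
    return ScenarioScript(tuple(segments)), scene


def script_to_json(script: ScenarioScript, scene: Optional[SceneConfig] = None) -> str:
    doc: Dict = {
        "segments": [
            {
                "location": s.location.value,
                "posture": s.posture.value,
                "position": list(s.position),
                "duration_s": s.duration_s,
            }
            for s in script.segments
        ]
    }
    if scene is not None:
        doc["scene"] = {
            "ambient": scene.ambient,
            "bed_rect": list(scene.bed_rect),
            "noise_sigma": scene.noise_sigma,
            "decay_tau": scene.decay_tau,
        }
    return json.dumps(doc, indent=1)
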