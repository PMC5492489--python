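"""Floating-window stable-state tracking and bedside event rules.

A (location, posture) pair becomes *stable* once it has been classified in
N consecutive accepted frames; erroneous frames are dismissed and neither
advance nor reset the run (up to a dismissal budget, after which the window
aborts).  Events are transitions between consecutive stable states:

* ``Fall`` — new stable (Floor, Laying|Sitting) from any prior state, N = 10;
* ``AreaEntry`` / ``AreaExit`` — (None, None) to a fully known state and
  back, N = 5;
* ``BedEntry`` — from Floor or None into (Bed, Laying|Sitting) or
  (Bedrail, Sitting), N = 10;
* ``BedExit`` — from Bed or Bedrail into (Floor, any posture) or
  (None, None), N = 10.

A single transition may satisfy several rules (leaving the bed onto the
floor in a lying posture is both a BedExit and a Fall); each matching event
is emitted once, at the frame where its own window length is reached.

Fall recognition can additionally be gated on physical evidence: a spike in
the changed-pixel count M during the transition, and — when coming from the
bed — an abrupt collapse of in-bed imprint pixels with a simultaneous rise
outside.  Both gates are configurable and can be disabled (e.g. when the
engine is fed ground-truth labels rather than sensor-derived features).

A confirmed (Bedrail, Laying) state is treated as a hazard: events that
confirm it carry ``hazard_flag=True`` and the engine records the frame in
``EngineState.hazard_frames``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Deque, Iterable, List, Optional, Sequence, Tuple

from collections import deque

from .classify import FrameClassification, Status
from .features import FrameFeatures
from .io import EventRecord, EventType, Location, Posture

Pair = Tuple[Location, Posture]

_NONE_PAIR: Pair = (Location.NONE, Posture.NONE)


@dataclass(frozen=True)
class WindowConfig:
    n_fall: int = 10
    n_bed: int = 10
    n_area: int = 5
    mf_spike_fraction: float = 0.2
    bed_drop_fraction: float = 0.5
    max_dismissals: Optional[int] = None  # default: the largest window length
    require_mf_spike: bool = True
    require_bed_drop: bool = True
    gate_lookback: int = 5  # frames before the run start inspected by gates

    def __post_init__(self) -> None:
        if min(self.n_fall, self.n_bed, self.n_area) < 1:
            raise ValueError("window lengths must be >= 1")

    @property
    def dismissal_budget(self) -> int:
        if self.max_dismissals is not None:
            return self.max_dismissals
        return max(self.n_fall, self.n_bed, self.n_area)


@dataclass(frozen=True)
class StableState:
    location: Location
    posture: Posture
    confirmed_at: int

    @property
    def pair(self) -> Pair:
        return (self.location, self.posture)


@dataclass
class EngineState:
    stable: StableState = field(
        default_factory=lambda: StableState(Location.NONE, Posture.NONE, 0)
    )
    run_pair: Optional[Pair] = None
    run_len: int = 0
    run_start_index: int = -1
    run_prev_stable: Pair = _NONE_PAIR
    dismissals: int = 0
    emitted: set = field(default_factory=set)  # event types emitted this run
    history: Deque[Tuple[int, int, int, int]] = field(
        default_factory=lambda: deque(maxlen=40)
    )  # (index, m, p_in, p_out)
    last_index: Optional[int] = None
    hazard_frames: List[int] = field(default_factory=list)


def transition_events(old: Pair, new: Pair, cfg: WindowConfig) -> List[Tuple[EventType, int]]:
    """Event types (with their window lengths) implied by a stable-state change."""
    if old == new:
        return []
    o_loc, o_pos = old
    n_loc, n_pos = new
    events: List[Tuple[EventType, int]] = []
    if old == _NONE_PAIR and n_loc is not Location.NONE and n_pos is not Posture.NONE:
        events.append((EventType.AREA_ENTRY, cfg.n_area))
    if new == _NONE_PAIR and o_loc is not Location.NONE and o_pos is not Posture.NONE:
        events.append((EventType.AREA_EXIT, cfg.n_area))
    if n_loc is Location.FLOOR and n_pos in (Posture.LAYING, Posture.SITTING):
        events.append((EventType.FALL, cfg.n_fall))
    if o_loc in (Location.FLOOR, Location.NONE) and (
        (n_loc is Location.BED and n_pos in (Posture.LAYING, Posture.SITTING))
        or (n_loc is Location.BEDRAIL and n_pos is Posture.SITTING)
    ):
        events.append((EventType.BED_ENTRY, cfg.n_bed))
    if o_loc in (Location.BED, Location.BEDRAIL) and (
        (
            n_loc is Location.FLOOR
            and n_pos in (Posture.LAYING, Posture.SITTING, Posture.STANDING)
        )
        or new == _NONE_PAIR
    ):
        events.append((EventType.BED_EXIT, cfg.n_bed))
    return events


def _fall_gates_pass(state: EngineState, cfg: WindowConfig) -> bool:
    window = [
        h for h in state.history if h[0] >= state.run_start_index - cfg.gate_lookback
    ]
    if not window:
        return not (cfg.require_mf_spike or cfg.require_bed_drop)
    ok = True
    if cfg.require_mf_spike:
        sizes = [p_in + p_out for _, _, p_in, p_out in window]
        mean_size = sum(sizes) / len(sizes)
        max_m = max(m for _, m, _, _ in window)
        if mean_size > 0 and max_m < cfg.mf_spike_fraction * mean_size:
            ok = False
    if ok and cfg.require_bed_drop and state.run_prev_stable[0] in (
        Location.BED,
        Location.BEDRAIL,
    ):
        # the bed must empty while the outside imprint grows, possibly with a
        # one-frame lag while lingering residual heat is still being flagged
        drop_seen = False
        for i in range(len(window)):
            _, _, a_in, a_out = window[i]
            if a_in <= 0:
                continue
            for j in range(i + 1, len(window)):
                _, _, b_in, b_out = window[j]
                if b_in <= (1.0 - cfg.bed_drop_fraction) * a_in and b_out > a_out:
                    drop_seen = True
                    break
            if drop_seen:
                break
        if not drop_seen:
            ok = False
    return ok


def step(
    state: EngineState,
    c: FrameClassification,
    f: FrameFeatures,
    cfg: Optional[WindowConfig] = None,
) -> Tuple[EngineState, List[EventRecord]]:
    """Advance the tracker by one frame; return emitted events (if any)."""
    cfg = cfg or WindowConfig()
    if state.last_index is not None and c.index <= state.last_index:
        raise ValueError(
            f"out-of-order frame index {c.index} (last was {state.last_index})"
        )
    state.last_index = c.index
    state.history.append((c.index, f.m, f.p_in, f.p_out))

    if c.status is Status.ERRONEOUS:
        if state.run_pair is not None:
            state.dismissals += 1
            if state.dismissals > cfg.dismissal_budget:
                state.run_pair = None
                state.run_len = 0
                state.emitted = set()
        return state, []

    pair = (c.location, c.posture)
    if state.run_pair == pair:
        state.run_len += 1
    else:
        state.run_pair = pair
        state.run_len = 1
        state.run_start_index = c.index
        state.run_prev_stable = state.stable.pair
        state.dismissals = 0
        state.emitted = set()

    prev = state.run_prev_stable
    events: List[EventRecord] = []
    if pair != prev:
        matched = transition_events(prev, pair, cfg)
        hazard = pair == (Location.BEDRAIL, Posture.LAYING)
        for ev_type, n_req in matched:
            if state.run_len == n_req and ev_type not in state.emitted:
                if ev_type is EventType.FALL and not _fall_gates_pass(state, cfg):
                    state.emitted.add(ev_type)  # suppressed for this run
                    continue
                events.append(EventRecord(ev_type, c.index, hazard_flag=hazard))
                state.emitted.add(ev_type)
        confirm_n = min((n for _, n in matched), default=cfg.n_bed)
        if state.run_len >= confirm_n and state.stable.pair != pair:
            state.stable = StableState(pair[0], pair[1], confirmed_at=c.index)
            if hazard:
                state.hazard_frames.append(c.index)
    return state, events


def detect_events(
    classifications: Sequence[FrameClassification],
    features: Sequence[FrameFeatures],
    cfg: Optional[WindowConfig] = None,
    initial: Optional[Pair] = None,
) -> List[EventRecord]:
    """Run the engine over an aligned stream of classifications and features.

    ``initial`` overrides the starting stable state; by default a recording
    is assumed to begin with an empty room, i.e. (None, None).
    """
    if len(classifications) != len(features):
        raise ValueError("classification/feature length mismatch")
    state = EngineState()
    if initial is not None:
        state.stable = StableState(initial[0], initial[1], 0)
    out: List[EventRecord] = []
    for c, f in zip(classifications, features):
        state, events = step(state, c, f, cfg)
        out.extend(events)
    return out
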