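"""Background estimation, heat-imprint binarization and residual-heat disposal.

The background model is a per-pixel arithmetic mean B(x, y) over N frames of
an empty room.  The heat impression of a frame is the per-pixel absolute
deviation H(x, y) = |V(x, y) - B(x, y)|; pixels strictly above a threshold
(default 20 counts = 1.00 degC) form the imprint mask.

Residual heat is warmth left in bedding or on the floor after the body has
moved away.  It decays monotonically towards ambient, while the body itself
keeps the hottest pixel of the frame (the uncovered head).  The disposal
step therefore labels the imprint into 8-connected components, protects the
component carrying the global maximum deviation, and removes any other
component whose peak deviation has been non-increasing (within a small
tolerance) over a confirmation window of consecutive frames.  Components are
tracked across frames by pixel overlap; a component whose tracked peak
abruptly collapses (the body just vacated the spot, leaving only contact
warmth) is flagged at once, so a vacated bed patch is removed from its first
decay frame even while it is the hottest thing left in view.  A tracked
region is released once its pixels drop below the imprint threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io import GRID_COLS, GRID_ROWS, FrameSequence, ThermalFrame

#: Imprint threshold in sensor counts; 20 counts = 1.00 degC at 0.05 degC/count.
DEFAULT_THRESHOLD = 20.0

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel mean temperature of the empty scene, in sensor counts."""

    mean_grid: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.mean_grid, dtype=float)
        if grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"mean_grid must be {GRID_ROWS}x{GRID_COLS}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "mean_grid", grid)


@dataclass(frozen=True)
class ImprintMask:
    """Binary heat impression plus its magnitude grid (absolute deviation)."""

    mask: np.ndarray
    magnitude: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        mag = np.asarray(self.magnitude, dtype=float)
        if mask.shape != (GRID_ROWS, GRID_COLS) or mag.shape != mask.shape:
            raise ValueError("mask and magnitude must be 60x80 and share shape")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "magnitude", mag)


@dataclass(frozen=True)
class _TrackedRegion:
    pixels: np.ndarray          # boolean footprint at last sighting
    peaks: Tuple[float, ...]    # recent peak magnitudes, oldest first
    residual: bool              # already confirmed as residual heat
    missed: int = 0             # consecutive frames without a matching component


@dataclass(frozen=True)
class ResidualHeatState:
    """Cross-frame tracking state for the disposal algorithm.

    ``drop_fraction`` triggers the immediate residual flag: a component
    whose peak falls to at most this fraction of its matched track's last
    peak has just lost the body (skin contact warmth is far cooler than the
    body itself) and is disposed without waiting for the confirmation
    window.
    """

    regions: Tuple[_TrackedRegion, ...] = ()
    tolerance: float = 1.0
    confirm_frames: int = 3
    connectivity: int = 8
    drop_fraction: float = 0.6
    #: frames a flagged region is remembered after its pixels leave the mask;
    #: a patch hovering at the threshold flickers in and out with noise and
    #: must keep matching its (flagged) track while it does.
    linger_frames: int = 15


def estimate_background(frames: FrameSequence) -> BackgroundModel:
    """Average N person-free frames into a per-pixel background model."""
    if len(frames) == 0:
        raise ValueError("cannot estimate background from an empty sequence")
    acc = np.zeros((GRID_ROWS, GRID_COLS), dtype=float)
    for f in frames:
        acc += f.grid
    return BackgroundModel(mean_grid=acc / len(frames), n_frames=len(frames))


def imprint_mask(
    frame: ThermalFrame,
    bg: BackgroundModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> ImprintMask:
    """Binarize the absolute deviation from background at ``threshold``.

    The comparison is strict: a pixel exactly at the threshold is not part
    of the imprint.  Both warm and cold deviations count (absolute value).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    magnitude = np.abs(frame.grid.astype(float) - bg.mean_grid)
    return ImprintMask(mask=magnitude > threshold, magnitude=magnitude, threshold=threshold)


def _non_increasing(peaks: Tuple[float, ...], tolerance: float) -> bool:
    return all(b <= a + tolerance for a, b in zip(peaks, peaks[1:]))


def dispose_residual_heat(
    state: ResidualHeatState,
    imprint: ImprintMask,
    prev: Optional[ImprintMask] = None,
) -> Tuple[ResidualHeatState, ImprintMask]:
    """Remove residual-heat components from an imprint mask.

    Returns the updated tracking state and a filtered mask.  The filtered
    mask is always a subset of the input mask.  ``prev`` (the previous
    frame's unfiltered imprint) is accepted for callers that stream frames
    but is not needed by the overlap-based tracker.
    """
    del prev  # tracking is carried in ``state``
    mask = imprint.mask
    structure = _STRUCT_8 if state.connectivity == 8 else _STRUCT_4
    labels, n_comp = ndimage.label(mask, structure=structure)

    if n_comp == 0:
        return replace(state, regions=()), imprint

    masked_mag = np.where(mask, imprint.magnitude, -np.inf)
    body_label = labels[np.unravel_index(np.argmax(masked_mag), mask.shape)]

    remove = np.zeros_like(mask)
    new_regions: List[_TrackedRegion] = []
    matched_tracks: set = set()
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        peak = float(imprint.magnitude[comp_mask].max())

        matched: Optional[_TrackedRegion] = None
        matched_idx = -1
        best_overlap = 0
        for idx, region in enumerate(state.regions):
            overlap = int(np.count_nonzero(region.pixels & comp_mask))
            if overlap > best_overlap:
                best_overlap = overlap
                matched = region
                matched_idx = idx
        if matched is not None:
            matched_tracks.add(matched_idx)

        history = (matched.peaks if matched else ()) + (peak,)
        history = history[-state.confirm_frames:]
        was_residual = matched.residual if matched else False
        # a collapse of the tracked peak means the body just vacated the spot
        abrupt_drop = (
            matched is not None and peak <= state.drop_fraction * matched.peaks[-1]
        )

        if comp == body_label and not abrupt_drop:
            # The body carries the frame's hottest deviation.  A component
            # that merely inherits a residual flag (the body stepping onto a
            # still-warm patch) is reclaimed when its peak jumps back up;
            # a flagged patch that is merely the hottest thing left after
            # the body leaves keeps decaying and stays flagged.
            reclaimed = (
                matched is None
                or not was_residual
                or peak > matched.peaks[-1] + state.tolerance
            )
            if reclaimed:
                new_regions.append(_TrackedRegion(comp_mask, history, residual=False))
                continue

        residual = was_residual or abrupt_drop or (
            len(history) >= state.confirm_frames
            and _non_increasing(history, state.tolerance)
        )
        if residual:
            remove |= comp_mask
        # a flagged region keeps its full historical extent: the patch
        # shrinks as it decays, but late noise flickers can pop up anywhere
        # under the original footprint and must still match the track
        footprint = (
            comp_mask | matched.pixels if residual and matched is not None else comp_mask
        )
        new_regions.append(_TrackedRegion(footprint, history, residual=residual))

    # flagged regions that vanished this frame linger for a while: a patch
    # hovering at the imprint threshold resurfaces under noise and must keep
    # matching its track so its pixels stay disposed
    for idx, region in enumerate(state.regions):
        if idx in matched_tracks or not region.residual:
            continue
        if region.missed < state.linger_frames:
            new_regions.append(replace(region, missed=region.missed + 1))

    filtered = ImprintMask(
        mask=mask & ~remove, magnitude=imprint.magnitude, threshold=imprint.threshold
    )
    return replace(state, regions=tuple(new_regions)), filtered
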