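"""End-to-end wiring: background -> imprint -> disposal -> features ->
classification -> sanity rules -> event engine.

The first ``background_frames`` frames of a recording are assumed empty and
are averaged into the background model; every later frame is processed in
stream order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .classify import (
    ClassifierModel,
    ClassifierSpec,
    CompatibilityRules,
    FrameClassification,
    Status,
    classify_location,
    classify_posture,
    fit,
    location_vector,
    posture_vector,
    sanitize,
)
from .events import EngineState, WindowConfig, step
from .features import FrameFeatures, extract_features
from .io import BedMask, EventRecord, FrameLabel, FrameSequence, Location
from .thermal import (
    DEFAULT_THRESHOLD,
    BackgroundModel,
    ImprintMask,
    ResidualHeatState,
    dispose_residual_heat,
    estimate_background,
    imprint_mask,
)


@dataclass
class PipelineConfig:
    background_frames: int = 10
    threshold: float = DEFAULT_THRESHOLD
    residual_tolerance: float = 1.0
    residual_confirm_frames: int = 3
    connectivity: int = 8
    window: WindowConfig = field(default_factory=WindowConfig)
    rules: CompatibilityRules = field(default_factory=CompatibilityRules)


@dataclass
class DetectionResult:
    features: List[FrameFeatures]
    classifications: List[FrameClassification]
    events: List[EventRecord]
    background: BackgroundModel


def extract_feature_stream(
    frames: FrameSequence,
    bed: BedMask,
    config: Optional[PipelineConfig] = None,
    background: Optional[BackgroundModel] = None,
) -> Tuple[List[FrameFeatures], BackgroundModel]:
    """Run the thermal chain over a recording and return per-frame features.

    When no background model is supplied, the first ``background_frames``
    frames are averaged into one and skipped from the feature stream.
    """
    config = config or PipelineConfig()
    start = 0
    if background is None:
        if len(frames) <= config.background_frames:
            raise ValueError(
                f"need more than {config.background_frames} frames to both "
                "estimate a background and extract features"
            )
        background = estimate_background(
            FrameSequence(list(frames)[: config.background_frames])
        )
        start = config.background_frames

    state = ResidualHeatState(
        tolerance=config.residual_tolerance,
        confirm_frames=config.residual_confirm_frames,
        connectivity=config.connectivity,
    )
    features: List[FrameFeatures] = []
    prev_filtered: Optional[ImprintMask] = None
    for frame in list(frames)[start:]:
        raw = imprint_mask(frame, background, config.threshold)
        state, filtered = dispose_residual_heat(state, raw)
        features.append(
            extract_features(frame, filtered, bed, prev_filtered, background)
        )
        prev_filtered = filtered
    return features, background


def train_models(
    features: Sequence[FrameFeatures],
    labels: Sequence[FrameLabel],
    location_spec: Optional[ClassifierSpec] = None,
    posture_spec: Optional[ClassifierSpec] = None,
) -> Tuple[ClassifierModel, ClassifierModel]:
    """Train the location and posture models on aligned features/labels.

    Defaults mirror the preferred configuration: an MLP for location and
    k-NN with k = 3 for posture.  The posture model is conditioned on the
    ground-truth location during training.
    """
    by_index = {l.index: l for l in labels}
    paired = [(f, by_index[f.index]) for f in features if f.index in by_index]
    if not paired:
        raise ValueError("no features align with the provided labels")
    location_spec = location_spec or ClassifierSpec("mlp", "location")
    posture_spec = posture_spec or ClassifierSpec("knn", "posture", k=3)
    loc_model = fit(
        location_spec,
        [location_vector(f) for f, _ in paired],
        [l.location for _, l in paired],
    )
    pos_model = fit(
        posture_spec,
        [posture_vector(f, l.location) for f, l in paired],
        [l.posture for _, l in paired],
    )
    return loc_model, pos_model


def run_detection(
    frames: FrameSequence,
    bed: BedMask,
    location_model: ClassifierModel,
    posture_model: ClassifierModel,
    config: Optional[PipelineConfig] = None,
    background: Optional[BackgroundModel] = None,
) -> DetectionResult:
    """Full detection pass over a recording."""
    config = config or PipelineConfig()
    features, background = extract_feature_stream(frames, bed, config, background)

    classifications: List[FrameClassification] = []
    for f in features:
        loc = classify_location(location_model, f)
        pos = classify_posture(posture_model, f, loc)
        c = sanitize(
            FrameClassification(f.index, loc, pos, Status.ACCEPTED), f.d, config.rules
        )
        classifications.append(c)

    state = EngineState()
    events: List[EventRecord] = []
    for c, f in zip(classifications, features):
        state, emitted = step(state, c, f, config.window)
        events.extend(emitted)
    return DetectionResult(features, classifications, events, background)
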