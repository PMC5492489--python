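"""Published evaluation tallies from the original ceiling-sensor deployment.

The original study recorded 8032 frames over 28 bedroom sessions, split
20/80 into learning and test sets, and reported per-class recognition
counts for three classifier families plus event-level confusion counts for
the five bedside event types.  Those printed tallies are kept here as plain
data: they are the inputs for validating this package's metric arithmetic
(the raw recordings themselves were never deposited).

All counts refer to the 6426-frame test set unless noted otherwise.
"""

from __future__ import annotations

from .io import EventType
from .metrics import ConfusionCounts

TOTAL_FRAMES = 8032
LEARNING_FRAMES = 1606
TEST_FRAMES = 6426
TOTAL_EVENTS = 145
N_RECORDINGS = 28

#: Event-level confusion counts (TN = per-recording non-event opportunities).
EVENT_COUNTS = {
    EventType.FALL: ConfusionCounts(tp=26, fp=2, tn=117, fn=0),
    EventType.BED_ENTRY: ConfusionCounts(tp=24, fp=0, tn=123, fn=2),
    EventType.BED_EXIT: ConfusionCounts(tp=22, fp=1, tn=126, fn=4),
    EventType.AREA_ENTRY: ConfusionCounts(tp=41, fp=1, tn=108, fn=5),
    EventType.AREA_EXIT: ConfusionCounts(tp=15, fp=1, tn=135, fn=6),
}

#: Actual event counts per type across the 28 recordings.
ACTUAL_EVENTS = {
    EventType.FALL: 26,
    EventType.BED_ENTRY: 26,
    EventType.BED_EXIT: 26,
    EventType.AREA_ENTRY: 46,
    EventType.AREA_EXIT: 21,
}

#: Correctly recognized locations per class and algorithm (test set).
LOCATION_CORRECT = {
    "mlp": {"None": 176, "Bed": 1699, "Floor": 2395, "Bedrail": 1633},
    "knn": {"None": 151, "Bed": 1697, "Floor": 2417, "Bedrail": 1641},
    "tree": {"None": 137, "Bed": 1702, "Floor": 2458, "Bedrail": 1575},
}

#: Correctly recognized postures per class and algorithm (test set).
POSTURE_CORRECT = {
    "mlp": {"None": 188, "Sitting": 1731, "Standing": 297, "Laying": 2950},
    "knn": {"None": 192, "Sitting": 2013, "Standing": 251, "Laying": 2950},
    "tree": {"None": 190, "Sitting": 1935, "Standing": 298, "Laying": 2963},
}

#: 8x8 confusion matrix of a single joint location/posture tree run on the
#: test set.  Rows are truth, columns predictions, in JOINT_CLASSES order.
JOINT_CLASSES = (
    "None/None",
    "Floor/Sitting",
    "Floor/Standing",
    "Floor/Laying",
    "Bedrail/Sitting",
    "Bedrail/Laying",
    "Bed/Sitting",
    "Bed/Laying",
)
JOINT_TREE_MATRIX = (
    (183, 5, 3, 0, 3, 4, 1, 5),
    (5, 400, 48, 216, 8, 56, 0, 0),
    (32, 73, 167, 63, 47, 32, 0, 10),
    (6, 175, 42, 1183, 6, 22, 0, 1),
    (4, 28, 30, 9, 1158, 52, 15, 52),
    (1, 56, 16, 13, 69, 277, 0, 22),
    (0, 0, 2, 0, 15, 7, 298, 74),
    (2, 2, 14, 1, 56, 8, 87, 1262),
)

#: Frames with both location and posture correct, per (location algorithm,
#: posture algorithm) pairing, over all 8032 frames.
JOINT_CROSS_CORRECT = {
    ("mlp", "mlp"): 6060,
    ("mlp", "tree"): 6380,
    ("mlp", "knn"): 6405,
    ("tree", "mlp"): 6000,
    ("tree", "tree"): 6336,
    ("tree", "knn"): 6361,
    ("knn", "mlp"): 6057,
    ("knn", "tree"): 6368,
    ("knn", "knn"): 6394,
}

#: Total correctly recognized location/posture per algorithm, all frames.
LOCATION_TOTAL_CORRECT = {"mlp": 7381, "knn": 7380, "tree": 7327}
POSTURE_TOTAL_CORRECT = {"mlp": 6477, "knn": 6757, "tree": 6707}
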