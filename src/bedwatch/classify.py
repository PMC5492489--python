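"""Per-frame location and posture classification.

Location Lf is classified from (p_in, p_out, t_in, t_out); posture POf is
classified from the same four values plus the distance reading d and the
location (one-hot encoded).  Three classifier families are provided:

* ``mlp`` — a small multilayer perceptron with two hidden layers (6 and 4
  units, logistic activations), trained by stochastic gradient descent with
  learning rate 0.2 and momentum 0.1;
* ``knn`` — k-nearest neighbours with Euclidean distance (k = 7 for
  location, k = 3 for posture by convention here);
* ``tree`` — an entropy-split decision tree with optional cost-complexity
  pruning, standing in for classic C4.5-style trees.

Inputs to the mlp and knn families are min-max scaled with ranges fitted on
the learning set.  Classes are encoded in a fixed order (None first), which
also resolves voting ties deterministically in favour of the lowest class
index.  Trained models serialize to self-describing JSON (no pickles).

After classification, :func:`sanitize` applies per-frame plausibility rules:
an impossible (Bed|Bedrail, Standing) pair marks the frame erroneous, a
one-sided None is widened to (None, None), and a distance reading outside
the compatibility interval configured for the (location, posture) pair also
marks the frame erroneous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FrameFeatures
from .io import (
    DISTANCE_BEYOND,
    LOCATION_ORDER,
    POSTURE_ORDER,
    FrameLabel,
    Location,
    Posture,
)


class Status(str, Enum):
    ACCEPTED = "accepted"
    ERRONEOUS = "erroneous"


@dataclass(frozen=True)
class FrameClassification:
    index: int
    location: Location
    posture: Posture
    status: Status = Status.ACCEPTED


@dataclass(frozen=True)
class ClassifierSpec:
    """Family, target and hyperparameters of one classifier."""

    family: str  # mlp | knn | tree
    target: str  # location | posture
    k: int = 7
    hidden: Tuple[int, ...] = (6, 4)
    learning_rate: float = 0.2
    momentum: float = 0.1
    seed: int = 42
    max_iter: int = 800
    ccp_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("mlp", "knn", "tree"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.target not in ("location", "posture"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be an odd integer >= 1")
        if not self.hidden:
            raise ValueError("hidden layout must be non-empty")


def split_dataset(
    labels: Sequence[FrameLabel], learn_fraction: float, seed: int
) -> Tuple[List[FrameLabel], List[FrameLabel]]:
    """Seeded random split into (learning, test) sets.

    The learning set holds ``round(fraction * n)`` items; the two sets are
    disjoint, exhaustive, and identical for identical seeds.
    """
    if not labels:
        raise ValueError("cannot split an empty label list")
    if not 0.0 < learn_fraction < 1.0:
        raise ValueError("learn_fraction must be in (0, 1)")
    n = len(labels)
    n_learn = int(np.floor(learn_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    learn_idx = set(perm[:n_learn].tolist())
    learning = [labels[i] for i in range(n) if i in learn_idx]
    test = [labels[i] for i in range(n) if i not in learn_idx]
    return learning, test


def _classes_for(target: str):
    return LOCATION_ORDER if target == "location" else POSTURE_ORDER


def location_vector(f: FrameFeatures) -> List[float]:
    return [f.p_in, f.p_out, f.t_in, f.t_out]


def posture_vector(f: FrameFeatures, location: Location) -> List[float]:
    onehot = [1.0 if location is loc else 0.0 for loc in LOCATION_ORDER]
    return [f.p_in, f.p_out, f.t_in, f.t_out, float(f.d)] + onehot


@dataclass
class ClassifierModel:
    """A trained model with its scaler and JSON (de)serialization."""

    spec: ClassifierSpec
    classes: List[str]
    scaler_min: Optional[List[float]]
    scaler_range: Optional[List[float]]
    payload: Dict

    # -- prediction -----------------------------------------------------
    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_min is None:
            return X
        lo = np.asarray(self.scaler_min)
        rng = np.asarray(self.scaler_range)
        return (X - lo) / rng

    def predict(self, X: np.ndarray) -> List[str]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self._scale(X)
        if self.spec.family == "knn":
            idx = self._knn().predict(Xs)
        elif self.spec.family == "mlp":
            idx = self._mlp_forward(Xs)
        else:
            idx = self._tree_traverse(X)  # trees are scale-invariant; raw inputs
        return [self.classes[int(i)] for i in idx]

    def _knn(self) -> KNeighborsClassifier:
        if "_knn_cache" not in self.payload:
            knn = KNeighborsClassifier(
                n_neighbors=self.spec.k, metric="euclidean", algorithm="brute"
            )
            knn.fit(
                np.asarray(self.payload["table"], dtype=float),
                np.asarray(self.payload["labels"], dtype=int),
            )
            self.payload["_knn_cache"] = knn
        return self.payload["_knn_cache"]

    def _mlp_forward(self, Xs: np.ndarray) -> np.ndarray:
        a = Xs
        coefs = [np.asarray(c) for c in self.payload["coefs"]]
        intercepts = [np.asarray(b) for b in self.payload["intercepts"]]
        for W, b in zip(coefs[:-1], intercepts[:-1]):
            a = 1.0 / (1.0 + np.exp(-(a @ W + b)))
        z = a @ coefs[-1] + intercepts[-1]
        out_classes = np.asarray(self.payload["out_classes"], dtype=int)
        if z.shape[1] == 1:  # binary problems use a single logistic output
            return out_classes[(z.ravel() > 0).astype(int)]
        return out_classes[np.argmax(z, axis=1)]

    def _tree_traverse(self, X: np.ndarray) -> np.ndarray:
        left = self.payload["children_left"]
        right = self.payload["children_right"]
        feat = self.payload["feature"]
        thresh = self.payload["threshold"]
        leaf_class = self.payload["leaf_class"]
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            node = 0
            while left[node] != -1:
                node = left[node] if x[feat[node]] <= thresh[node] else right[node]
            out[i] = leaf_class[node]
        return out

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        payload = {k: v for k, v in self.payload.items() if not k.startswith("_")}
        doc = {
            "format": "bedwatch-classifier/1",
            "spec": {
                "family": self.spec.family,
                "target": self.spec.target,
                "k": self.spec.k,
                "hidden": list(self.spec.hidden),
                "learning_rate": self.spec.learning_rate,
                "momentum": self.spec.momentum,
                "seed": self.spec.seed,
                "max_iter": self.spec.max_iter,
                "ccp_alpha": self.spec.ccp_alpha,
            },
            "classes": self.classes,
            "scaler_min": self.scaler_min,
            "scaler_range": self.scaler_range,
            "payload": payload,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        doc = json.loads(text)
        spec_doc = dict(doc["spec"])
        spec_doc["hidden"] = tuple(spec_doc["hidden"])
        return cls(
            spec=ClassifierSpec(**spec_doc),
            classes=doc["classes"],
            scaler_min=doc["scaler_min"],
            scaler_range=doc["scaler_range"],
            payload=doc["payload"],
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ClassifierModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def fit(
    spec: ClassifierSpec,
    X: Sequence[Sequence[float]],
    labels: Sequence[Union[str, Location, Posture]],
) -> ClassifierModel:
    """Train a classifier on a feature matrix and class labels."""
    X = np.asarray(X, dtype=float)
    if len(X) != len(labels):
        raise ValueError("feature/label length mismatch")
    if len(X) == 0:
        raise ValueError("cannot fit on an empty training set")

    classes = [c.value for c in _classes_for(spec.target)]
    try:
        y = np.array([classes.index(getattr(l, "value", l)) for l in labels])
    except ValueError:
        bad = sorted({getattr(l, "value", l) for l in labels} - set(classes))
        raise ValueError(
            f"labels {bad} are not valid {spec.target} classes {classes}"
        ) from None

    scaler_min = scaler_range = None
    Xs = X
    if spec.family in ("mlp", "knn"):
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0] = 1.0
        scaler_min, scaler_range = lo.tolist(), rng.tolist()
        Xs = (X - lo) / rng

    if spec.family == "knn":
        payload = {"table": Xs.tolist(), "labels": y.tolist()}
    elif spec.family == "mlp":
        mlp = MLPClassifier(
            hidden_layer_sizes=spec.hidden,
            activation="logistic",
            solver="sgd",
            learning_rate_init=spec.learning_rate,
            momentum=spec.momentum,
            max_iter=spec.max_iter,
            random_state=spec.seed,
            tol=1e-5,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlp.fit(Xs, y)
        payload = {
            "coefs": [c.tolist() for c in mlp.coefs_],
            "intercepts": [b.tolist() for b in mlp.intercepts_],
            "out_classes": mlp.classes_.tolist(),
        }
    else:
        tree = DecisionTreeClassifier(
            criterion="entropy", random_state=spec.seed, ccp_alpha=spec.ccp_alpha
        )
        tree.fit(X, y)
        t = tree.tree_
        leaf_class = tree.classes_[np.argmax(t.value[:, 0, :], axis=1)]
        payload = {
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "leaf_class": leaf_class.tolist(),
        }

    return ClassifierModel(
        spec=spec,
        classes=classes,
        scaler_min=scaler_min,
        scaler_range=scaler_range,
        payload=payload,
    )


def classify_location(model: ClassifierModel, f: FrameFeatures) -> Location:
    if model.spec.target != "location":
        raise ValueError("model does not target location")
    return Location(model.predict([location_vector(f)])[0])


def classify_posture(
    model: ClassifierModel, f: FrameFeatures, location: Location
) -> Posture:
    if model.spec.target != "posture":
        raise ValueError("model does not target posture")
    return Posture(model.predict([posture_vector(f, location)])[0])


# -- plausibility rules -------------------------------------------------


def default_df_intervals() -> Dict[Tuple[Location, Posture], Tuple[int, int]]:
    """Distance compatibility intervals (cm from a ~220 cm ceiling)."""
    intervals: Dict[Tuple[Location, Posture], Tuple[int, int]] = {}
    for loc in (Location.FLOOR,):
        intervals[(loc, Posture.STANDING)] = (40, 110)
    for loc in (Location.BED, Location.BEDRAIL, Location.FLOOR):
        intervals[(loc, Posture.SITTING)] = (90, 170)
    for loc in (Location.BED, Location.BEDRAIL):
        intervals[(loc, Posture.LAYING)] = (130, 190)
    intervals[(Location.FLOOR, Posture.LAYING)] = (170, DISTANCE_BEYOND)
    return intervals


@dataclass(frozen=True)
class CompatibilityRules:
    df_intervals: Dict[Tuple[Location, Posture], Tuple[int, int]] = field(
        default_factory=default_df_intervals
    )
    check_distance: bool = True


def sanitize(
    c: FrameClassification,
    d: int,
    rules: Optional[CompatibilityRules] = None,
) -> FrameClassification:
    """Apply the per-frame plausibility rules to a classified frame.

    Order of checks: the impossible (Bed|Bedrail, Standing) pair first, then
    widening of one-sided None, then the distance-compatibility interval.
    """
    rules = rules or CompatibilityRules()
    if (
        c.location in (Location.BED, Location.BEDRAIL)
        and c.posture is Posture.STANDING
    ):
        return replace(c, status=Status.ERRONEOUS)
    if c.location is Location.NONE or c.posture is Posture.NONE:
        return replace(
            c, location=Location.NONE, posture=Posture.NONE, status=Status.ACCEPTED
        )
    if rules.check_distance:
        interval = rules.df_intervals.get((c.location, c.posture))
        if interval is not None and not interval[0] <= d <= interval[1]:
            return replace(c, status=Status.ERRONEOUS)
    return replace(c, status=Status.ACCEPTED)
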