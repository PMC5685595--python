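"""Removal of specious skeleton segments with a soft-margin linear SVM.

Even a noise-robust skeleton retains segments that are not vessel: short
stubs from residual boundary noise and thin protrusions that are really
filopodia of the tip cell.  Each segment is summarized by the feature
vector [l, r_max, r_min, J] — arc length, extreme radii, and a connection
type encoding which node roles the segment joins — and classified
vessel (+1) / specious (-1) by a linear soft-margin SVM trained on labeled
templates.  Features are standardized before fitting because their scales
differ by orders of magnitude.  After pruning, node degrees are recounted
and roles relabeled: a false branch node that loses its filopodial stub
becomes an ordinary junction node.

The labeled experimental templates behind the original classifier are not
distributed; the package ships a synthetic, linearly separable template
set (thick/long vessel trunks vs short/thin spurs) plus a loader for
user-supplied labeled CSVs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graph import (
    LABEL_SPECIOUS,
    LABEL_VESSEL,
    ROLE_BASE,
    ROLE_BRANCH,
    ROLE_END,
    ROLE_JUNCTION,
    SkeletonGraph,
)

# connection type J: scalar code from the endpoint roles.  Junction/base
# endpoints count as continuation of the vessel body, i.e. like a branch
# endpoint (junctions only exist after pruning; templates are pre-pruning).
J_BRANCH_BRANCH = 0
J_BRANCH_END = 1
J_END_END = 2

FEATURE_NAMES = ("l", "r_max", "r_min", "J")


@dataclass
class SegmentFeatures:
    segment_id: int
    l: float
    r_max: float
    r_min: float
    J: int
    y: int | None = None      # +1 vessel, -1 specious, None unknown

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.l, self.r_max, self.r_min, self.J], dtype=float)


def connection_type(role_a: str, role_b: str) -> int:
    def is_endlike(r):
        return r == ROLE_END
    a_end, b_end = is_endlike(role_a), is_endlike(role_b)
    if a_end and b_end:
        return J_END_END
    if a_end or b_end:
        return J_BRANCH_END
    return J_BRANCH_BRANCH


def extract_segment_features(graph: SkeletonGraph, segment_id: int) -> SegmentFeatures:
    """Features of one segment; requires sampled radii."""
    seg = graph.segments[segment_id]
    if seg.radii is None or len(seg.radii) == 0:
        raise ValueError(f"segment {segment_id} has no sampled radii")
    return SegmentFeatures(
        segment_id=segment_id,
        l=seg.length,
        r_max=float(np.max(seg.radii)),
        r_min=float(np.min(seg.radii)),
        J=connection_type(graph.nodes[seg.node_a].role, graph.nodes[seg.node_b].role),
    )


def extract_all_features(graph: SkeletonGraph) -> list[SegmentFeatures]:
    return [extract_segment_features(graph, sid) for sid in sorted(graph.segments)]


@dataclass
class LinearSVMModel:
    """Hyperplane (w, b) in standardized feature space: the decision value
    for a template x is w . (x - mean)/scale + b; its sign is the label."""

    w: np.ndarray
    b: float
    mean: np.ndarray
    scale: np.ndarray
    C: float = 1.0

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.mean) / self.scale) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "w": self.w.tolist(),
                    "b": self.b,
                    "mean": self.mean.tolist(),
                    "scale": self.scale.tolist(),
                    "C": self.C,
                    "features": list(FEATURE_NAMES),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "LinearSVMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            C=float(d.get("C", 1.0)),
        )


def _design(features: list[SegmentFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([f.vector for f in features])
    y = np.array([f.y for f in features], dtype=float)
    return X, y


def train_segment_classifier(training: list[SegmentFeatures], C: float = 1.0) -> LinearSVMModel:
    """Fit the soft-margin linear SVM on standardized features."""
    X, y = _design(training)
    if np.any(np.isnan(y)):
        raise ValueError("all training templates need labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    svc = SVC(kernel="linear", C=C)
    svc.fit((X - scaler.mean_) / scale, y)
    return LinearSVMModel(
        w=svc.coef_.ravel().copy(),
        b=float(svc.intercept_[0]),
        mean=scaler.mean_.copy(),
        scale=scale,
        C=C,
    )


def cross_validate_classifier(
    training: list[SegmentFeatures], k: int = 5, seed: int = 0, C: float = 1.0
) -> float:
    """Stratified k-fold cross-validation accuracy."""
    X, y = _design(training)
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(classes) < 2 or counts.min() < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold CV")
    pipe = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=C))])
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(cross_val_score(pipe, X, y, cv=cv).mean())


def prune_graph(graph: SkeletonGraph, model: LinearSVMModel) -> SkeletonGraph:
    """Delete segments classified specious; rederive node roles.

    Works on a copy.  Segment labels are recorded on the surviving graph;
    orphaned nodes are dropped, degrees recounted, roles relabeled
    (>=3 branch, 2 junction, 1 end).
    """
    out = graph.copy()
    feats = extract_all_features(out)
    X = np.array([f.vector for f in feats])
    labels = model.predict(X) if len(feats) else np.empty(0)
    for f, lab in zip(feats, labels):
        if lab < 0:
            out.remove_segment(f.segment_id)
        else:
            out.segments[f.segment_id].label = LABEL_VESSEL
    out.drop_orphans()
    out.relabel_roles(preserve_base=True)
    if out.n_segments == 0 and graph.n_segments > 0:
        warnings.warn("pruning removed every segment", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# synthetic training templates

def synthetic_training_set(
    n_pos: int = 214,
    n_neg: int = 102,
    seed: int = 0,
    label_noise: float = 0.0,
) -> list[SegmentFeatures]:
    """Linearly separable synthetic templates: vessel trunks vs spurs.

    Positive templates emulate vessel segments (radii >= 3 px, lengths up
    to a few hundred px); negatives emulate filopodial/noise spurs (thin,
    r_max <= 2.5 px, short).  The classes are separable in the radius
    coordinates by construction.  ``label_noise`` flips that fraction of
    labels (seeded), for robustness checks.
    """
    rng = np.random.default_rng(seed)
    feats: list[SegmentFeatures] = []
    for i in range(n_pos):
        r_max = rng.uniform(3.5, 9.0)
        r_min = r_max - rng.uniform(0.0, 2.0)
        feats.append(
            SegmentFeatures(
                segment_id=i + 1,
                l=float(rng.uniform(15.0, 250.0)),
                r_max=float(r_max),
                r_min=float(max(r_min, 3.0)),
                # unbranched sprouts are end-end segments, so every
                # connection type occurs among genuine vessel segments
                J=int(rng.choice([J_BRANCH_BRANCH, J_BRANCH_END, J_END_END], p=[0.35, 0.40, 0.25])),
                y=1,
            )
        )
    for i in range(n_neg):
        r_max = rng.uniform(0.8, 2.5)
        r_min = r_max - rng.uniform(0.0, 0.7)
        feats.append(
            SegmentFeatures(
                segment_id=n_pos + i + 1,
                l=float(rng.uniform(3.0, 30.0)),
                r_max=float(r_max),
                r_min=float(max(r_min, 0.5)),
                J=int(rng.choice([J_BRANCH_END, J_END_END], p=[0.8, 0.2])),
                y=-1,
            )
        )
    if label_noise > 0:
        flip = rng.random(len(feats)) < label_noise
        for f, do in zip(feats, flip):
            if do:
                f.y = -f.y
    return feats


def templates_to_csv(features: list[SegmentFeatures], path) -> None:
    pd.DataFrame(
        [
            {"segment_id": f.segment_id, "l": f.l, "r_max": f.r_max,
             "r_min": f.r_min, "J": f.J, "y": f.y}
            for f in features
        ]
    ).to_csv(path, index=False)


def load_templates_csv(path) -> list[SegmentFeatures]:
    """Load labeled templates from CSV columns segment_id, l, r_max, r_min, J, y."""
    df = pd.read_csv(path)
    return [
        SegmentFeatures(
            segment_id=int(r.segment_id), l=float(r.l), r_max=float(r.r_max),
            r_min=float(r.r_min), J=int(r.J),
            y=int(r.y) if not pd.isna(r.y) else None,
        )
        for r in df.itertuples()
    ]


def shipped_training_set() -> list[SegmentFeatures]:
    """The template set distributed with the package."""
    with resources.as_file(resources.files("sprouttrack.data") / "templates.csv") as p:
        return load_templates_csv(p)


def default_classifier(C: float = 1.0) -> LinearSVMModel:
    """Classifier trained on the shipped template set."""
    return train_segment_classifier(shipped_training_set(), C=C)
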