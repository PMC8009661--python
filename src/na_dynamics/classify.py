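"""Nine-class trajectory classification with a cubic-kernel SVM.

Training data come from conservative rule-based auto-labeling (high
precision, low recall) optionally amended by manual labels; classes are
balanced to the mean label count by seeded over/under-sampling before
training a degree-3 polynomial SVM on standardized features.  Retraining
after a manual relabel is a pure function of (features, labels), emulating
the human-in-the-loop workflow without a GUI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .tracking import AdhesionTrack

__all__ = ["LabelSet", "ClassModel", "auto_label", "balance_labels",
           "train", "predict", "MIN_LABELS_PER_CLASS"]

MIN_LABELS_PER_CLASS = 10
CLASS_NAMES = [f"G{i}" for i in range(1, 10)]


@dataclass
class LabelSet:
    """track_id -> class label, with per-label provenance (auto/manual)."""

    labels: dict[int, str] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def set(self, track_id: int, label: str, provenance: str = "manual") -> None:
        if label not in CLASS_NAMES:
            raise ValueError(f"unknown class {label!r}")
        self.labels[track_id] = label
        self.provenance[track_id] = provenance

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.labels.values():
            out[v] = out.get(v, 0) + 1
        return out

    def ready_for_training(self) -> bool:
        c = self.counts()
        return len(c) >= 2 and all(v >= MIN_LABELS_PER_CLASS for v in c.values())


@dataclass
class ClassModel:
    """Trained classifier: standardization + degree-3 polynomial SVM."""

    pipeline: Pipeline
    classes: list[str]
    validation_accuracy: float
    n_features: int = 22


def _col(features: pd.DataFrame, name: str) -> np.ndarray:
    return features[name].to_numpy()


def auto_label(features: pd.DataFrame,
               tracks: list[AdhesionTrack] | None = None,
               frame_interval_s: float = 2.0) -> LabelSet:
    """Rule-based high-confidence labeling; ambiguous tracks stay unlabeled.

    Rules operate on the 22-feature table (all in physical units): e.g.
    G9 = blip of <= 3 frames with no segment overlap; G2 = born at the edge,
    matured, long-lived; G3 = born at the edge and moving with the
    protrusion.
    """
    ls = LabelSet()
    life = _col(features, "f1_lifetime_s")
    mean_amp = _col(features, "f2_mean_amplitude")
    v_edge = _col(features, "f11_signed_edge_normal_velocity")
    d_birth = _col(features, "f14_initial_distance_to_edge_um")
    frac_seg = _col(features, "f18_fraction_frames_in_segment")
    ends_seg = _col(features, "f21_ends_in_segment")
    born_edge = _col(features, "f22_born_at_edge") > 0.5
    speed = _col(features, "f10_mean_speed")
    early = _col(features, "f7_early_amplitude_slope")
    late = _col(features, "f8_late_amplitude_slope")
    ids = _col(features, "track_id").astype(int)

    na_like = frac_seg < 0.05
    net_disp = _col(features, "f12_net_displacement_um")
    end_ratio = _col(features, "f5_end_to_max_amplitude_ratio")

    for i, tid in enumerate(ids):
        label = None
        if life[i] <= 2 * frame_interval_s and frac_seg[i] == 0:
            label = "G9"
        elif born_edge[i] and frac_seg[i] > 0.3 and ends_seg[i] > 0.5 and life[i] > 900:
            label = "G2"
        elif born_edge[i] and v_edge[i] > 0.5 and na_like[i] and life[i] < 150:
            label = "G3"
        elif born_edge[i] and na_like[i] and abs(v_edge[i]) < 0.3 and 150 <= life[i] <= 600:
            label = "G1"
        elif (not born_edge[i]) and na_like[i] and life[i] < 200 and d_birth[i] > 2.0:
            label = "G4"
        elif (not born_edge[i]) and 0.05 < frac_seg[i] < 0.4 and ends_seg[i] < 0.5 and 150 <= life[i] < 400:
            label = "G5"
        elif frac_seg[i] > 0.9 and life[i] > 500:
            # FA classes: sliding-disassembling moves far and fades; growing
            # ends at its amplitude maximum; stable lives longest in place
            if net_disp[i] > 2.0 and end_ratio[i] < 0.6:
                label = "G8"
            elif net_disp[i] <= 2.0 and end_ratio[i] > 0.8:
                label = "G7"
            elif net_disp[i] <= 2.0 and end_ratio[i] < 0.6 and life[i] > 1000:
                label = "G6"
        if label is not None:
            ls.set(int(tid), label, provenance="auto")
    return ls


def balance_labels(labels: LabelSet, seed: int = 0) -> list[tuple[int, str]]:
    """Resample every class to round(mean class count).

    Minority classes are oversampled with replacement, majority classes
    undersampled without; returns (track_id, label) pairs.  Seeded and
    deterministic.
    """
    counts = labels.counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to balance")
    if any(v == 0 for v in counts.values()):
        raise ValueError("empty class")
    target = int(round(np.mean(list(counts.values()))))
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for tid, lab in sorted(labels.labels.items()):
        by_class.setdefault(lab, []).append(tid)
    out: list[tuple[int, str]] = []
    for lab in sorted(by_class):
        ids = np.array(by_class[lab])
        if len(ids) >= target:
            chosen = rng.choice(ids, size=target, replace=False)
        else:
            chosen = np.concatenate([
                ids, rng.choice(ids, size=target - len(ids), replace=True)])
        out.extend((int(t), lab) for t in chosen)
    return out


def _matrix(features: pd.DataFrame, ids: list[int]) -> np.ndarray:
    sub = features.set_index("track_id").loc[ids, FEATURE_NAMES]
    return sub.to_numpy(dtype=float)


def train(features: pd.DataFrame, balanced: list[tuple[int, str]],
          cv_folds: int = 5, C: float = 1.0, seed: int = 0) -> ClassModel:
    """Train the degree-3 polynomial SVM on balanced labels.

    Features are standardized inside the pipeline (identically applied at
    prediction); k-fold validation accuracy is estimated with seeded
    stratified folds.
    """
    ids = [t for t, _ in balanced]
    y = np.array([lab for _, lab in balanced])
    classes, cls_counts = np.unique(y, return_counts=True)
    if (cls_counts < MIN_LABELS_PER_CLASS).any():
        raise ValueError(
            f"every class needs >= {MIN_LABELS_PER_CLASS} labels before training")
    X = _matrix(features, ids)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate features: zero variance everywhere")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        # coef0=1: inhomogeneous cubic kernel (includes the lower-order
        # terms), the usual "cubic SVM" convention
        ("svm", SVC(kernel="poly", degree=3, coef0=1.0, C=C,
                    decision_function_shape="ovo", random_state=seed)),
    ])
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(pipe, X, y, cv=skf)
    pipe.fit(X, y)
    return ClassModel(pipe, list(classes), float(scores.mean()),
                      n_features=X.shape[1])


def predict(model: ClassModel, features: pd.DataFrame) -> pd.Series:
    """Class per track; index = track_id.  Deterministic."""
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing or len(FEATURE_NAMES) != model.n_features:
        raise ValueError("feature table does not carry the 22 expected features")
    X = features[FEATURE_NAMES].to_numpy(dtype=float)
    return pd.Series(model.pipeline.predict(X),
                     index=features["track_id"].astype(int), name="class")
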