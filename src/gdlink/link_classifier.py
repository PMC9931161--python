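"""Pair features and the logistic link classifier.

A labeled node pair (u, v) is represented by the element-wise sum of its
two embedding vectors with the pair's GDPS appended as one extra feature.
The classifier is an L2-regularized logistic regression predicting the
"link formation" class at probability threshold 0.5; class balance in the
labeled set makes 0.5 the natural operating point. An ablation switch
drops the GDPS column to quantify its contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
    auc as trapezoid_auc,
)
from sklearn.model_selection import StratifiedKFold

from . import gdps as gdps_mod
from .edge_sampling import LabeledEdgeSet, Pair
from .embedding import EmbeddingTable, pair_vector
from .gdps import GdpsContext


class ClassifierError(ValueError):
    pass


@dataclass
class PairFeature:
    vector: np.ndarray
    label: int
    pair: Pair


@dataclass
class EvalReport:
    micro_f1: float
    precision: float
    recall: float
    auc: float
    roc_points: list[tuple[float, float]]
    cv_mean_f1: float | None = None
    cv_sd_f1: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def save_roc_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


def build_features(
    labeled: LabeledEdgeSet,
    tbl: EmbeddingTable,
    ctx: GdpsContext,
    use_gdps: bool = True,
    split: str | None = None,
) -> list[PairFeature]:
    """One feature vector per labeled pair (optionally one split only)."""
    features = []
    for pair, label in labeled.labeled_pairs():
        if split is not None and labeled.split[pair] != split:
            continue
        vec = pair_vector(tbl, *pair)
        if use_gdps:
            g = labeled.gdps.get(pair)
            if g is None:
                g = gdps_mod.score_pair(ctx, *pair)
            vec = np.concatenate([vec, [g]])
        features.append(PairFeature(vector=vec, label=label, pair=pair))
    return features


def feature_pair(
    tbl: EmbeddingTable,
    ctx: GdpsContext,
    a: str,
    b: str,
    use_gdps: bool = True,
) -> np.ndarray:
    """Feature vector for an unlabeled candidate pair."""
    vec = pair_vector(tbl, a, b)
    if use_gdps:
        vec = np.concatenate([vec, [gdps_mod.score_pair(ctx, a, b)]])
    return vec


def _design(features: list[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    if not features:
        raise ClassifierError("empty feature list")
    X = np.vstack([f.vector for f in features])
    y = np.array([f.label for f in features])
    return X, y


def train(
    features: list[PairFeature],
    seed: int,
    c: float = 1.0,
    standardize: bool = False,
) -> LogisticRegression:
    """Fit the L2 logistic model on the given features.

    ``standardize`` optionally z-scores columns before fitting (embedding
    coordinates and GDPS are both O(1), so the default leaves them raw).
    """
    X, y = _design(features)
    if len(np.unique(y)) < 2:
        raise ClassifierError("training data contains a single class")
    if standardize:
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=c, max_iter=1000, random_state=seed),
        )
    else:
        model = LogisticRegression(C=c, max_iter=1000, random_state=seed)
    model.fit(X, y)
    return model


def cross_validate(
    features: list[PairFeature], k: int, seed: int, c: float = 1.0
) -> tuple[float, float]:
    """Mean and SD of per-fold micro-F1 under stratified k-fold CV."""
    X, y = _design(features)
    class_counts = np.bincount(y)
    if k < 2 or k > class_counts.min():
        raise ClassifierError(f"k={k} invalid for class counts {class_counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        model = LogisticRegression(C=c, max_iter=1000, random_state=seed)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        scores.append(f1_score(y[test_idx], pred, average="micro"))
    return float(np.mean(scores)), float(np.std(scores))


def evaluate(model, features: list[PairFeature]) -> EvalReport:
    """Threshold-0.5 precision/recall/micro-F1 plus the trapezoidal AUC."""
    X, y = _design(features)
    prob = model.predict_proba(X)[:, 1]
    pred = (prob >= 0.5).astype(int)
    fpr, tpr, _ = roc_curve(y, prob)
    return EvalReport(
        micro_f1=float(f1_score(y, pred, average="micro")),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        auc=float(trapezoid_auc(fpr, tpr)),
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


def save_model(model, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path):
    return joblib.load(path)
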