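"""Cell classification from per-marker counts and evaluation metrics.

A random forest over the 11 marker-count features (plus the total) separates
the five cell classes.  Evaluation reports a truth-on-rows confusion matrix,
one-vs-rest precision/recall/F1/specificity per class, and the generalized
multiclass Matthews correlation coefficient.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .simgen import MARKERS

__all__ = [
    "CellClassifier",
    "EvalReport",
    "split_training",
    "train_classifier",
    "evaluate",
    "cohort_summary",
    "DEFAULT_QUOTAS",
    "QUALITY_FLAGS",
]

#: Stratified training quotas at ratio 2/5/1/1/1 over 1000 cells.
DEFAULT_QUOTAS = {
    "CTC": 200,
    "PBMC": 500,
    "artefact": 100,
    "false_positive": 100,
    "negative": 100,
}

QUALITY_FLAGS = ("oversegmented", "undersegmented", "mixed_true_false_signals")


def split_training(
    profiles: pd.DataFrame,
    labels: pd.Series,
    quotas: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified training/test split by per-class quotas.

    Cells flagged with any quality issue (over/undersegmentation, mixed
    true/false signals) are excluded from the training draw; the test set is
    everything not drawn.  Returns (train_index, test_index) positional
    index arrays.  Deterministic for a given seed.
    """
    quotas = quotas if quotas is not None else DEFAULT_QUOTAS
    labels = labels.reset_index(drop=True)
    profiles = profiles.reset_index(drop=True)

    eligible = np.ones(len(profiles), dtype=bool)
    for flag in QUALITY_FLAGS:
        if flag in profiles.columns:
            eligible &= ~profiles[flag].astype(bool).to_numpy()

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls in sorted(quotas):
        quota = quotas[cls]
        pool = np.flatnonzero((labels == cls).to_numpy() & eligible)
        if len(pool) < quota:
            raise ValueError(
                f"class {cls!r} has only {len(pool)} eligible cells for a quota of "
                f"{quota} (shortfall {quota - len(pool)})"
            )
        train_idx.extend(rng.choice(pool, size=quota, replace=False))
    train = np.sort(np.array(train_idx, dtype=int))
    test = np.setdiff1d(np.arange(len(profiles)), train)
    return train, test


@dataclass
class CellClassifier:
    """Serialized-forest wrapper pinning the feature order and seed."""

    model: RandomForestClassifier
    features: tuple[str, ...]
    seed: int

    def predict(self, profiles: pd.DataFrame) -> np.ndarray:
        return self.model.predict(profiles[list(self.features)].to_numpy())

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"model": self.model, "features": self.features, "seed": self.seed}, fh)

    @classmethod
    def load(cls, path) -> "CellClassifier":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        return cls(model=d["model"], features=tuple(d["features"]), seed=d["seed"])


def train_classifier(
    profiles: pd.DataFrame,
    labels: pd.Series,
    n_estimators: int = 100,
    max_depth: int | None = None,
    include_total: bool = True,
    seed: int = 0,
) -> CellClassifier:
    """Train a random forest on marker-count features."""
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    features = list(MARKERS)
    if include_total and "total" in profiles.columns:
        features.append("total")
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(profiles[features].to_numpy(), np.asarray(labels))
    return CellClassifier(model=model, features=tuple(features), seed=seed)


@dataclass
class EvalReport:
    confusion: pd.DataFrame  # rows = truth, cols = predicted
    per_class: pd.DataFrame  # precision, recall, f1, specificity, support
    mcc: float
    positive_class: str | None = None
    positive_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "classes": list(self.confusion.index),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "per_class": self.per_class.to_dict(orient="index"),
            "mcc": self.mcc,
            "positive_class": self.positive_class,
            "positive_summary": self.positive_summary,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, data: str) -> "EvalReport":
        d = json.loads(data)
        classes = d["confusion"]["classes"]
        confusion = pd.DataFrame(d["confusion"]["matrix"], index=classes, columns=classes)
        per_class = pd.DataFrame.from_dict(d["per_class"], orient="index")
        return cls(
            confusion=confusion,
            per_class=per_class,
            mcc=d["mcc"],
            positive_class=d.get("positive_class"),
            positive_summary=d.get("positive_summary", {}),
        )


def _multiclass_mcc(confusion: np.ndarray) -> float:
    """Generalized (Gorodkin) multiclass Matthews correlation coefficient."""
    c = confusion.astype(float)
    n = c.sum()
    trace = np.trace(c)
    pred = c.sum(axis=0)
    true = c.sum(axis=1)
    cov_xy = trace * n - true @ pred
    cov_xx = n * n - pred @ pred
    cov_yy = n * n - true @ true
    denom = np.sqrt(cov_xx * cov_yy)
    if denom == 0:
        return 0.0
    return float(cov_xy / denom)


def evaluate(
    predicted, truth, positive_class: str | None = None, classes: list[str] | None = None
) -> EvalReport:
    """Compute the confusion matrix and one-vs-rest metrics.

    precision = TP/(TP+FP), recall = TP/(TP+FN), specificity = TN/(TN+FP),
    F1 = harmonic mean of precision and recall.  Rates are 0 where undefined.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label vectors must have equal length")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))

    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        conf[index[t], index[p]] += 1

    n = conf.sum()
    rows = {}
    for c in classes:
        i = index[c]
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "specificity": specificity,
            "support": int(tp + fn),
        }

    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    report = EvalReport(
        confusion=confusion,
        per_class=per_class,
        mcc=_multiclass_mcc(conf),
        positive_class=positive_class,
    )
    if positive_class is not None and positive_class in rows:
        report.positive_summary = dict(rows[positive_class])
    return report


def cohort_summary(
    profiles: pd.DataFrame,
    groups: pd.Series,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Per-group, per-marker positivity and median (Q1, Q3) summary.

    Positivity is the percentage of cells with count >= 1; quantiles use
    linear interpolation.  A ``total`` row is appended per group.  Empty
    groups yield NaN rows flagged via the ``n`` column, never silent zeros.
    """
    groups = groups.reset_index(drop=True)
    profiles = profiles.reset_index(drop=True)
    rows = []
    # categorical group labels keep empty categories visible (flagged n=0)
    group_names = (
        list(groups.cat.categories)
        if isinstance(groups.dtype, pd.CategoricalDtype)
        else list(pd.unique(groups))
    )
    for group in group_names:
        sub = profiles[(groups == group).to_numpy()]
        names = list(markers) + (["total"] if "total" in profiles.columns else [])
        for marker in names:
            if sub.empty:
                rows.append(
                    {
                        "group": group, "marker": marker, "n": 0,
                        "positivity_pct": np.nan, "median": np.nan,
                        "q1": np.nan, "q3": np.nan,
                    }
                )
                continue
            counts = sub[marker].to_numpy(float)
            rows.append(
                {
                    "group": group,
                    "marker": marker,
                    "n": len(counts),
                    "positivity_pct": 100.0 * np.mean(counts >= 1),
                    "median": float(np.percentile(counts, 50)),
                    "q1": float(np.percentile(counts, 25)),
                    "q3": float(np.percentile(counts, 75)),
                }
            )
    return pd.DataFrame(rows)
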