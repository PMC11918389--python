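"""Crop recommendation from soil and ambient measurements.

Seven features drive the recommendation: ambient temperature (°C), air
humidity (%), soil moisture (%), soil pH and the three macronutrients N, P, K
(mg/kg).  Two routes are provided:

* ``nearest_centroid_predict`` — compares a sample against packaged per-crop
  reference profiles (mean feature values for cotton, jute, lentil, maize and
  rice) in standardized feature space; no training data needed.
* ``train_classifier`` / ``evaluate`` — a conventional supervised route
  (random forest, nearest-centroid or logistic regression) scored with
  accuracy and macro precision/recall/F1.

The centroid route measures distance over the macronutrients N, P, K by
default (configurable).  The packaged profiles carry no soil-moisture mean,
and a probe sample's temperature/humidity record the instantaneous ambient at
measurement time — e.g. lab room conditions — rather than the growing-season
climate means the profiles describe, so ambient features are informative for
a trained classifier on real data but misleading for a desk-scale centroid
match.  Features are z-scored with the per-feature standard deviation taken
across the profile means themselves; without this the mg/kg-scale nutrients
would dominate any mixed-unit distance.  A synthetic generator emulates a
labelled recommendation dataset by Gaussian sampling around the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestCentroid

__all__ = [
    "SoilSample",
    "CropProfile",
    "ClassReport",
    "REFERENCE_PROFILES",
    "FEATURES",
    "PROFILE_FEATURES",
    "CENTROID_FEATURES",
    "nearest_centroid_predict",
    "generate_crop_dataset",
    "train_classifier",
    "evaluate",
    "profiles_frame",
]

#: Feature order used throughout; CSV headers use exactly these names.
FEATURES = ("temperature", "humidity", "moisture", "ph", "n", "p", "k")

#: Features present in the packaged reference profiles (moisture has no
#: published per-crop mean).
PROFILE_FEATURES = ("temperature", "humidity", "ph", "n", "p", "k")

#: Default distance features for the centroid route: the persistent soil
#: nutrient signature.  Ambient temperature/humidity (and pH, which varies
#: within a field more than across these profiles) are excluded by default.
CENTROID_FEATURES = ("n", "p", "k")

_RANGES = {
    "temperature": (-20.0, 60.0),
    "humidity": (0.0, 100.0),
    "moisture": (0.0, 100.0),
    "ph": (0.0, 14.0),
    "n": (0.0, np.inf),
    "p": (0.0, np.inf),
    "k": (0.0, np.inf),
}


@dataclass
class SoilSample:
    """One point measurement of the seven recommendation features."""

    temperature: float
    humidity: float
    moisture: float
    ph: float
    n: float
    p: float
    k: float

    def __post_init__(self) -> None:
        for name in FEATURES:
            lo, hi = _RANGES[name]
            v = float(getattr(self, name))
            if not np.isfinite(v) or not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside valid range [{lo}, {hi}]")

    def vector(self, features: Sequence[str] = PROFILE_FEATURES) -> np.ndarray:
        return np.array([getattr(self, f) for f in features], dtype=float)


@dataclass
class CropProfile:
    """Per-crop mean feature values, optionally with per-feature spreads."""

    crop: str
    means: dict[str, float]
    spread: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, v in self.means.items():
            lo, hi = _RANGES[name]
            if not lo <= v <= hi:
                raise ValueError(f"profile {self.crop}: {name}={v} outside [{lo}, {hi}]")
        if self.spread is not None and any(s < 0 for s in self.spread.values()):
            raise ValueError("spread values must be non-negative")

    def vector(self, features: Sequence[str]) -> np.ndarray:
        return np.array([self.means[f] for f in features], dtype=float)


#: Desk-scale reference set: mean parameter values for the five crops grown
#: in the study region (temperature °C, humidity %, soil pH, N/P/K mg/kg).
REFERENCE_PROFILES: tuple[CropProfile, ...] = (
    CropProfile("cotton", {"temperature": 31.23, "humidity": 58.90, "ph": 6.3,
                           "n": 102.35, "p": 51.70, "k": 92.55}),
    CropProfile("jute", {"temperature": 26.11, "humidity": 82.49, "ph": 7.0,
                         "n": 203.04, "p": 189.69, "k": 201.49}),
    CropProfile("lentil", {"temperature": 35.87, "humidity": 58.08, "ph": 7.1,
                           "n": 130.00, "p": 37.70, "k": 139.32}),
    CropProfile("maize", {"temperature": 32.83, "humidity": 77.03, "ph": 5.9,
                          "n": 188.66, "p": 66.27, "k": 198.62}),
    CropProfile("rice", {"temperature": 32.61, "humidity": 70.25, "ph": 5.6,
                         "n": 163.77, "p": 112.77, "k": 134.26}),
)


def profiles_frame(profiles: Iterable[CropProfile] = REFERENCE_PROFILES) -> pd.DataFrame:
    """Reference profiles as a tidy DataFrame (one row per crop)."""
    rows = [{"crop": p.crop, **p.means} for p in profiles]
    return pd.DataFrame(rows).set_index("crop")


def _standardize(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean, scale) from the centroid matrix itself.

    Scale is the standard deviation across profile means; a min-max range is
    the fallback for any degenerate (constant) feature.
    """
    mu = centroids.mean(axis=0)
    sd = centroids.std(axis=0)
    rng = centroids.max(axis=0) - centroids.min(axis=0)
    scale = np.where(sd > 0, sd, np.where(rng > 0, rng, 1.0))
    return mu, scale


def nearest_centroid_predict(sample: SoilSample,
                             profiles: Sequence[CropProfile] = REFERENCE_PROFILES,
                             features: Sequence[str] = CENTROID_FEATURES) -> str:
    """Crop whose standardized reference centroid is nearest (Euclidean).

    Deterministic; ties break alphabetically by crop name.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two crop profiles")
    names = [p.crop for p in profiles]
    C = np.vstack([p.vector(features) for p in profiles])
    mu, scale = _standardize(C)
    z_sample = (sample.vector(features) - mu) / scale
    z_cent = (C - mu) / scale
    d = np.linalg.norm(z_cent - z_sample, axis=1)
    best = min(zip(d, names))  # distance, then alphabetical tie-break
    return best[1]


def generate_crop_dataset(profiles: Sequence[CropProfile] = REFERENCE_PROFILES,
                          spread: float | dict[str, float] = 0.05,
                          n_per_class: int = 100, seed: int = 0,
                          features: Sequence[str] = PROFILE_FEATURES) -> pd.DataFrame:
    """Balanced synthetic labelled dataset around the profile means.

    ``spread`` is either a per-feature sd mapping (feature units) or a single
    fraction of each feature's across-profile range.  Samples are Gaussian
    around each crop's mean, truncated to the valid feature ranges.  Seeded.
    """
    rng = np.random.default_rng(seed)
    C = np.vstack([p.vector(features) for p in profiles])
    span = C.max(axis=0) - C.min(axis=0)
    if isinstance(spread, dict):
        sd = np.array([spread.get(f, 0.0) for f in features], dtype=float)
    else:
        sd = float(spread) * span
    frames = []
    for p in profiles:
        X = rng.normal(p.vector(features), sd, size=(n_per_class, len(features)))
        for j, f in enumerate(features):
            lo, hi = _RANGES[f]
            X[:, j] = np.clip(X[:, j], lo, min(hi, 1e12))
        df = pd.DataFrame(X, columns=list(features))
        df["label"] = p.crop
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def train_classifier(dataset: pd.DataFrame, algorithm: str = "tree_ensemble",
                     seed: int = 0, features: Sequence[str] = PROFILE_FEATURES):
    """Fit a crop classifier on a labelled dataset.

    ``algorithm`` is one of ``tree_ensemble`` (random forest),
    ``nearest_centroid`` or ``logistic``.
    """
    X = dataset[list(features)].to_numpy(dtype=float)
    y = dataset["label"].to_numpy()
    if algorithm == "tree_ensemble":
        model = RandomForestClassifier(n_estimators=200, random_state=int(seed))
    elif algorithm == "nearest_centroid":
        model = NearestCentroid()
    elif algorithm == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=int(seed))
    else:
        raise ValueError(f"unknown algorithm '{algorithm}'")
    model.fit(X, y)
    model.feature_names_ = tuple(features)  # type: ignore[attr-defined]
    return model


@dataclass
class ClassReport:
    """Accuracy, macro precision/recall/F1 and the confusion matrix."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    confusion: pd.DataFrame  # rows: true class, cols: predicted class

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.precision_macro, self.recall_macro, self.f1_macro):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("metrics must lie in [0, 1]")
        total = self.confusion.to_numpy().sum()
        trace = np.trace(self.confusion.to_numpy())
        if total and abs(self.accuracy - trace / total) > 1e-9:
            raise ValueError("accuracy must equal confusion-matrix trace / total")


def evaluate(model, heldout: pd.DataFrame,
             features: Sequence[str] | None = None) -> ClassReport:
    """Score a classifier on held-out labelled data.

    Macro metrics average the per-class precision/recall/F1 over the classes
    present in the truth labels; a class never predicted contributes zero
    precision (the usual convention).
    """
    if features is None:
        features = getattr(model, "feature_names_", PROFILE_FEATURES)
    X = heldout[list(features)].to_numpy(dtype=float)
    y_true = heldout["label"].to_numpy()
    y_pred = model.predict(X)
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    conf = pd.DataFrame(M, index=classes, columns=classes)
    accuracy = float(np.trace(M) / M.sum())
    true_classes = [c for c in classes if conf.loc[c].sum() > 0]
    precisions, recalls, f1s = [], [], []
    for c in true_classes:
        tp = conf.loc[c, c]
        col = conf[c].sum()
        row = conf.loc[c].sum()
        prec = tp / col if col else 0.0
        rec = tp / row if row else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return ClassReport(accuracy=accuracy,
                       precision_macro=float(np.mean(precisions)),
                       recall_macro=float(np.mean(recalls)),
                       f1_macro=float(np.mean(f1s)),
                       confusion=conf)
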