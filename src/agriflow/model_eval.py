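"""Regression-error metrics and a generic yield-regression harness.

Crop-yield models are scored with the three standard loss functions

    MAE  = Σ|yᵢ − ŷᵢ| / n
    MSE  = Σ(yᵢ − ŷᵢ)² / n
    RMSE = sqrt(MSE)

and two ordinary regressors — least squares and a bagged decision-tree
ensemble — are provided behind a small, seeded interface.  Because the field
yield records this harness was designed around are not publicly deposited,
a synthetic generator produces linear yield data from the same driver
features (soil moisture, chlorophyll, NDVI, NDSI) for end-to-end exercise.

``accuracy_pct`` is an explicit convention of this package: it maps a loss
value to a percentage as 100·(1 − loss/reference_scale), clipped to [0, 100].
Published "accuracy" percentages derived from loss functions rarely state
their normalization, so none is treated as a reference value here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

__all__ = [
    "PredictionSet",
    "EvalReport",
    "SyntheticYieldConfig",
    "mae",
    "mse",
    "rmse",
    "accuracy_pct",
    "evaluate_predictions",
    "fit_linear",
    "fit_tree_ensemble",
    "generate_yield_data",
    "train_test_split_indices",
]

YIELD_FEATURES = ("soil_moisture", "chlorophyll", "ndvi", "ndsi")


@dataclass
class PredictionSet:
    """Paired observed/predicted values for one evaluation."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.observed.size != self.predicted.size:
            raise ValueError("observed and predicted lengths differ")
        if self.observed.size < 1:
            raise ValueError("need at least one prediction pair")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("non-finite values in prediction set")

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def errors(self) -> np.ndarray:
        return self.observed - self.predicted


def mae(p: PredictionSet) -> float:
    """Mean absolute error, Σ|yᵢ − ŷᵢ|/n."""
    return float(np.mean(np.abs(p.errors)))


def mse(p: PredictionSet) -> float:
    """Mean squared error, Σ(yᵢ − ŷᵢ)²/n."""
    return float(np.mean(p.errors ** 2))


def rmse(p: PredictionSet) -> float:
    """Root mean squared error, sqrt(MSE)."""
    return float(np.sqrt(mse(p)))


def accuracy_pct(metric_value: float, reference_scale: float) -> float:
    """Map a loss value to a percentage: 100·(1 − loss/reference), clipped.

    ``reference_scale`` is typically the mean absolute observed value.  This
    mapping is a documented convention of this package, not a universal
    definition.
    """
    if reference_scale <= 0:
        raise ValueError("reference_scale must be positive")
    return float(np.clip(100.0 * (1.0 - metric_value / reference_scale), 0.0, 100.0))


@dataclass
class EvalReport:
    """MAE/MSE/RMSE plus their percentage twins for one prediction set."""

    mae: float
    mse: float
    rmse: float
    accuracy_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mae < 0 or self.rmse < 0:
            raise ValueError("mae and rmse must be non-negative")
        if abs(self.mse - self.rmse ** 2) > 1e-9 * max(1.0, self.mse):
            raise ValueError("mse must equal rmse²")
        if self.rmse < self.mae - 1e-12:
            raise ValueError("rmse cannot be smaller than mae")


def evaluate_predictions(p: PredictionSet,
                         reference_scale: float | None = None) -> EvalReport:
    """Compute the full metric report for a prediction set.

    ``reference_scale`` for the percentage mapping defaults to the mean
    absolute observed value.
    """
    if reference_scale is None:
        reference_scale = float(np.mean(np.abs(p.observed)))
    m, s, r = mae(p), mse(p), rmse(p)
    acc = {
        "mae": accuracy_pct(m, reference_scale),
        "rmse": accuracy_pct(r, reference_scale),
        "mse": accuracy_pct(s, reference_scale ** 2),
    }
    return EvalReport(mae=m, mse=s, rmse=r, accuracy_pct=acc)


def fit_linear(features: np.ndarray, target: np.ndarray) -> LinearRegression:
    """Ordinary least-squares fit; recovers exact coefficients on noiseless
    linear data."""
    model = LinearRegression()
    model.fit(np.asarray(features, dtype=float), np.asarray(target, dtype=float))
    return model


def fit_tree_ensemble(features: np.ndarray, target: np.ndarray,
                      n_trees: int = 100, seed: int = 0,
                      max_depth: int | None = None) -> RandomForestRegressor:
    """Bagged regression-tree ensemble (random forest), seeded.

    With unlimited depth and distinct inputs, each tree interpolates its
    bootstrap sample, so training RMSE shrinks toward zero.
    """
    model = RandomForestRegressor(n_estimators=n_trees, random_state=int(seed),
                                  max_depth=max_depth)
    model.fit(np.asarray(features, dtype=float), np.asarray(target, dtype=float))
    return model


@dataclass
class SyntheticYieldConfig:
    """Linear synthetic-yield generator settings.

    Features mirror the remote-sensing drivers of a yield model: soil moisture
    (%), chlorophyll (index, positive), NDVI and NDSI (each in [−1, 1]).  The
    target is ``intercept + coeffs·x + N(0, noise_sd)``.
    """

    coefficients: tuple[float, float, float, float] = (0.08, 1.5, 4.0, -2.0)
    intercept: float = 2.0
    noise_sd: float = 0.25
    n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("n must exceed the number of features")


def generate_yield_data(cfg: SyntheticYieldConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw (features, target) under the configured linear model.

    Feature ranges: soil moisture uniform on [5, 95] %, chlorophyll uniform on
    [0.5, 8] (arbitrary positive index units), NDVI and NDSI uniform on
    [−1, 1].  Reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    X = np.column_stack([
        rng.uniform(5.0, 95.0, cfg.n),
        rng.uniform(0.5, 8.0, cfg.n),
        rng.uniform(-1.0, 1.0, cfg.n),
        rng.uniform(-1.0, 1.0, cfg.n),
    ])
    y = cfg.intercept + X @ np.asarray(cfg.coefficients, dtype=float)
    y = y + rng.normal(0.0, cfg.noise_sd, cfg.n)
    return X, y


def train_test_split_indices(n: int, test_fraction: float = 0.2,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffled split; default 80/20."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return perm[n_test:], perm[:n_test]
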