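"""Neural probability-of-occurrence surfaces.

A single-hidden-layer network with logistic (sigmoid) hidden activation
maps the normalized driver vector of each cell to one raw score per land
class; scores are turned into a per-cell probability distribution by
dividing by their sum, so the suitability probabilities of all classes
sum to exactly 1 on every cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .grids import DriverStack, LandUseMap


@dataclass
class SuitabilityStack:
    """Per-class probability rasters; per-cell sums are 1 on valid cells."""

    sp: np.ndarray  # (K, rows, cols)
    classes: np.ndarray
    nodata_mask: np.ndarray

    def probs(self) -> np.ndarray:
        return self.sp

    def class_index(self, code: int) -> int:
        return int(np.where(self.classes == code)[0][0])


@dataclass
class SuitabilityModel:
    """Trained one-hidden-layer suitability network plus its preprocessing."""

    input_names: list[str]
    hidden_size: int
    normalization_bounds: dict[str, tuple[float, float]]
    classes: np.ndarray  # all K class codes, canonical order
    rng_seed: int
    estimator: MLPClassifier | None = None
    single_class: int | None = None  # degenerate one-class training set
    loss_curve: list[float] = field(default_factory=list)

    @property
    def weights_in(self) -> np.ndarray | None:
        return None if self.estimator is None else self.estimator.coefs_[0]

    @property
    def weights_out(self) -> np.ndarray | None:
        return None if self.estimator is None else self.estimator.coefs_[1]


def sample_training_cells(
    lu: LandUseMap,
    drivers: DriverStack,
    fraction: float = 0.05,
    strategy: str = "stratified",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a reproducible training sample of (driver vector, class) pairs.

    ``stratified`` draws equal counts per class where possible (classes
    with fewer cells contribute everything they have); ``uniform`` draws
    cells uniformly over the landscape. ``fraction`` is relative to the
    non-nodata cell count.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if strategy not in ("uniform", "stratified"):
        raise ValueError(f"unknown sampling strategy {strategy!r}")
    valid = ~lu.nodata_mask
    flat_idx = np.flatnonzero(valid.ravel())
    labels_all = lu.codes.ravel()[flat_idx]
    n_request = max(1, int(round(fraction * len(flat_idx))))
    rng = np.random.default_rng(seed)

    if fraction == 1.0:
        chosen = flat_idx
    elif strategy == "uniform":
        chosen = rng.choice(flat_idx, size=n_request, replace=False)
    else:
        codes = lu.class_codes
        present = [c for c in codes if np.any(labels_all == c)]
        skipped = [c for c in codes if c not in present]
        if skipped:
            warnings.warn(
                f"stratified sampling: no cells for class(es) {skipped}, skipped",
                stacklevel=2,
            )
        per_class = max(1, n_request // len(present))
        parts = []
        for c in present:
            pool = flat_idx[labels_all == c]
            take = min(per_class, len(pool))
            parts.append(rng.choice(pool, size=take, replace=False))
        chosen = np.concatenate(parts)
    chosen = np.sort(chosen)
    features = drivers.data.reshape(len(drivers.names), -1)[:, chosen].T
    labels = lu.codes.ravel()[chosen]
    return features, labels


def train_suitability_model(
    features: np.ndarray,
    labels: np.ndarray,
    input_names: list[str],
    normalization_bounds: dict[str, tuple[float, float]],
    classes: np.ndarray,
    hidden_size: int = 12,
    epochs: int = 200,
    seed: int = 0,
) -> SuitabilityModel:
    """Fit the suitability network on (already normalized) features.

    Deterministic given ``seed``. A single-class training set bypasses the
    network and yields a constant predictor for that class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise ValueError("driver features contain non-finite values")
    present = np.unique(labels)
    model = SuitabilityModel(
        input_names=list(input_names),
        hidden_size=hidden_size,
        normalization_bounds=dict(normalization_bounds),
        classes=np.asarray(classes),
        rng_seed=seed,
    )
    if len(present) == 1:
        model.single_class = int(present[0])
        return model
    est = MLPClassifier(
        hidden_layer_sizes=(hidden_size,),
        activation="logistic",
        solver="adam",
        max_iter=epochs,
        random_state=seed,
        n_iter_no_change=epochs,  # run the full epoch budget
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(features, labels)
    model.estimator = est
    model.loss_curve = list(est.loss_curve_)
    return model


def fit_suitability(
    lu: LandUseMap,
    drivers: DriverStack,
    fraction: float = 0.05,
    strategy: str = "stratified",
    hidden_size: int = 12,
    epochs: int = 200,
    seed: int = 0,
) -> SuitabilityModel:
    """Convenience wrapper: normalize drivers, sample cells, train."""
    norm = drivers.normalized()
    features, labels = sample_training_cells(lu, norm, fraction, strategy, seed)
    return train_suitability_model(
        features,
        labels,
        norm.names,
        norm.normalization_bounds,
        lu.class_codes,
        hidden_size=hidden_size,
        epochs=epochs,
        seed=seed,
    )


def predict_suitability(model: SuitabilityModel, drivers: DriverStack) -> SuitabilityStack:
    """Per-cell, per-class suitability probabilities, sum-normalized to 1.

    Drivers are reordered to the model's input layout and min-max scaled
    with the bounds stored at fit time; values outside those bounds are
    clamped to [0, 1] with a warning.
    """
    missing = set(model.input_names) - set(drivers.names)
    if missing:
        raise ValueError(f"driver stack missing layer(s): {sorted(missing)}")
    rows, cols = drivers.shape
    valid = ~drivers.nodata_mask
    X = np.empty((int(valid.sum()), len(model.input_names)))
    clamped = False
    for j, name in enumerate(model.input_names):
        lo, hi = model.normalization_bounds[name]
        span = hi - lo if hi > lo else 1.0
        x = (drivers.layer(name)[valid] - lo) / span
        if np.any(x < 0) or np.any(x > 1):
            clamped = True
            x = np.clip(x, 0.0, 1.0)
        X[:, j] = x
    if clamped:
        warnings.warn("driver values outside fit-time bounds were clamped", stacklevel=2)

    k = len(model.classes)
    probs = np.zeros((int(valid.sum()), k))
    if model.single_class is not None:
        probs[:, np.where(model.classes == model.single_class)[0][0]] = 1.0
    else:
        est = model.estimator
        raw = est.predict_proba(X)
        cols_idx = [int(np.where(model.classes == c)[0][0]) for c in est.classes_]
        probs[:, cols_idx] = raw
        probs /= probs.sum(axis=1, keepdims=True)

    sp = np.full((k, rows, cols), np.nan)
    for i in range(k):
        layer = sp[i]
        layer[valid] = probs[:, i]
    return SuitabilityStack(sp, np.asarray(model.classes), drivers.nodata_mask.copy())
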