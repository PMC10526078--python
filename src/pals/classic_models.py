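"""Per-pixel baselines: quadratic discriminant analysis, a one-hidden-layer
neural network, an RBF support vector machine, and a random forest.

Defaults: NN hidden nodes 53; SVM RBF kernel with C = 16; RF 50 trees with
min_samples_leaf = 1000.  Each fitted model classifies pixels independently
from their normalized spectra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from pals.core_io import Frame, SegmentationResult, ValidationError
from pals.evaluation import score_algorithm
from pals.sampling import PixelDataset, balance, extract_pixels

log = logging.getLogger(__name__)

FAMILIES = ("QDA", "NN", "SVM", "RF")

_DEFAULT_HYPERPARAMS = {
    "QDA": {},
    "NN": {"hidden_nodes": 53},
    "SVM": {"kernel": "rbf", "C": 16.0},
    "RF": {"n_trees": 50, "min_samples_leaf": 1000},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")

    def resolved(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMS[self.family])
        params.update(self.hyperparams)
        return params


@dataclass
class FittedPixelModel:
    """A trained per-pixel classifier bound to its wavelength count."""

    spec: ModelSpec
    estimator: object
    n_wavelengths: int

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        if spectra.shape[1] != self.n_wavelengths:
            raise ValidationError(
                f"model expects {self.n_wavelengths} wavelengths, "
                f"got {spectra.shape[1]}"
            )
        return np.asarray(self.estimator.predict(spectra), dtype=np.int8)

    def scores(self, spectra: np.ndarray) -> np.ndarray:
        """N x 2 score matrix (decision-function based where available)."""
        est = self.estimator
        if hasattr(est, "predict_proba"):
            try:
                return np.asarray(est.predict_proba(spectra))
            except AttributeError:  # pragma: no cover - SVC(probability=False)
                pass
        if hasattr(est, "decision_function"):
            d = np.asarray(est.decision_function(spectra))
            return np.stack([-d, d], axis=1)
        pred = self.predict(spectra)
        return np.stack([1.0 - pred, pred], axis=1)


def _build_estimator(spec: ModelSpec, seed: int):
    p = spec.resolved()
    if spec.family == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.0))
    if spec.family == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(p["hidden_nodes"],),
            max_iter=p.get("max_iter", 300),
            random_state=seed,
        )
    if spec.family == "SVM":
        return SVC(kernel=p["kernel"], C=p["C"], random_state=seed)
    if spec.family == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValidationError(f"unknown family {spec.family!r}")  # pragma: no cover


def train(spec: ModelSpec, dataset: PixelDataset, seed: int = 0) -> FittedPixelModel:
    """Fit a per-pixel classifier on a (balanced) pixel dataset."""
    classes = np.unique(dataset.labels)
    if classes.size < 2:
        raise ValidationError("training requires both classes present")
    est = _build_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny datasets
        try:
            est.fit(dataset.features, dataset.labels)
        except np.linalg.LinAlgError:
            if spec.family == "QDA":
                log.warning("QDA covariance singular; refitting with ridge")
                est = QuadraticDiscriminantAnalysis(reg_param=1e-3)
                est.fit(dataset.features, dataset.labels)
            else:
                raise
    return FittedPixelModel(
        spec=spec, estimator=est, n_wavelengths=dataset.n_wavelengths
    )


def segment_frame(model: FittedPixelModel, frame: Frame) -> SegmentationResult:
    """Classify every pixel of a preprocessed frame independently."""
    cube = frame.cube
    if cube.shape[2] != model.n_wavelengths:
        raise ValidationError(
            f"frame has {cube.shape[2]} wavelengths, model expects "
            f"{model.n_wavelengths}"
        )
    H, W, L = cube.shape
    flat = cube.intensities.reshape(-1, L)
    pred = model.predict(flat)
    scores = model.scores(flat).reshape(H, W, 2)
    return SegmentationResult(scores=scores, decision=pred.reshape(H, W))


def tuning_curve(
    family: str,
    param_name: str,
    values: Sequence,
    train_frames: list[Frame],
    valid_frames: list[Frame],
    seed: int = 0,
) -> list[tuple[object, float]]:
    """Sweep one hyperparameter: fit on group A, score mean F1 on group B."""
    blocks_a = {f.block_id for f in train_frames}
    blocks_b = {f.block_id for f in valid_frames}
    if blocks_a & blocks_b:
        raise ValidationError(f"overlapping blocks in A and B: {blocks_a & blocks_b}")
    dataset = balance(extract_pixels(train_frames), seed=seed)
    curve = []
    for value in values:
        spec = ModelSpec(family=family, hyperparams={param_name: value})
        model = train(spec, dataset, seed=seed)
        decisions = [segment_frame(model, f).decision for f in valid_frames]
        masks = [f.mask for f in valid_frames]
        curve.append((value, score_algorithm(decisions, masks)))
    return curve
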