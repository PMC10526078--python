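"""Greedy sequential forward wavelength selection with a quadratic
classifier, mean-spectrum diagnostics, and wavelength subsetting of cubes.

Selection repeatedly adds the wavelength that minimizes the held-out error
of a quadratic classifier on a 90/10 shuffled pixel split, stopping when no
addition lowers the error.  Earlier-selected wavelengths are more
"important"; reduced sets of size k take the first k entries.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from pals.core_io import MWPACube, ValidationError, WavelengthGrid
from pals.sampling import PixelDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionTrace:
    """Wavelengths in selection order with the error after each addition."""

    order: tuple[float, ...]  # wavelengths (nm), most important first
    errors: tuple[float, ...]
    stop_reason: str  # "no improvement" or "exhausted"

    def __post_init__(self) -> None:
        if len(self.order) != len(set(self.order)):
            raise ValidationError("selection order contains duplicates")
        e = np.asarray(self.errors)
        if e.size > 1 and np.any(np.diff(e) >= 0):
            raise ValidationError("recorded error sequence must strictly decrease")

    def top(self, k: int) -> tuple[float, ...]:
        if k > len(self.order):
            raise ValidationError(f"only {len(self.order)} wavelengths selected")
        return self.order[:k]


def _fit_quadratic(x: np.ndarray, y: np.ndarray) -> QuadraticDiscriminantAnalysis:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear-variable warnings
        try:
            clf = QuadraticDiscriminantAnalysis()
            clf.fit(x, y)
        except np.linalg.LinAlgError:
            log.warning("quadratic fit degenerate; retrying with ridge")
            clf = QuadraticDiscriminantAnalysis(reg_param=1e-3)
            clf.fit(x, y)
    return clf


def _holdout_error(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, y_test: np.ndarray
) -> float:
    clf = _fit_quadratic(x_train, y_train)
    return float(np.mean(clf.predict(x_test) != y_test))


def sequential_select(
    dataset: PixelDataset,
    wavelengths_nm: Sequence[float],
    seed: int = 0,
    test_fraction: float = 0.1,
) -> SelectionTrace:
    """Greedy forward selection over the dataset's wavelength channels."""
    n, n_wl = dataset.features.shape
    if n_wl < 1 or len(wavelengths_nm) != n_wl:
        raise ValidationError("wavelengths must match the feature columns")
    if np.unique(dataset.labels).size < 2:
        raise ValidationError("selection requires both classes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    x_tr, y_tr = dataset.features[train_idx], dataset.labels[train_idx]
    x_te, y_te = dataset.features[test_idx], dataset.labels[test_idx]

    selected: list[int] = []
    errors: list[float] = []
    best_error = np.inf
    wavelengths = np.asarray(wavelengths_nm, dtype=float)
    while len(selected) < n_wl:
        candidates = [j for j in range(n_wl) if j not in selected]
        cand_errors = np.array(
            [
                _holdout_error(
                    x_tr[:, selected + [j]], y_tr, x_te[:, selected + [j]], y_te
                )
                for j in candidates
            ]
        )
        best = cand_errors.min()
        if best >= best_error:
            return SelectionTrace(
                order=tuple(wavelengths[selected]),
                errors=tuple(errors),
                stop_reason="no improvement",
            )
        # tie among equal-error candidates: take the shortest wavelength
        tied = [candidates[i] for i in np.nonzero(cand_errors == best)[0]]
        choice = min(tied, key=lambda j: wavelengths[j])
        selected.append(choice)
        errors.append(float(best))
        best_error = best
    return SelectionTrace(
        order=tuple(wavelengths[selected]),
        errors=tuple(errors),
        stop_reason="exhausted",
    )


def mean_spectra(
    dataset: PixelDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class mean normalized spectra and their ablated:non-ablated ratio."""
    pos = dataset.labels == 1
    neg = dataset.labels == 0
    if not pos.any() or not neg.any():
        raise ValidationError("mean_spectra requires both classes")
    mean_abl = dataset.features[pos].mean(axis=0)
    mean_non = dataset.features[neg].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_non > 0, mean_abl / mean_non, np.inf)
    return mean_abl, mean_non, ratio


def subset_cube(cube: MWPACube, wavelengths_nm: Sequence[float]) -> MWPACube:
    """Restrict a cube to the given wavelengths (re-sorted ascending)."""
    idx = sorted(cube.grid.index_of(wl) for wl in wavelengths_nm)
    if len(idx) != len(set(idx)):
        raise ValidationError("duplicate wavelengths in subset")
    values = [cube.grid.values[i] for i in idx]
    if len(values) == len(cube.grid):
        return dataclasses.replace(cube)
    grid = WavelengthGrid.from_values(values)
    return MWPACube(
        intensities=np.ascontiguousarray(cube.intensities[:, :, idx]),
        grid=grid,
        pixel_pitch_um=cube.pixel_pitch_um,
        state=cube.state,
    )
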