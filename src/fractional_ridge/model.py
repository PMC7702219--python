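"""Estimator-style layer over the fractional ridge solver.

Provides a fit/predict interface over many targets, optional predictor
standardization (centering, or centering plus unit-variance scaling), the
coefficient of determination R^2, and single-split cross-validated
selection of the best fraction per target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DimensionError,
    FRRError,
    ParameterError,
    FRRSolution,
    frr,
)

__all__ = [
    "DegeneratePredictorError",
    "UndefinedScoreError",
    "SplitError",
    "FractionalRidge",
    "CVResult",
    "fit",
    "predict",
    "r2_score",
    "cv_select",
    "DEFAULT_FRACTIONS",
]

#: Fractions 0, 0.05, ..., 1 — the standard 21-level request grid.
DEFAULT_FRACTIONS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)

_STANDARDIZE_CHOICES = ("none", "center", "zscore")


class DegeneratePredictorError(FRRError, ValueError):
    """A predictor has zero variance and cannot be scaled."""


class UndefinedScoreError(FRRError, ValueError):
    """R^2 is undefined because the observed values have zero variance."""


class SplitError(FRRError, ValueError):
    """Train/test split leaves too few data points on one side."""


class FractionalRidge:
    """Fractional ridge regression estimator over many targets.

    Parameters
    ----------
    fractions : sequence of float in [0, 1], optional
        Requested coefficient-norm fractions (default 0 to 1 in steps of
        0.05).
    standardize : {"none", "center", "zscore"}
        "center" removes the per-predictor mean (and the per-target mean,
        re-added at prediction time, which plays the role of an intercept);
        "zscore" additionally scales predictors to unit standard deviation.
    truncation_tol, log_spacing
        Passed to the core solver.

    Attributes (after fit)
    ----------------------
    solution_ : FRRSolution
        Solver output on the (possibly standardized) training problem.
    coefs_ : ndarray, shape (p, f, t)
        Coefficients on the standardized predictor scale.
    alphas_, achieved_fractions_ : ndarray, shape (f, t)
    x_mean_, x_scale_ : ndarray, shape (p,)
    y_mean_ : ndarray, shape (t,)
    """

    def __init__(
        self,
        fractions=None,
        standardize: str = "none",
        truncation_tol: float | None = None,
        log_spacing: float = 0.2,
    ):
        self.fractions = DEFAULT_FRACTIONS if fractions is None else np.asarray(fractions, float)
        if standardize not in _STANDARDIZE_CHOICES:
            raise ParameterError(
                f"standardize must be one of {_STANDARDIZE_CHOICES}, got {standardize!r}"
            )
        self.standardize = standardize
        self.truncation_tol = truncation_tol
        self.log_spacing = log_spacing

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "FractionalRidge":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.shape[0] != X.shape[0]:
            raise DimensionError("X and Y must be 2-D with matching row counts")
        d, p = X.shape
        center = self.standardize in ("center", "zscore")
        scale = self.standardize == "zscore"
        self.x_mean_ = X.mean(axis=0) if center else np.zeros(p)
        self.y_mean_ = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
        Xs = X - self.x_mean_
        Ys = Y - self.y_mean_
        if scale:
            scales = Xs.std(axis=0)
            bad = np.flatnonzero(scales == 0.0)
            if bad.size:
                raise DegeneratePredictorError(
                    f"predictor column(s) {bad.tolist()} have zero variance; cannot scale"
                )
            self.x_scale_ = scales
            Xs = Xs / scales
        else:
            self.x_scale_ = np.ones(p)
        self.solution_: FRRSolution = frr(
            Xs,
            Ys,
            self.fractions,
            truncation_tol=self.truncation_tol,
            log_spacing=self.log_spacing,
        )
        self.coefs_ = self.solution_.coefs
        self.alphas_ = self.solution_.alphas
        self.achieved_fractions_ = self.solution_.achieved_fractions
        self.n_predictors_ = p
        return self

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predictions of shape (d_new, f, t), de-standardized.

        ``X`` is transformed with the stored training means/scales, applied
        to the coefficients, and the training target mean is re-added.
        """
        if not hasattr(self, "solution_"):
            raise FRRError("predict called before fit")
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.n_predictors_:
            raise DimensionError(
                f"X_new has {X_new.shape[1]} columns, expected {self.n_predictors_}"
            )
        Xs = (X_new - self.x_mean_) / self.x_scale_
        preds = np.einsum("dp,pft->dft", Xs, self.coefs_)
        return preds + self.y_mean_[None, None, :]


def fit(X, Y, fractions=None, standardize: str = "none") -> FractionalRidge:
    """Functional wrapper: construct and fit a :class:`FractionalRidge`."""
    return FractionalRidge(fractions=fractions, standardize=standardize).fit(X, Y)


def predict(model: FractionalRidge, X_new) -> np.ndarray:
    """Functional wrapper for :meth:`FractionalRidge.predict`."""
    return model.predict(X_new)


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot`` (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise DimensionError("y_true and y_pred must be equal-length 1-D arrays (>= 2 points)")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedScoreError("y_true has zero variance; R^2 is undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class CVResult:
    """Outcome of single-split cross-validated fraction selection.

    ``best_fraction[k]`` attains the maximum of ``test_r2[:, k]``; exact
    ties are broken toward the smallest (most regularized) fraction.
    """

    best_fraction: np.ndarray  # (t,)
    best_alpha: np.ndarray  # (t,)
    test_r2: np.ndarray  # (f, t)
    split: dict = field(repr=False, default_factory=dict)


def cv_select(
    X,
    Y,
    fractions=None,
    split_spec: float = 0.5,
    seed: int = 0,
    standardize: str = "none",
) -> CVResult:
    """Select the best fraction per target on one train/test split.

    Rows are permuted with a generator seeded by ``seed``; a fraction
    ``split_spec`` of them forms the test set.  The model is fit on the
    training rows, scored by R^2 on the test rows for every fraction and
    target, and the best fraction per target is the R^2 argmax (ties broken
    toward the smallest fraction).  The split indices and seed are recorded
    so the result is exactly reproducible.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (0.0 < split_spec < 1.0):
        raise SplitError(f"split fraction must lie in (0, 1), got {split_spec}")
    d = X.shape[0]
    n_test = int(round(d * split_spec))
    n_train = d - n_test
    if n_train < 2 or n_test < 2:
        raise SplitError(f"split leaves too few points (train {n_train}, test {n_test})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(d)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    model = FractionalRidge(fractions=fractions, standardize=standardize)
    model.fit(X[train_idx], Y[train_idx])
    preds = model.predict(X[test_idx])  # (n_test, f, t)
    f, t = model.coefs_.shape[1], model.coefs_.shape[2]
    test_r2 = np.empty((f, t))
    for k in range(t):
        for j in range(f):
            test_r2[j, k] = r2_score(Y[test_idx, k], preds[:, j, k])

    fracs = model.fractions
    best_fraction = np.empty(t)
    best_alpha = np.empty(t)
    for k in range(t):
        col = test_r2[:, k]
        tied = np.flatnonzero(col == col.max())
        j = tied[np.argmin(fracs[tied])]
        best_fraction[k] = fracs[j]
        best_alpha[k] = model.alphas_[j, k]

    return CVResult(
        best_fraction=best_fraction,
        best_alpha=best_alpha,
        test_r2=test_r2,
        split={
            "train_indices": train_idx,
            "test_indices": test_idx,
            "seed": seed,
            "test_fraction": split_spec,
        },
    )
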