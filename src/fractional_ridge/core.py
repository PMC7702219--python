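"""Fractional ridge regression: the SVD-based solver.

Ridge regression shrinks linear-regression coefficients by adding a penalty
``alpha`` on their squared L2-norm.  Instead of asking the user for ``alpha``
— whose useful range depends on the scale of the design matrix and on
predictor collinearity — fractional ridge regression (FRR) asks for the
fraction ``gamma`` in [0, 1] by which the L2-norm of the solution should be
shrunk relative to the unregularized (OLS / pseudoinverse) solution, and
finds the ``alpha`` that achieves it for each target.

The machinery rests on the singular value decomposition X = U S V^T.
Rotating the target by U^T turns ridge regression into independent scalar
shrinkages: each rotated OLS coefficient ``b_i = y_rot_i / lambda_i`` is
multiplied by ``lambda_i^2 / (lambda_i^2 + alpha)``.  The achieved fraction
``gamma(alpha)`` is therefore cheap to evaluate on a grid of candidate
``alpha`` values, and the ``alpha`` matching a requested fraction is found
by interpolation.  A single back-rotation by V returns all solutions to the
original predictor space; V being orthonormal, coefficient norms (and hence
fractions) are identical in both spaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "FRRError",
    "InvalidInputError",
    "DegenerateDesignError",
    "DimensionError",
    "ParameterError",
    "ZeroNormTargetError",
    "InternalConsistencyError",
    "DesignDecomposition",
    "RotatedTarget",
    "AlphaGrid",
    "ShrinkageTable",
    "FRRSolution",
    "decompose_design",
    "rotate_target",
    "build_alpha_grid",
    "shrinkage_factors",
    "gamma_curve",
    "interpolate_alphas",
    "solve_target",
    "unrotate",
    "frr",
    "ridge_direct",
]

logger = logging.getLogger(__name__)

#: Default log10 spacing of the internal alpha grid.  Fine enough that
#: piecewise-linear interpolation recovers requested fractions to ~1%.
DEFAULT_LOG_SPACING = 0.2


class FRRError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(FRRError, ValueError):
    """Input array contains non-finite values or has an invalid shape."""


class DegenerateDesignError(FRRError, ValueError):
    """Design matrix has rank zero (e.g., all-zero X)."""


class DimensionError(FRRError, ValueError):
    """Array dimensions are inconsistent with each other."""


class ParameterError(FRRError, ValueError):
    """A scalar parameter is outside its valid range."""


class ZeroNormTargetError(FRRError, ValueError):
    """Target has a zero-norm OLS solution; the fraction gamma is undefined."""


class InternalConsistencyError(FRRError, RuntimeError):
    """An internal invariant was violated (e.g., non-monotone gamma curve)."""


@dataclass(frozen=True)
class DesignDecomposition:
    """Reduced SVD of a design matrix, truncated at numerically-zero rank.

    Attributes
    ----------
    singular_values : ndarray, shape (r,)
        Strictly positive singular values, sorted non-increasing.
    right_rotation : ndarray, shape (p, r)
        Right singular vectors V; columns orthonormal.  Maps rotated-space
        coefficients back to predictor space.
    target_projector : ndarray, shape (d, r)
        Left singular vectors U; ``U.T @ y`` projects a target into the
        reduced space.
    rank : int
        Effective rank r after truncation.
    truncation_tol : float
        Relative threshold: singular values below ``tol * lambda_1`` were
        treated as zero.
    """

    singular_values: np.ndarray
    right_rotation: np.ndarray
    target_projector: np.ndarray
    rank: int
    truncation_tol: float

    def project_targets(self, Y: np.ndarray) -> np.ndarray:
        """Apply U^T to one target vector or a (d, t) matrix of targets."""
        return self.target_projector.T @ Y


@dataclass(frozen=True)
class RotatedTarget:
    """A single target in the reduced (rotated) space.

    ``beta_ols_rot[i] = y_rot[i] / lambda_i`` is the rotated OLS solution;
    ``ols_norm`` is its Euclidean norm, the denominator of every fraction.
    """

    y_rot: np.ndarray
    beta_ols_rot: np.ndarray
    ols_norm: float


@dataclass(frozen=True)
class AlphaGrid:
    """Log-spaced candidate ridge penalties spanning the useful range.

    The span runs from well below ``lambda_r**2`` (negligible shrinkage of
    every component) to well above ``lambda_1**2`` (near-total shrinkage),
    with endpoints snapped outward onto the ``log_spacing`` lattice so the
    grid is reproducible for a given singular-value range.
    """

    alphas: np.ndarray
    log_spacing: float
    lo_exponent: float
    hi_exponent: float


@dataclass(frozen=True)
class ShrinkageTable:
    """Per-component shrinkage factors ``SF[i, j] = l_i^2 / (l_i^2 + a_j)``."""

    factors: np.ndarray  # shape (r, m), entries in (0, 1)


@dataclass(frozen=True)
class FRRSolution:
    """Result of a fractional ridge fit over many targets.

    Attributes
    ----------
    fractions : ndarray, shape (f,)
        Requested fractions, in the caller's original order.
    coefs : ndarray, shape (p, f, t)
        Coefficients per predictor, fraction, target (original space).
    alphas : ndarray, shape (f, t)
        Ridge penalty achieving each fraction for each target.  0 for
        gamma=1, ``inf`` for gamma=0, NaN for degenerate (zero-OLS) targets.
    achieved_fractions : ndarray, shape (f, t)
        ``||beta_frr||_2 / ||beta_ols||_2`` actually realized; NaN for
        degenerate targets.
    """

    fractions: np.ndarray
    coefs: np.ndarray
    alphas: np.ndarray
    achieved_fractions: np.ndarray


def decompose_design(
    X: np.ndarray,
    truncation_tol: float | None = None,
    method: str = "auto",
) -> DesignDecomposition:
    """Compute the truncated SVD of the design matrix.

    Parameters
    ----------
    X : ndarray, shape (d, p)
        Design matrix; rows are data points, columns are predictors.
    truncation_tol : float, optional
        Relative cutoff; singular values below ``tol * lambda_1`` are
        discarded.  Default ``max(d, p) * machine epsilon`` (the standard
        pseudoinverse convention).
    method : {"auto", "svd", "gram"}
        "svd" decomposes X directly.  "gram" obtains the singular values as
        square roots of the eigenvalues of the p-by-p matrix X^T X, which is
        cheaper in memory when d > p.  "auto" picks "gram" when d > p.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise InvalidInputError(f"design must be a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("design matrix contains non-finite entries")
    d, p = X.shape
    if truncation_tol is None:
        truncation_tol = max(d, p) * np.finfo(float).eps
    if method == "auto":
        method = "gram" if d > p else "svd"
    if method == "gram":
        evals, evecs = linalg.eigh(X.T @ X)
        # eigh returns ascending order
        evals = evals[::-1]
        V = evecs[:, ::-1]
        # the Gram route works on squared singular values, so components
        # below ~sqrt(eps)*lambda_1 are numerically indistinguishable from
        # zero and must be cut on the eigenvalue scale
        gram_cut = max(d, p) * np.finfo(float).eps * max(evals[0], 0.0)
        evals = np.where(evals >= gram_cut, evals, 0.0)
        lam = np.sqrt(np.clip(evals, 0.0, None))
    elif method == "svd":
        U_full, lam, Vt = linalg.svd(X, full_matrices=False)
        V = Vt.T
    else:
        raise ParameterError(f"unknown decomposition method {method!r}")
    if lam[0] <= 0.0:
        raise DegenerateDesignError("design matrix is all-zero (rank 0)")
    keep = lam >= truncation_tol * lam[0]
    r = int(np.count_nonzero(keep))
    lam = np.ascontiguousarray(lam[:r])
    V = np.ascontiguousarray(V[:, :r])
    if method == "gram":
        U = (X @ V) / lam
    else:
        U = np.ascontiguousarray(U_full[:, :r])
    logger.info("decomposed %dx%d design: rank %d (tol %.3g)", d, p, r, truncation_tol)
    return DesignDecomposition(
        singular_values=lam,
        right_rotation=V,
        target_projector=U,
        rank=r,
        truncation_tol=float(truncation_tol),
    )


def rotate_target(dec: DesignDecomposition, y: np.ndarray) -> RotatedTarget:
    """Project a target into the reduced space and solve OLS there.

    ``y_rot = U^T y`` and ``beta_ols_rot[i] = y_rot[i] / lambda_i``; the OLS
    problem reduces to one elementwise division.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != dec.target_projector.shape[0]:
        raise DimensionError(
            f"target has shape {y.shape}, expected ({dec.target_projector.shape[0]},)"
        )
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("target contains non-finite entries")
    y_rot = dec.project_targets(y)
    beta = y_rot / dec.singular_values
    return RotatedTarget(y_rot=y_rot, beta_ols_rot=beta, ols_norm=float(np.linalg.norm(beta)))


def build_alpha_grid(
    dec: DesignDecomposition, log_spacing: float = DEFAULT_LOG_SPACING
) -> AlphaGrid:
    """Construct the internal log-spaced candidate alpha grid.

    Spans ``[1e-3 * lambda_r**2, 1e3 * lambda_1**2]`` — from penalties far
    too small to shrink even the weakest retained component, to penalties
    that shrink even the strongest essentially to zero — with endpoints
    snapped outward onto integer multiples of ``log_spacing`` (in log10) so
    the lattice is deterministic for a given singular-value range.
    """
    if not np.isfinite(log_spacing) or log_spacing <= 0:
        raise ParameterError(f"log_spacing must be positive, got {log_spacing}")
    lam = dec.singular_values
    lo_target = np.log10(1e-3 * lam[-1] ** 2)
    hi_target = np.log10(1e3 * lam[0] ** 2)
    # snap outward; the 1e-9 guard keeps exact lattice multiples from
    # drifting one full step under floating-point division
    lo = np.floor(lo_target / log_spacing + 1e-9) * log_spacing
    hi = np.ceil(hi_target / log_spacing - 1e-9) * log_spacing
    n = int(round((hi - lo) / log_spacing)) + 1
    alphas = 10.0 ** (lo + log_spacing * np.arange(n))
    return AlphaGrid(
        alphas=alphas, log_spacing=float(log_spacing), lo_exponent=float(lo), hi_exponent=float(hi)
    )


def shrinkage_factors(dec: DesignDecomposition, grid: AlphaGrid) -> ShrinkageTable:
    """Tabulate ``lambda_i^2 / (lambda_i^2 + alpha_j)`` as one outer operation.

    The table depends only on the design (not on any target), so it is
    computed once and reused across all targets.
    """
    lam2 = dec.singular_values[:, None] ** 2
    return ShrinkageTable(factors=lam2 / (lam2 + grid.alphas[None, :]))


def gamma_curve(target: RotatedTarget, table: ShrinkageTable) -> np.ndarray:
    """Achieved fraction gamma at every grid alpha for one target.

    ``gamma_j = ||SF[:, j] * beta_ols_rot||_2 / ||beta_ols_rot||_2``.
    Strictly decreasing along the grid (every component shrinks strictly
    as alpha grows).
    """
    if target.ols_norm == 0.0:
        raise ZeroNormTargetError("target has zero-norm OLS solution; gamma is undefined")
    shrunk = table.factors * target.beta_ols_rot[:, None]
    return np.linalg.norm(shrunk, axis=0) / target.ols_norm


def interpolate_alphas(
    gammas_on_grid: np.ndarray, grid: AlphaGrid, requested: np.ndarray
) -> np.ndarray:
    """Find the alpha achieving each requested fraction by interpolation.

    Piecewise-linear interpolation of ``log10(alpha)`` as a function of the
    achieved gamma (gamma varies smoothly and near-linearly in log alpha
    over the shrinkage transition, so the 0.2-log10 grid suffices for ~1%
    fraction accuracy).  Endpoints bypass interpolation: gamma=1 maps to
    alpha=0 exactly and gamma=0 to the +inf sentinel.  A requested gamma
    above the largest grid-achieved gamma (possible because the grid's
    minimum alpha is positive) is linearly extrapolated; exponentiation
    keeps the result non-negative.
    """
    g = np.asarray(gammas_on_grid, dtype=float)
    if g.shape != grid.alphas.shape:
        raise DimensionError("gamma curve and alpha grid have mismatched lengths")
    diffs = np.diff(g)
    if np.any(diffs > 0):
        raise InternalConsistencyError("gamma curve is not monotonically decreasing")
    req = np.atleast_1d(np.asarray(requested, dtype=float))
    if np.any(~np.isfinite(req)) or np.any((req < 0) | (req > 1)):
        raise ParameterError("requested fractions must lie in [0, 1]")
    log_alpha = np.log10(grid.alphas)
    # ascending-gamma view; collapse exact float ties (curve can saturate
    # to 1.0 at the small-alpha end), keeping the smallest alpha per gamma
    g_asc = g[::-1]
    la_asc = log_alpha[::-1]
    uniq_mask = np.ones(g_asc.shape, dtype=bool)
    uniq_mask[:-1] = np.diff(g_asc) > 0
    g_asc = g_asc[uniq_mask]
    la_asc = la_asc[uniq_mask]
    if g_asc.size < 2:
        raise InternalConsistencyError("gamma curve is degenerate (constant)")
    la = np.interp(req, g_asc, la_asc)
    hi_mask = req > g_asc[-1]
    if np.any(hi_mask):
        slope = (la_asc[-1] - la_asc[-2]) / (g_asc[-1] - g_asc[-2])
        la[hi_mask] = la_asc[-1] + slope * (req[hi_mask] - g_asc[-1])
    lo_mask = req < g_asc[0]
    if np.any(lo_mask):
        slope = (la_asc[1] - la_asc[0]) / (g_asc[1] - g_asc[0])
        la[lo_mask] = la_asc[0] + slope * (req[lo_mask] - g_asc[0])
    alphas_star = 10.0**la
    alphas_star[req == 1.0] = 0.0
    alphas_star[req == 0.0] = np.inf
    return alphas_star


def solve_target(
    target: RotatedTarget, dec: DesignDecomposition, alphas_star: np.ndarray
) -> np.ndarray:
    """Ridge solutions in rotated space for one target at several penalties.

    ``beta_rr_i = lambda_i^2 / (lambda_i^2 + alpha) * beta_ols_i`` — each
    ridge solution is a componentwise scaled-down copy of the OLS solution.
    alpha=0 reproduces OLS exactly; the +inf sentinel yields zeros.
    """
    a = np.atleast_1d(np.asarray(alphas_star, dtype=float))
    if np.any(np.isnan(a)) or np.any(a < 0):
        raise ParameterError("alphas must be >= 0 (inf sentinel allowed)")
    lam2 = dec.singular_values[:, None] ** 2
    sf = lam2 / (lam2 + a[None, :])  # inf -> 0.0, 0 -> 1.0 exactly
    return sf * target.beta_ols_rot[:, None]


def unrotate(dec: DesignDecomposition, beta_rot: np.ndarray) -> np.ndarray:
    """Rotate coefficients back to predictor space: ``beta = V @ beta_rot``.

    V has orthonormal columns, so column L2-norms — and therefore achieved
    fractions — are preserved.
    """
    beta_rot = np.asarray(beta_rot, dtype=float)
    rows = beta_rot.shape[0]
    if rows != dec.rank:
        raise DimensionError(f"expected {dec.rank} rotated rows, got {rows}")
    return dec.right_rotation @ beta_rot


def frr(
    X: np.ndarray,
    Y: np.ndarray,
    fractions,
    *,
    truncation_tol: float | None = None,
    log_spacing: float = DEFAULT_LOG_SPACING,
    method: str = "auto",
) -> FRRSolution:
    """Fractional ridge regression over many targets.

    Parameters
    ----------
    X : ndarray, shape (d, p)
        Design matrix.
    Y : ndarray, shape (d, t) or (d,)
        Target matrix (columns are targets) or a single target vector.
    fractions : sequence of float in [0, 1]
        Requested coefficient-norm fractions.  Deduplicated and sorted
        internally; the output follows the caller's original order.
    truncation_tol, log_spacing, method
        Passed through to :func:`decompose_design` / :func:`build_alpha_grid`.

    Returns
    -------
    FRRSolution
        Coefficients (p, f, t), the per-target alphas achieving each
        fraction, and the fractions actually achieved.

    Notes
    -----
    One SVD and one back-rotation serve all targets; the per-target work is
    a vectorized gamma-curve evaluation plus a 1-D interpolation.  Targets
    whose OLS solution is exactly zero get zero coefficients at every
    fraction, with NaN recorded for alpha and achieved fraction (any
    penalty yields the same zero solution, so gamma is 0/0).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise DimensionError(
            f"X has {X.shape[0]} rows but Y has shape {Y.shape}; row counts must match"
        )
    if not np.all(np.isfinite(Y)):
        raise InvalidInputError("target matrix contains non-finite entries")
    fr_req = np.atleast_1d(np.asarray(fractions, dtype=float))
    if fr_req.ndim != 1 or fr_req.size == 0:
        raise ParameterError("fractions must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(fr_req)) or np.any((fr_req < 0) | (fr_req > 1)):
        raise ParameterError("fractions must lie in [0, 1]")

    dec = decompose_design(X, truncation_tol=truncation_tol, method=method)
    p = X.shape[1]
    t = Y.shape[1]
    uniq = np.unique(fr_req)
    f_u = uniq.size

    if t == 0:
        empty = np.zeros((p, fr_req.size, 0))
        return FRRSolution(fr_req, empty, np.zeros((fr_req.size, 0)), np.zeros((fr_req.size, 0)))

    Y_rot = dec.project_targets(Y)
    lam = dec.singular_values
    B_ols = Y_rot / lam[:, None]
    ols_norms = np.linalg.norm(B_ols, axis=0)

    grid = build_alpha_grid(dec, log_spacing=log_spacing)
    table = shrinkage_factors(dec, grid)
    logger.info("alpha grid: %d points in [1e%.1f, 1e%.1f]", grid.alphas.size,
                grid.lo_exponent, grid.hi_exponent)

    B_rot = np.zeros((dec.rank, f_u, t))
    alphas = np.full((f_u, t), np.nan)
    for k in range(t):
        if ols_norms[k] == 0.0:
            continue  # degenerate target: zeros, NaN bookkeeping
        tgt = RotatedTarget(Y_rot[:, k], B_ols[:, k], float(ols_norms[k]))
        g = gamma_curve(tgt, table)
        a_star = interpolate_alphas(g, grid, uniq)
        alphas[:, k] = a_star
        B_rot[:, :, k] = solve_target(tgt, dec, a_star)

    with np.errstate(invalid="ignore", divide="ignore"):
        achieved = np.linalg.norm(B_rot, axis=0) / ols_norms[None, :]
    achieved[:, ols_norms == 0.0] = np.nan

    coefs = unrotate(dec, B_rot.reshape(dec.rank, -1)).reshape(p, f_u, t)

    # restore the caller's original fraction order
    idx = np.searchsorted(uniq, fr_req)
    return FRRSolution(
        fractions=fr_req,
        coefs=coefs[:, idx, :],
        alphas=alphas[idx, :],
        achieved_fractions=achieved[idx, :],
    )


def ridge_direct(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge regression by direct normal-equations solve (test oracle).

    ``beta = (X^T X + alpha I)^{-1} X^T y``.  At alpha=0 with a
    rank-deficient design the inverse does not exist and the Moore-Penrose
    pseudoinverse solution is returned instead (a warning is logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(alpha) or alpha < 0:
        raise ParameterError(f"alpha must be finite and >= 0, got {alpha}")
    if y.shape[0] != X.shape[0]:
        raise DimensionError("X and y row counts must match")
    p = X.shape[1]
    if alpha == 0.0:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < p:
            logger.warning(
                "alpha=0 on a rank-deficient design (rank %d < %d); pseudoinverse used",
                rank, p,
            )
        return beta
    A = X.T @ X + alpha * np.eye(p)
    return linalg.solve(A, X.T @ y, assume_a="pos")
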