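"""Synthetic regression scenarios and standard-ridge baselines.

The generator emulates the structure of encoding-model regression problems:
a Gaussian design with induced predictor correlations (repeatedly replacing
one of a random predictor pair with their sum plus noise, then z-scoring
columns), Gaussian ground-truth coefficients, and additive Gaussian noise
whose standard deviation can be matched per target to the standard
deviation of the noiseless signal.

Two standard-ridge (SRR) baselines are provided — a naive per-alpha
pseudo-inversion and a rotation-based solver that reuses one SVD across the
alpha grid — along with a comparison harness that fits FRR and SRR on the
same half-split problem and tabulates train/test R^2, fractional
coefficient norm, and effective degrees of freedom per regularization
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ParameterError, decompose_design, frr
from .model import DEFAULT_FRACTIONS, r2_score
from .theory import SpectrumSummary, effective_dof

__all__ = [
    "ScenarioSpec",
    "SRRGrid",
    "make_correlated_design",
    "simulate_targets",
    "srr_solve_naive",
    "srr_solve_rotated",
    "compare_frr_srr",
]

#: Named random streams derived from a scenario's single seed (splittable
#: generator: every consumer gets an independent, reproducible stream).
_STREAM_DESIGN = 0
_STREAM_TARGETS = 1


def _default_srr_alphas() -> np.ndarray:
    # 0 plus 10^-4 .. 10^5.5 in 0.5-log10 steps: 21 levels in total
    return np.concatenate([[0.0], 10.0 ** np.arange(-4.0, 5.5 + 1e-9, 0.5)])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic regression scenario.

    ``correlation_rounds`` defaults to ``2 * p``; ``noise_sd`` may be a
    positive number or the string ``"match-signal"``, in which case the
    noise standard deviation of each target equals the standard deviation
    of that target's noiseless signal.
    """

    d: int
    p: int
    correlation_rounds: int | None = None
    noise_sd: float | str = "match-signal"
    seed: int = 0
    beta_sd: float = 1.0

    def __post_init__(self):
        if self.d < 4 or self.p < 2:
            raise ParameterError(f"need d >= 4 and p >= 2, got d={self.d}, p={self.p}")
        if self.correlation_rounds is not None and self.correlation_rounds < 0:
            raise ParameterError("correlation_rounds must be >= 0")
        if isinstance(self.noise_sd, str):
            if self.noise_sd != "match-signal":
                raise ParameterError(f"unknown noise_sd spec {self.noise_sd!r}")
        elif self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.beta_sd <= 0:
            raise ParameterError("beta_sd must be positive")

    @property
    def rounds(self) -> int:
        return 2 * self.p if self.correlation_rounds is None else self.correlation_rounds


@dataclass(frozen=True)
class SRRGrid:
    """Heuristic standard-ridge alpha grid: 0, then log-spaced values."""

    alphas: np.ndarray = field(default_factory=_default_srr_alphas)


def _rng(spec: ScenarioSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,)))


def make_correlated_design(spec: ScenarioSpec) -> np.ndarray:
    """Correlated Gaussian design with z-scored columns.

    Starts from iid standard-normal entries; then, ``correlation_rounds``
    times, two distinct predictors are drawn at random and the first is
    replaced by their sum plus fresh standard-normal noise; finally every
    column is z-scored (population standard deviation, so the unit-SD
    invariant is exact).
    """
    rng = _rng(spec, _STREAM_DESIGN)
    X = rng.standard_normal((spec.d, spec.p))
    for _ in range(spec.rounds):
        i, j = rng.choice(spec.p, size=2, replace=False)
        X[:, i] = X[:, i] + X[:, j] + rng.standard_normal(spec.d)
    X = X - X.mean(axis=0)
    X = X / X.std(axis=0)
    return X


def simulate_targets(
    X: np.ndarray, spec: ScenarioSpec, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth coefficients and noisy targets for a given design.

    ``beta ~ Normal(0, beta_sd^2)`` per entry, ``Y = X beta + eps`` with
    iid Gaussian noise.  Under ``"match-signal"`` the noise SD of each
    target equals the population SD of its noiseless signal.
    """
    if t < 1:
        raise ParameterError(f"t must be >= 1, got {t}")
    rng = _rng(spec, _STREAM_TARGETS)
    beta = rng.standard_normal((spec.p, t)) * spec.beta_sd
    signal = X @ beta
    if spec.noise_sd == "match-signal":
        noise_scale = signal.std(axis=0)
    else:
        noise_scale = float(spec.noise_sd)
    eps = rng.standard_normal((X.shape[0], t)) * noise_scale
    return beta, signal + eps


def srr_solve_naive(X: np.ndarray, Y: np.ndarray, grid: SRRGrid | None = None) -> np.ndarray:
    """Standard ridge with an independent pseudo-inversion per alpha.

    Returns coefficients of shape (p, f, t).  Deliberately wasteful — it is
    the baseline the rotation-based solver is checked against.
    """
    if grid is None:
        grid = SRRGrid()
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    p = X.shape[1]
    XtX = X.T @ X
    XtY = X.T @ Y
    out = np.empty((p, grid.alphas.size, Y.shape[1]))
    for j, a in enumerate(grid.alphas):
        out[:, j, :] = np.linalg.pinv(XtX + a * np.eye(p)) @ XtY
    return out


def srr_solve_rotated(X: np.ndarray, Y: np.ndarray, grid: SRRGrid | None = None) -> np.ndarray:
    """Standard ridge via one SVD: rotate targets, scale per component
    by ``lambda_i / (lambda_i^2 + alpha)``, back-rotate once."""
    if grid is None:
        grid = SRRGrid()
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    dec = decompose_design(X)
    lam = dec.singular_values
    Y_rot = dec.project_targets(Y)  # (r, t)
    scale = lam[:, None] / (lam[:, None] ** 2 + grid.alphas[None, :])  # (r, f)
    B_rot = scale[:, :, None] * Y_rot[:, None, :]  # (r, f, t)
    r = dec.rank
    return (dec.right_rotation @ B_rot.reshape(r, -1)).reshape(
        X.shape[1], grid.alphas.size, Y.shape[1]
    )


def compare_frr_srr(
    spec: ScenarioSpec,
    t: int,
    frr_fractions=None,
    srr_grid: SRRGrid | None = None,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Fit FRR and SRR on the same half-split scenario; tabulate the paths.

    Generates the scenario, splits rows 50/50 (permutation seeded by
    ``split_seed``), fits both methods on the training half, and returns a
    tidy table with one row per (method, regularization level, target):
    ``method`` ("frr"/"srr"), ``level`` (requested gamma for FRR, alpha for
    SRR), ``train_r2``, ``test_r2``, ``frac_norm`` (coefficient norm
    relative to the training-half OLS norm), ``dof`` (effective degrees of
    freedom at the solution's alpha), and ``target_id``.
    """
    if frr_fractions is None:
        frr_fractions = DEFAULT_FRACTIONS
    frr_fractions = np.asarray(frr_fractions, dtype=float)
    if srr_grid is None:
        srr_grid = SRRGrid()

    X = make_correlated_design(spec)
    _, Y = simulate_targets(X, spec, t)
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(spec.d)
    half = spec.d // 2
    tr = np.sort(perm[:half])
    te = np.sort(perm[half:])
    Xtr, Ytr = X[tr], Y[tr]
    Xte, Yte = X[te], Y[te]

    sol = frr(Xtr, Ytr, frr_fractions)
    srr_coefs = srr_solve_rotated(Xtr, Ytr, srr_grid)
    beta_ols, *_ = np.linalg.lstsq(Xtr, Ytr, rcond=None)
    ols_norms = np.linalg.norm(beta_ols, axis=0)

    dec = decompose_design(Xtr)
    spectrum = SpectrumSummary(dec.singular_values, Xtr.shape[1])

    rows = []

    def add_rows(method, levels, coefs, alphas_for_dof):
        for j, level in enumerate(levels):
            for k in range(t):
                b = coefs[:, j, k]
                a = alphas_for_dof(j, k)
                rows.append(
                    {
                        "method": method,
                        "level": level,
                        "train_r2": r2_score(Ytr[:, k], Xtr @ b),
                        "test_r2": r2_score(Yte[:, k], Xte @ b),
                        "frac_norm": np.linalg.norm(b) / ols_norms[k],
                        "dof": np.nan if np.isnan(a) else effective_dof(spectrum, a)
                        if np.isfinite(a)
                        else 0.0,
                        "target_id": k,
                    }
                )

    add_rows("frr", sol.fractions, sol.coefs, lambda j, k: sol.alphas[j, k])
    add_rows("srr", srr_grid.alphas, srr_coefs, lambda j, k: srr_grid.alphas[j])
    return pd.DataFrame(rows)
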