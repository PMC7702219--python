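"""Closed-form ridge identities used as independent oracles.

When the singular-value spectrum of the design is flat (all values equal to
``lam``), the fraction achieved by penalty ``alpha`` collapses to
``gamma = lam**2 / (lam**2 + alpha)``, which inverts analytically to
``alpha = lam**2 * (1/gamma - 1)``.  These are never used as a fast path in
the solver; they exist to validate the general interpolation machinery.

The sum of the per-component shrinkages ``sum_i lam_i^2/(lam_i^2 + alpha)``
is the effective degrees of freedom of ridge regression: it decreases
monotonically from the design rank (no penalty) toward zero (infinite
penalty) and is a scale-free summary of regularization strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterError

__all__ = [
    "SpectrumSummary",
    "flat_spectrum_gamma",
    "flat_spectrum_alpha",
    "effective_dof",
    "l1_fraction_rotated",
]


@dataclass(frozen=True)
class SpectrumSummary:
    """Singular values (sorted non-increasing) and the predictor count p."""

    singular_values: np.ndarray
    p: int


def flat_spectrum_gamma(lam: float, alpha: float) -> float:
    """Fraction achieved by ``alpha`` on a flat-spectrum design."""
    if lam <= 0:
        raise ParameterError(f"lam must be positive, got {lam}")
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    return lam**2 / (lam**2 + alpha)


def flat_spectrum_alpha(lam: float, gamma: float) -> float:
    """Penalty achieving fraction ``gamma`` on a flat-spectrum design.

    Exact algebraic inverse of :func:`flat_spectrum_gamma` on (0, 1].
    ``gamma = 0`` would require an infinite penalty and raises.
    """
    if lam <= 0:
        raise ParameterError(f"lam must be positive, got {lam}")
    if gamma <= 0 or gamma > 1:
        raise ParameterError(f"gamma must lie in (0, 1], got {gamma}")
    return lam**2 * (1.0 / gamma - 1.0)


def effective_dof(spec: SpectrumSummary, alpha: float) -> float:
    """Effective degrees of freedom ``sum_i lam_i^2 / (lam_i^2 + alpha)``."""
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    lam2 = np.asarray(spec.singular_values, dtype=float) ** 2
    return float(np.sum(lam2 / (lam2 + alpha)))


def l1_fraction_rotated(spec: SpectrumSummary, alpha: float) -> float:
    """L1-norm shrinkage fraction in the special case of equal-magnitude
    rotated OLS coefficients: the average of the per-component shrinkages,
    ``effective_dof / p``.

    The L1-norm here refers to the rotated space; it need not equal the
    L1-norm fraction in the original predictor space.
    """
    return effective_dof(spec, alpha) / spec.p
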