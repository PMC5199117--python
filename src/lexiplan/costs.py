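"""Wish-list cost functions on per-voxel structure doses.

All functions take a 1-D array of member-voxel doses (Gy) and are convex in
dose, so every optimization stage remains a convex program:

* ``ltcp`` — logarithmic tumor-control surrogate ``mean(exp(-alpha (d - Dp)))``,
  strictly decreasing in every voxel dose; driving it to its goal forces
  target coverage.
* ``geud`` — generalized equivalent uniform dose, the power mean
  ``(mean(d^k))^(1/k)``; k = 1 is the arithmetic mean, k -> inf the maximum.
  k < 1 is rejected (non-convex regime).
* ``mean_dose`` / ``max_dose`` — the linear special cases.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["ltcp", "log_ltcp", "geud", "mean_dose", "max_dose"]


def _check(dose: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float).ravel()
    if dose.size == 0:
        raise ValueError("structure is empty")
    return dose


def log_ltcp(dose, prescription_dose: float, alpha: float) -> float:
    """log of the LTCP; numerically stable via log-sum-exp."""
    dose = _check(dose)
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return float(logsumexp(-alpha * (dose - prescription_dose)) - np.log(dose.size))


def ltcp(dose, prescription_dose: float, alpha: float) -> float:
    """mean(exp(-alpha (d_i - D^p))): 1.0 at uniform D^p, 0.5 when every voxel
    exceeds D^p by ln(2)/alpha."""
    return float(np.exp(log_ltcp(dose, prescription_dose, alpha)))


def geud(dose, k: float) -> float:
    """Generalized EUD (power mean) with volume-effect exponent k >= 1."""
    dose = _check(dose)
    if k < 1:
        raise ValueError(f"volume-effect k must be >= 1, got {k}")
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if k == 1:
        return float(dose.mean())
    m = dose.max()
    if m == 0:
        return 0.0
    # factor out the max for overflow safety at large k
    return float(m * (np.mean((dose / m) ** k)) ** (1.0 / k))


def mean_dose(dose) -> float:
    return float(_check(dose).mean())


def max_dose(dose) -> float:
    return float(_check(dose).max())
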