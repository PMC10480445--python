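"""Shared statistical helpers: q-value FDR adjustment.

Storey's q-value with a smoothed null-proportion estimate is the default
(it reduces to Benjamini-Hochberg when pi0 is forced to 1); plain BH is
available via ``method="bh"``.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["qvalues", "estimate_pi0"]


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fitted with a cubic
    polynomial over the lambda grid and evaluated at the largest lambda,
    then clipped to (0, 1].  Small inputs fall back to pi0 = 1
    (conservative; equals BH).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        return 1.0
    pi0_lam = np.array(
        [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    if np.all(pi0_lam == 0):
        return 1.0 / m
    coef = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p, method: str = "storey", pi0: float | None = None) -> np.ndarray:
    """FDR-adjusted q-values, order-matching the input.

    Parameters
    ----------
    p : array-like of p-values in [0, 1].
    method : "storey" (smoothed pi0 estimate) or "bh" (pi0 = 1).
    pi0 : override the null-proportion estimate (must be in (0, 1]).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown method {method!r}")

    if pi0 is None:
        pi0 = 1.0 if method == "bh" else estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")

    # BH step-up via statsmodels, then scale by pi0
    _, q_bh, _, _ = multipletests(p, method="fdr_bh")
    q = np.minimum(pi0 * q_bh, 1.0)
    return q
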