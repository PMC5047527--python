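"""Multiple-testing primitives shared across the pipeline.

Both procedures are implemented from their step-up definitions so that they
can be verified exactly against brute-force oracles; ``storey_qvalues`` with
``pi0 = 1`` coincides with ``bh_adjust``.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike


def bh_adjust(p: ArrayLike) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values.

    For sorted p-values ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``padj_(i) = min_{j >= i} m * p_(j) / j``, capped at 1, returned in the
    original order.

    Parameters
    ----------
    p : array-like of float in [0, 1]

    Returns
    -------
    ndarray of adjusted p-values, same shape as ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def storey_pi0(p: ArrayLike, lam: float = 0.5) -> float:
    """Storey's null-proportion estimate at a single tuning point ``lam``.

    ``pi0_hat = #{p > lam} / (m * (1 - lam))``, capped at 1. The fixed-lambda
    form (no smoother) is robust at the few thousand tests this pipeline
    produces per sample.
    """
    p = np.asarray(p, dtype=float)
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    if p.size == 0:
        raise ValueError("empty p-value vector")
    pi0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(1.0, pi0))


def storey_qvalues(p: ArrayLike, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimate.

    ``q_(i) = min_{j >= i} pi0_hat * m * p_(j) / j`` over the sorted order;
    equals BH exactly when ``pi0_hat`` caps at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty one-dimensional vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = storey_pi0(p, lam=lam)
    return np.minimum(bh_adjust(p) * pi0, 1.0)
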