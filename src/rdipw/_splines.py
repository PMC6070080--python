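"""Restricted (natural) cubic spline bases, Harrell parameterisation."""

from __future__ import annotations

import numpy as np

__all__ = ["rcs_basis", "period_basis"]


def rcs_basis(x, knots) -> np.ndarray:
    """Nonlinear columns of a restricted cubic spline with the given knots.

    Returns an ``(n, k - 2)`` array for ``k`` knots; the linear term is not
    included. The basis is linear beyond the boundary knots and scaled by
    the squared knot span for numerical balance with the linear term.
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = t.size
    if k < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    if np.unique(t).size != k:
        raise ValueError("spline knots must be distinct")
    norm = (t[-1] - t[0]) ** 2

    def plus3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = []
    for j in range(k - 2):
        col = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(col / norm)
    return np.column_stack(cols)


def period_basis(periods, n_knots: int = 4) -> dict[str, np.ndarray]:
    """Smooth main effects of discrete time (period index).

    Uses a restricted cubic spline with ``n_knots`` knots at evenly spaced
    quantiles of the observed periods. When there are too few distinct
    periods for that, falls back to indicator columns (dropping the first
    period as reference), and to nothing at all for a single period.
    """
    p = np.asarray(periods, dtype=float)
    distinct = np.unique(p)
    out: dict[str, np.ndarray] = {}
    if distinct.size <= 1:
        return out
    if distinct.size <= 2 * n_knots:
        for v in distinct[1:]:
            out[f"period_{int(v)}"] = (p == v).astype(float)
        return out
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(p, qs))
    out["period_lin"] = p
    if knots.size >= 3:
        nl = rcs_basis(p, knots)
        for j in range(nl.shape[1]):
            out[f"period_rcs{j + 1}"] = nl[:, j]
    return out
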