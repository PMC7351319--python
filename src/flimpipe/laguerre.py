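"""Discrete-time Laguerre function basis for decay deconvolution.

The functions are generated by the standard two-term recurrence

    l_0[k] = sqrt(1 - a) * a^(k/2)
    l_j[k] = sqrt(a) l_j[k-1] + sqrt(a) l_{j-1}[k] - l_{j-1}[k-1]

which is orthonormal on the half line.  On a finite grid the truncated
functions are re-orthonormalized with a QR factorization (the span is
unchanged; the correction is a small rotation whenever the grid is long
enough for the envelope to decay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LaguerreBasis", "build_laguerre_basis", "laguerre_recurrence", "alpha_for_envelope"]


def laguerre_recurrence(order: int, alpha: float, n_samples: int) -> np.ndarray:
    """Raw (un-reorthonormalized) discrete Laguerre functions, shape (n, order)."""
    sa = np.sqrt(alpha)
    out = np.zeros((n_samples, order))
    out[:, 0] = np.sqrt(1.0 - alpha) * sa ** np.arange(n_samples)
    for j in range(1, order):
        prev = out[:, j - 1]
        cur = out[:, j]
        cur[0] = sa * prev[0]
        for k in range(1, n_samples):
            cur[k] = sa * cur[k - 1] + sa * prev[k] - prev[k - 1]
    return out


def alpha_for_envelope(tau_env: float, dt: float) -> float:
    """Laguerre scale whose geometric envelope a^(k/2) decays with time
    constant ``tau_env`` (ns) on a grid with spacing ``dt`` (ns)."""
    if tau_env <= 0:
        raise ValueError("tau_env must be positive")
    return float(np.exp(-2.0 * dt / tau_env))


@dataclass(frozen=True)
class LaguerreBasis:
    """Orthonormal Laguerre basis sampled on ``n_samples`` points.

    ``basis`` has shape (n_samples, order); columns are orthonormal with
    Gram deviation below 1e-8.
    """

    order: int
    alpha: float
    basis: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.basis.shape[0]

    def gram_deviation(self) -> float:
        g = self.basis.T @ self.basis
        return float(np.abs(g - np.eye(self.order)).max())


def build_laguerre_basis(
    order: int,
    alpha: float,
    n_samples: int,
    max_raw_deviation: float = 0.1,
) -> LaguerreBasis:
    """Build an orthonormal Laguerre basis on a finite grid.

    Raises
    ------
    ValueError
        If ``alpha`` is outside (0, 1), ``order`` < 1, or the functions
        have not decayed on ``n_samples`` points (raw Gram deviation above
        ``max_raw_deviation``), in which case a longer grid or smaller
        alpha is required.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if order < 1:
        raise ValueError("order must be >= 1")
    if n_samples < order:
        raise ValueError("n_samples must be at least the basis order")
    raw = laguerre_recurrence(order, alpha, n_samples)
    gram = raw.T @ raw
    dev = float(np.abs(gram - np.eye(order)).max())
    if dev > max_raw_deviation:
        raise ValueError(
            f"Laguerre functions (order={order}, alpha={alpha}) do not decay "
            f"within {n_samples} samples (Gram deviation {dev:.3g}); increase "
            "n_samples or reduce alpha"
        )
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # keep the leading-sample sign convention
    return LaguerreBasis(order=order, alpha=alpha, basis=q)
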