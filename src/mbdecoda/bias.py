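"""Minimum coverage interval (MCI) estimation of the compositional bias.

Because the sample offsets ``d_i`` and the effects ``Delta_k`` are
confounded along the variable of interest, every fitted effect
``Delta_tilde_k`` carries the same unknown additive bias ``gamma``.  Under
a sparse-signal assumption the null taxa cluster around ``gamma``, so the
shortest window of ``m = ceil(rho * K)`` sorted estimates locates that
cluster; its mean estimates the bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class BiasCorrection:
    """MCI window and the resulting bias estimate.

    ``member_indices`` index into the original (unsorted) ``Delta_tilde``
    vector and have exactly ``window_size`` elements; the interval
    endpoints are order statistics of the input and are themselves members.
    """

    rho: float
    window_size: int
    member_indices: np.ndarray
    interval: tuple[float, float]
    gamma_hat: float
    var_gamma_hat: float


def _window_size(n_values: int, rho: float) -> int:
    # guard against float fuzz in rho * K (e.g. 0.3 * 10 = 3.0000000000000004)
    return int(math.ceil(round(rho * n_values, 9)))


def mci(Delta_tilde: np.ndarray, rho: float = 0.5) -> BiasCorrection:
    """Find the shortest window of ``ceil(rho*K)`` sorted effect estimates.

    Non-finite entries (non-estimable taxa) are ignored.  Among windows of
    equal minimal width the left-most is chosen, making the output
    deterministic.  The returned ``gamma_hat`` is the window mean and
    ``var_gamma_hat`` the within-window mean squared deviation.
    """
    Delta_tilde = np.asarray(Delta_tilde, dtype=float).ravel()
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    finite = np.isfinite(Delta_tilde)
    idx = np.flatnonzero(finite)
    values = Delta_tilde[finite]
    K = values.size
    if K < 3:
        raise ValueError(f"need at least 3 finite effect estimates, got {K}")
    m = _window_size(K, rho)
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    widths = sorted_vals[m - 1 :] - sorted_vals[: K - m + 1]
    j_star = int(np.argmin(widths))  # argmin takes the smallest index on ties
    members_sorted = order[j_star : j_star + m]
    member_indices = np.sort(idx[members_sorted])
    window = sorted_vals[j_star : j_star + m]
    gamma_hat = float(window.mean())
    var_gamma_hat = float(np.mean((window - gamma_hat) ** 2))
    return BiasCorrection(
        rho=rho,
        window_size=m,
        member_indices=member_indices,
        interval=(float(sorted_vals[j_star]), float(sorted_vals[j_star + m - 1])),
        gamma_hat=gamma_hat,
        var_gamma_hat=var_gamma_hat,
    )


def debias(Delta_tilde: np.ndarray, bc: BiasCorrection) -> np.ndarray:
    """Subtract the estimated bias: ``Delta_hat = Delta_tilde - gamma_hat``.

    Non-finite entries stay non-finite.
    """
    return np.asarray(Delta_tilde, dtype=float) - bc.gamma_hat
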