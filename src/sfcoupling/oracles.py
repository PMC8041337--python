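"""Analytic VAR oracles for validating the nonparametric pipeline.

These closed-form quantities — the spectral matrix, cross-covariance
sequence and parametric Geweke causality of a known stable VAR — serve
as independent references in tests and acceptance checks.  They are
not part of the analysis pipeline: the pipeline itself never fits an
autoregressive model.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .synthetic import var_companion

__all__ = [
    "var_transfer",
    "var_spectral_matrix",
    "var_cross_covariance",
    "parametric_gc",
]


def var_transfer(coeffs: np.ndarray, freqs: np.ndarray,
                 fs: float) -> np.ndarray:
    """H(f) = A(f)^-1 with A(f) = I - sum_m A_m exp(-2 pi i f (m+1) / fs)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    A = np.tile(np.eye(k, dtype=complex), (freqs.size, 1, 1))
    for m in range(p):
        A -= z[:, m, None, None] * coeffs[m]
    return np.linalg.inv(A)


def var_spectral_matrix(coeffs: np.ndarray, noise_cov: np.ndarray,
                        freqs: np.ndarray, fs: float,
                        onesided: bool = True) -> np.ndarray:
    """Analytic CSD of a stable VAR on the given frequency grid.

    ``S(f) = H(f) Sigma H(f)^H / fs`` (per-Hz two-sided density),
    doubled at interior bins when ``onesided`` to match the scaling of
    :func:`sfcoupling.spectral.compute_csd`.
    """
    H = var_transfer(coeffs, freqs, fs)
    S = H @ np.asarray(noise_cov, dtype=float) @ np.conj(
        np.swapaxes(H, 1, 2)
    ) / fs
    if onesided:
        freqs = np.asarray(freqs, dtype=float)
        scale = np.full(freqs.size, 2.0)
        scale[np.isclose(freqs, 0.0)] = 1.0
        scale[np.isclose(freqs, fs / 2.0)] = 1.0
        S = S * scale[:, None, None]
    return S


def var_cross_covariance(coeffs: np.ndarray, noise_cov: np.ndarray,
                         max_lag: int) -> np.ndarray:
    """Cross-covariance Gamma(h) = Cov(x_t, x_{t-h}) for h = 0..max_lag.

    Computed from the companion-form stationary covariance (discrete
    Lyapunov equation), then propagated by Gamma(h) = A_comp Gamma(h-1)
    in companion space.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    comp = var_companion(coeffs)
    Q = np.zeros_like(comp)
    Q[:k, :k] = np.asarray(noise_cov, dtype=float)
    big = solve_discrete_lyapunov(comp, Q)
    out = np.zeros((max_lag + 1, k, k))
    cur = big
    out[0] = big[:k, :k]
    for h in range(1, max_lag + 1):
        cur = comp @ cur
        out[h] = cur[:k, :k]
    return out


def parametric_gc(coeffs: np.ndarray, noise_cov: np.ndarray,
                  freqs: np.ndarray, fs: float) -> tuple:
    """Geweke spectral causality of a known bivariate VAR.

    Returns (gc_xy, gc_yx): spectra for directions channel0 -> channel1
    and channel1 -> channel0, computed from the true transfer function
    and innovation covariance.
    """
    Sigma = np.asarray(noise_cov, dtype=float)
    if Sigma.shape != (2, 2):
        raise ValueError("parametric_gc is defined for bivariate VARs")
    H = var_transfer(coeffs, freqs, fs)
    S = np.real(H @ Sigma @ np.conj(np.swapaxes(H, 1, 2)))

    def one(x, y):
        partial = Sigma[y, y] - Sigma[x, y] ** 2 / Sigma[x, x]
        denom = S[:, x, x] - partial * np.abs(H[:, x, y]) ** 2
        return np.log(S[:, x, x] / denom)

    gc_xy = one(x=1, y=0)  # 0 -> 1
    gc_yx = one(x=0, y=1)  # 1 -> 0
    return gc_xy, gc_yx
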