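"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package:
arbitrary-precision series evaluation for the slab transmittance, a
closed-form exponentially-modified Gaussian for IRF convolution, a
brute-force local least-squares solve for Savitzky-Golay weights, and a
covariance eigendecomposition for PCA loadings.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np


def transmittance_oracle(
    t: float,
    mu_a: float,
    mu_s: float,
    s: float,
    rho: float = 0.0,
    n: float = 1.34,
    A: float = 2.58,
    max_m: int = 50,
    dps: int = 50,
) -> float:
    """Arbitrary-precision slab transmittance, series truncated at |m| <= max_m."""
    with mp.workdps(dps):
        mu_a_, mu_s_, s_, rho_, t_ = (mp.mpf(repr(x)) for x in (mu_a, mu_s, s, rho, t))
        v = mp.mpf("0.299792458") / mp.mpf(repr(n))
        D = 1 / (3 * mu_s_)
        z0 = 1 / mu_s_
        ze = 2 * mp.mpf(repr(A)) * D
        denom = 4 * D * v * t_
        total = mp.mpf(0)
        for m in range(-max_m, max_m + 1):
            z1 = s_ * (1 - 2 * m) - 4 * m * ze - z0
            z2 = s_ * (1 - 2 * m) - (4 * m - 2) * ze + z0
            total += z1 * mp.e ** (-(z1**2) / denom) - z2 * mp.e ** (-(z2**2) / denom)
        pref = mp.e ** (-mu_a_ * v * t_ - rho_**2 / denom) / (
            2 * (4 * mp.pi * D * v) ** mp.mpf("1.5") * t_ ** mp.mpf("2.5")
        )
        return float(abs(pref * total))


def emg_curve(t: np.ndarray, lam: float, mu: float, sigma: float) -> np.ndarray:
    """Closed-form Gaussian(mu, sigma) convolved with exp(-lam*t)*H(t).

    h(t) = (1/2) exp(lam^2 sigma^2/2 - lam (t - mu))
           * erfc((mu + lam sigma^2 - t) / (sigma sqrt(2)))
    """
    from scipy.special import erfc

    arg = (mu + lam * sigma**2 - t) / (sigma * np.sqrt(2.0))
    return 0.5 * np.exp(lam**2 * sigma**2 / 2.0 - lam * (t - mu)) * erfc(arg)


def savgol_weights_bruteforce(poly_order: int, frame_length: int) -> np.ndarray:
    """Central-point SG weights from the local least-squares normal equations."""
    half = frame_length // 2
    x = np.arange(-half, half + 1, dtype=float)
    A = np.vander(x, poly_order + 1, increasing=True)
    # fitted value at x=0 is the first row of the hat matrix's center row
    hat = A @ np.linalg.solve(A.T @ A, A.T)
    return hat[half]


def pca_loadings_bruteforce(X: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the sample covariance matrix, rows, descending."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order].T
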