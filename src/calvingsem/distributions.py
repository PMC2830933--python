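"""Sampling kernels used by the Gibbs sampler.

Vectorized truncated-normal draws (inverse-CDF with tail guards), scaled
inverse chi-square draws, and the fixed-corner conditional inverted-Wishart
sampler needed for an unstructured residual matrix whose SB diagonal entry
is pinned to 1.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import wishart


def truncated_normal(mean, sd, lower, upper, rng: np.random.Generator):
    """Draws from N(mean, sd^2) truncated to (lower, upper), vectorized.

    Bounds may be -inf/inf.  Uses the inverse-CDF method on the standardized
    scale; when the interval lies so far in a tail that both CDF values
    round to the same double, the draw falls back to the nearer finite
    bound (the conditional distribution is then numerically degenerate).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    shape = np.broadcast_shapes(mean.shape, sd.shape, lower.shape, upper.shape)
    a = np.broadcast_to((lower - mean) / sd, shape)
    b = np.broadcast_to((upper - mean) / sd, shape)
    fa = ndtr(a)
    fb = ndtr(b)
    u = rng.uniform(size=shape)
    p = fa + u * (fb - fa)
    z = ndtri(np.clip(p, 1e-300, 1.0 - 1e-16))
    # degenerate interval in a far tail: clamp to the interval
    z = np.minimum(np.maximum(z, a), b)
    bad = ~np.isfinite(z)
    if np.any(bad):
        z = np.where(bad, np.where(np.isfinite(a), a, b), z)
    out = np.broadcast_to(mean, shape) + np.broadcast_to(sd, shape) * z
    return out if shape else float(out)


def scaled_inv_chi2(nu: float, s2: float, rng: np.random.Generator) -> float:
    """One draw from Scale-inv-chi2(nu, s2), i.e. nu*s2 / chi2_nu."""
    return float(nu * s2 / rng.chisquare(nu))


def sample_invwishart(df: float, scale: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Inverted-Wishart draw, density |S|^{-(df+p+1)/2} exp(-tr(scale S^-1)/2)."""
    scale = np.asarray(scale, dtype=float)
    omega = wishart.rvs(df=df, scale=np.linalg.inv(scale), random_state=rng)
    omega = np.atleast_2d(omega)
    return np.linalg.inv(omega)


def sample_cond_invwishart_fixed_corner(df: float, scale: np.ndarray,
                                        corner: float,
                                        rng: np.random.Generator) -> np.ndarray:
    """Draw Sigma ~ IW(df, scale) conditional on Sigma[-1, -1] = corner.

    Works on the precision Omega = Sigma^{-1} ~ Wishart(df, scale^{-1}).
    Partition Omega with block a = all indices but the last and block b =
    the last.  By the Wishart partition theorem, Omega_aa ~ W(df, Psi_aa),
    Omega_ba | Omega_aa is (matrix) normal, and the Schur complement
    Omega_bb.a ~ W_1(df - p + 1, psi_bb.a) independent of both.  Since
    Sigma[-1, -1] = 1 / Omega_bb.a, conditioning simply fixes the Schur
    complement at 1/corner and leaves the other two components at their
    unconditional laws.
    """
    scale = np.asarray(scale, dtype=float)
    p = scale.shape[0]
    psi = np.linalg.inv(scale)
    psi_aa = psi[:p - 1, :p - 1]
    psi_ba = psi[p - 1, :p - 1]
    psi_bb = psi[p - 1, p - 1]
    psi_aa_inv = np.linalg.inv(psi_aa)
    psi_bb_a = psi_bb - psi_ba @ psi_aa_inv @ psi_ba
    if psi_bb_a <= 0:
        raise ValueError("scale matrix is not positive definite")

    omega_aa = np.atleast_2d(wishart.rvs(df=df, scale=psi_aa, random_state=rng))
    # Omega_ba | Omega_aa ~ N(psi_ba psi_aa^-1 Omega_aa, psi_bb.a * Omega_aa)
    mean_ba = psi_ba @ psi_aa_inv @ omega_aa
    chol = np.linalg.cholesky(omega_aa)
    omega_ba = mean_ba + np.sqrt(psi_bb_a) * (chol @ rng.standard_normal(p - 1))
    omega_bb = 1.0 / corner + omega_ba @ np.linalg.solve(omega_aa, omega_ba)

    omega = np.empty((p, p))
    omega[:p - 1, :p - 1] = omega_aa
    omega[p - 1, :p - 1] = omega_ba
    omega[:p - 1, p - 1] = omega_ba
    omega[p - 1, p - 1] = omega_bb
    sigma = np.linalg.inv(omega)
    sigma = 0.5 * (sigma + sigma.T)
    sigma[p - 1, p - 1] = corner  # exact, not just to round-off
    return sigma


def sample_mvn_from_precision(precision: np.ndarray, linear: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Draw from N(precision^{-1} linear, precision^{-1}) via Cholesky."""
    chol = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, linear)
    z = rng.standard_normal(precision.shape[0])
    # solve L' x = z gives covariance precision^{-1}
    return mean + np.linalg.solve(chol.T, z)
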