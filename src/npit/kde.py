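"""Kernel-density plug-in estimators.

A multivariate Gaussian kernel is placed on every sample point; the kernel
shape is the sample covariance scaled by the square of Silverman's
rule-of-thumb bandwidth h = (n(d+2)/4)^(-1/(d+4)).  Entropy, KL divergence
and mutual information are then obtained either by resubstitution (the mean
log-density over the sample points themselves) or by adaptive numerical
integration of the estimated density ("integral" mode).

Integral mode is limited to d <= 2: quadrature over a kernel sum becomes
prohibitively expensive in higher dimensions.  Its integration limits are
the per-dimension sample range widened by one bandwidth on each side, which
intentionally truncates the Gaussian tails on bounded-support data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.linalg import solve_triangular

__all__ = [
    "KDEModel",
    "silverman_bandwidth",
    "kde_fit",
    "kde_eval",
    "kde_entropy",
    "kde_kl",
    "kde_mi",
    "integration_box",
    "EstimationCostError",
]

#: resubstitution cost ceiling (kernel sums are O(n^2))
MAX_N_RESUBSTITUTION = 25_000
#: integral-mode cost ceiling
MAX_N_INTEGRAL = 10_000
_INTEGRAL_TOL = 1.49e-8
_EVAL_CHUNK = 1024

_MODES = ("resubstitution", "integral")


class EstimationCostError(RuntimeError):
    """The requested evaluation exceeds a configured cost ceiling."""


def silverman_bandwidth(n: int, d: int) -> float:
    """Silverman's rule-of-thumb smoothing multiplier (n(d+2)/4)^(-1/(d+4))."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return float((n * (d + 2) / 4.0) ** (-1.0 / (d + 4)))


@dataclass(frozen=True)
class KDEModel:
    """Fitted kernel density: retained sample, its covariance and bandwidth."""

    points: np.ndarray  # (n, d)
    cov: np.ndarray  # (d, d), unbiased sample covariance
    bandwidth: float

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def _as_matrix(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"sample must be an (n, d) matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite entries")
    return arr


def kde_fit(sample) -> KDEModel:
    """Fit the Gaussian-kernel density to an (n, d) sample."""
    pts = _as_matrix(sample)
    n, d = pts.shape
    if n < 2:
        raise ValueError(f"KDE requires at least 2 points, got {n}")
    variances = pts.var(axis=0, ddof=1)
    zero = np.flatnonzero(variances == 0.0)
    if zero.size:
        raise ValueError(
            f"sample covariance is singular: dimension(s) {zero.tolist()} are constant"
        )
    cov = np.cov(pts, rowvar=False, ddof=1).reshape(d, d)
    # a constant column is the common failure; anything else singular is
    # caught by the Cholesky factorization at evaluation time
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sample covariance is singular (collinear columns)") from exc
    return KDEModel(points=pts, cov=cov, bandwidth=silverman_bandwidth(n, d))


def kde_eval(model: KDEModel, points) -> np.ndarray:
    """Evaluate the fitted density at each row of `points`.

    p(x) = (1/n) sum_i (2 pi)^(-d/2) h^(-d) det(S)^(-1/2) exp(-u_i/2),
    u_i = (x - x_i)' S^{-1} (x - x_i) / h^2.
    """
    query = _as_matrix(points)
    if query.shape[1] != model.dim:
        raise ValueError(
            f"query dimension {query.shape[1]} does not match model dimension {model.dim}"
        )
    n, d = model.n, model.dim
    h = model.bandwidth
    chol = np.linalg.cholesky(model.cov)
    # whiten so that squared Euclidean distance equals the Mahalanobis form
    white_ref = solve_triangular(chol, model.points.T, lower=True).T / h
    white_q = solve_triangular(chol, query.T, lower=True).T / h
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    log_norm = -0.5 * d * math.log(2.0 * math.pi) - d * math.log(h) - 0.5 * logdet

    ref_sq = np.einsum("ij,ij->i", white_ref, white_ref)
    out = np.empty(white_q.shape[0])
    for start in range(0, white_q.shape[0], _EVAL_CHUNK):
        block = white_q[start : start + _EVAL_CHUNK]
        d2 = (
            np.einsum("ij,ij->i", block, block)[:, None]
            - 2.0 * block @ white_ref.T
            + ref_sq[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        out[start : start + _EVAL_CHUNK] = np.exp(-0.5 * d2).mean(axis=1)
    return out * math.exp(log_norm)


def integration_box(sample, h: float) -> list[tuple[float, float]]:
    """Per-dimension [min - h, max + h] integration limits."""
    pts = _as_matrix(sample)
    lo = pts.min(axis=0) - h
    hi = pts.max(axis=0) + h
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def _check_cost(n: int, d: int, mode: str, max_n: int | None) -> None:
    if mode == "integral":
        if d > 2:
            raise EstimationCostError(
                f"integral-mode KDE is limited to d <= 2 (got d={d}): quadrature "
                "over a kernel sum is too expensive in higher dimensions"
            )
        ceiling = max_n if max_n is not None else MAX_N_INTEGRAL
    else:
        ceiling = max_n if max_n is not None else MAX_N_RESUBSTITUTION
    if n > ceiling:
        raise EstimationCostError(
            f"sample size {n} exceeds the KDE {mode} ceiling of {ceiling}; "
            "raise max_n explicitly to override"
        )


def _integrate_box(fn, box, tol=_INTEGRAL_TOL) -> float:
    if len(box) == 1:
        value, _ = integrate.quad(fn, box[0][0], box[0][1], epsabs=tol, epsrel=tol, limit=200)
    else:
        value, _ = integrate.nquad(fn, box, opts={"epsabs": tol, "epsrel": tol, "limit": 200})
    return float(value)


def _eval_scalar(model: KDEModel, args) -> float:
    return float(kde_eval(model, np.asarray(args, dtype=float).reshape(1, -1))[0])


def kde_entropy(sample, mode: str = "resubstitution", max_n: int | None = None) -> float:
    """Plug-in entropy in nats: H = -(1/n) sum log p(x_i), or the integral
    of -p log p over the bandwidth-widened sample box in integral mode."""
    _check_mode(mode)
    pts = _as_matrix(sample)
    _check_cost(pts.shape[0], pts.shape[1], mode, max_n)
    model = kde_fit(pts)
    if mode == "resubstitution":
        dens = kde_eval(model, pts)
        return float(-np.mean(np.log(dens)))

    box = integration_box(pts, model.bandwidth)

    def integrand(*args):
        p = _eval_scalar(model, args)
        return 0.0 if p <= 0.0 else -p * math.log(p)

    return _integrate_box(integrand, box)


def kde_kl(sample_p, sample_q, mode: str = "resubstitution", max_n: int | None = None) -> float:
    """Plug-in KL divergence: mean over p-points of log(p_hat/q_hat), with
    p_hat fit on sample_p and q_hat on sample_q."""
    _check_mode(mode)
    p_pts = _as_matrix(sample_p)
    q_pts = _as_matrix(sample_q)
    if p_pts.shape[1] != q_pts.shape[1]:
        raise ValueError("samples must share a common dimension")
    _check_cost(max(p_pts.shape[0], q_pts.shape[0]), p_pts.shape[1], mode, max_n)
    model_p = kde_fit(p_pts)
    model_q = kde_fit(q_pts)
    if mode == "resubstitution":
        log_p = np.log(kde_eval(model_p, p_pts))
        log_q = np.log(kde_eval(model_q, p_pts))
        return float(np.mean(log_p - log_q))

    box = integration_box(p_pts, model_p.bandwidth)

    def integrand(*args):
        p = _eval_scalar(model_p, args)
        if p <= 0.0:
            return 0.0
        q = _eval_scalar(model_q, args)
        return p * math.log(p / q)

    return _integrate_box(integrand, box)


def kde_mi(sample_xy, dx: int, mode: str = "resubstitution", max_n: int | None = None) -> float:
    """Plug-in mutual information between the leading `dx` columns (X) and
    the remaining columns (Y).  No clipping is applied: the resubstitution
    value can be slightly negative by construction."""
    _check_mode(mode)
    pts = _as_matrix(sample_xy)
    d = pts.shape[1]
    if not 1 <= dx < d:
        raise ValueError(f"dx must be in [1, {d - 1}], got {dx}")
    _check_cost(pts.shape[0], d, mode, max_n)
    joint = kde_fit(pts)
    model_x = kde_fit(pts[:, :dx])
    model_y = kde_fit(pts[:, dx:])
    if mode == "resubstitution":
        log_j = np.log(kde_eval(joint, pts))
        log_x = np.log(kde_eval(model_x, pts[:, :dx]))
        log_y = np.log(kde_eval(model_y, pts[:, dx:]))
        return float(np.mean(log_j - log_x - log_y))

    # one shared joint box; the marginal models integrate over its projections
    box = integration_box(pts, joint.bandwidth)

    def integrand(*args):
        x = np.asarray(args, dtype=float).reshape(1, -1)
        pj = float(kde_eval(joint, x)[0])
        if pj <= 0.0:
            return 0.0
        px = float(kde_eval(model_x, x[:, :dx])[0])
        py = float(kde_eval(model_y, x[:, dx:])[0])
        return pj * math.log(pj / (px * py))

    return _integrate_box(integrand, box)
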