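"""Nearest-neighbor estimators: no explicit density required.

Distances to each point's k-th nearest neighbor carry enough local density
information to estimate entropy (Kozachenko-Leonenko), KL divergence
between two samples (Wang et al.) and mutual information (Kraskov et al.,
algorithm 1), each corrected with digamma terms.  Entropy and KL use the
Euclidean norm; the Kraskov estimator requires the maximum (Chebyshev)
norm so that neighbor counts live in axis-aligned hyper-stripes.

Exact neighbor search is delegated to a k-d tree.  Coincident points give
zero distances and are rejected by default; an explicit jitter option
breaks ties with a vanishing uniform perturbation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

__all__ = [
    "unit_ball_volume",
    "knn_distances",
    "kl_entropy",
    "knn_kl",
    "kraskov_mi",
    "knn_density",
]

_NORM_P = {"euclidean": 2.0, "maximum": np.inf}


def unit_ball_volume(d: int) -> float:
    """Lebesgue volume pi^(d/2) / Gamma(d/2 + 1) of the d-dim unit ball."""
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    return float(math.exp(0.5 * d * math.log(math.pi) - gammaln(0.5 * d + 1.0)))


def _as_matrix(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"sample must be an (n, d) matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite entries")
    return arr


def knn_distances(
    query_points,
    reference,
    k: int,
    norm: str = "euclidean",
    mode: str = "cross",
) -> np.ndarray:
    """Exact distance from each query point to its k-th nearest reference
    point.

    In ``mode="self"`` the query set IS the reference set and each point's
    own zero distance is skipped (requires k <= n-1); ``mode="cross"``
    searches a foreign sample (requires k <= m).
    """
    if norm not in _NORM_P:
        raise ValueError(f"norm must be one of {tuple(_NORM_P)}, got {norm!r}")
    if mode not in ("self", "cross"):
        raise ValueError(f"mode must be 'self' or 'cross', got {mode!r}")
    query = _as_matrix(query_points)
    ref = _as_matrix(reference)
    if query.shape[1] != ref.shape[1]:
        raise ValueError("query and reference must share a common dimension")
    m = ref.shape[0]
    limit = m - 1 if mode == "self" else m
    if not 1 <= k <= limit:
        raise ValueError(f"k={k} out of range for {mode} search over {m} reference points")
    tree = cKDTree(ref)
    p = _NORM_P[norm]
    if mode == "self":
        dist, _ = tree.query(query, k=k + 1, p=p)
        return np.asarray(dist)[:, k]
    dist, _ = tree.query(query, k=k, p=p)
    dist = np.asarray(dist)
    return dist[:, k - 1] if dist.ndim == 2 else dist


def _reject_or_jitter(
    pts: np.ndarray, jitter_duplicates: bool, jitter_seed, what: str
) -> np.ndarray:
    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if uniq.shape[0] == pts.shape[0]:
        return pts
    if not jitter_duplicates:
        dup_rows = np.flatnonzero(counts[inverse] > 1)[:10]
        raise ValueError(
            f"{what} contains coincident points (rows {dup_rows.tolist()}, possibly "
            "more): zero neighbor distances are undefined under the log; pass "
            "jitter_duplicates=True to break ties with a vanishing perturbation"
        )
    rng = np.random.default_rng(jitter_seed)
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0.0] = 1.0
    amplitude = 1e-10 * span
    return pts + rng.uniform(-1.0, 1.0, size=pts.shape) * amplitude


def kl_entropy(
    sample, k: int = 1, jitter_duplicates: bool = False, jitter_seed=0
) -> float:
    """Kozachenko-Leonenko entropy in nats.

    H = psi(N) - psi(k) + log c1(d) + (d/N) sum_i log rho_k(i), where
    rho_k(i) is the Euclidean distance from x_i to its k-th nearest
    neighbor within the sample.
    """
    pts = _as_matrix(sample)
    n, d = pts.shape
    if n < k + 1:
        raise ValueError(f"Kozachenko-Leonenko requires n >= k+1 (n={n}, k={k})")
    pts = _reject_or_jitter(pts, jitter_duplicates, jitter_seed, "sample")
    rho = knn_distances(pts, pts, k=k, norm="euclidean", mode="self")
    if np.any(rho == 0.0):
        raise ValueError("zero k-th neighbor distance: sample contains coincident points")
    return float(
        digamma(n) - digamma(k) + math.log(unit_ball_volume(d)) + d * np.mean(np.log(rho))
    )


def knn_kl(
    sample_p,
    sample_q,
    k: int = 1,
    jitter_duplicates: bool = False,
    jitter_seed=0,
) -> float:
    """Wang et al. two-sample KL divergence in nats.

    D = (d/n) sum_i log(nu_k(i)/rho_k(i)) + log(m/(n-1)), with rho the
    within-p and nu the into-q k-th neighbor distances (Euclidean).  The
    estimate is unbounded below and may legitimately be negative.
    """
    p_pts = _as_matrix(sample_p)
    q_pts = _as_matrix(sample_q)
    if p_pts.shape[1] != q_pts.shape[1]:
        raise ValueError("samples must share a common dimension")
    n, d = p_pts.shape
    m = q_pts.shape[0]
    if n < k + 1 or m < k:
        raise ValueError(f"knn_kl requires n >= k+1 and m >= k (n={n}, m={m}, k={k})")
    if jitter_duplicates:
        p_pts = _reject_or_jitter(p_pts, True, jitter_seed, "sample_p")
        q_pts = _reject_or_jitter(q_pts, True, np.random.SeedSequence(jitter_seed).spawn(1)[0], "sample_q")
    rho = knn_distances(p_pts, p_pts, k=k, norm="euclidean", mode="self")
    nu = knn_distances(p_pts, q_pts, k=k, norm="euclidean", mode="cross")
    if np.any(rho == 0.0) or np.any(nu == 0.0):
        raise ValueError(
            "zero k-th neighbor distance (coincident points within or across "
            "samples); pass jitter_duplicates=True to break ties"
        )
    return float(d * np.mean(np.log(nu / rho)) + math.log(m / (n - 1.0)))


def kraskov_mi(
    sample_xy,
    dx: int,
    k: int = 1,
    return_raw: bool = False,
):
    """Kraskov-Stogbauer-Grassberger mutual information (algorithm 1), nats.

    For each point, rho is the max-norm distance to its k-th neighbor in
    the joint space; n_x and n_y count the other points STRICTLY closer
    than rho in the X and Y marginal spaces.  I = psi(k) + psi(N)
    - mean(psi(n_x+1) + psi(n_y+1)).  Negative raw values are clipped to
    0.0 (mutual information is non-negative); pass ``return_raw=True`` to
    also receive the unclipped value.
    """
    pts = _as_matrix(sample_xy)
    n, d = pts.shape
    if not 1 <= dx < d:
        raise ValueError(f"dx must be in [1, {d - 1}], got {dx}")
    if n < k + 1:
        raise ValueError(f"kraskov_mi requires n >= k+1 (n={n}, k={k})")
    rho = knn_distances(pts, pts, k=k, norm="maximum", mode="self")

    x, y = pts[:, :dx], pts[:, dx:]
    tree_x, tree_y = cKDTree(x), cKDTree(y)
    # strict inequality at the radius: shrink to the previous representable
    # float so boundary ties are not counted
    radius = np.nextafter(rho, -np.inf)
    n_x = np.array(tree_x.query_ball_point(x, r=radius, p=np.inf, return_length=True))
    n_y = np.array(tree_y.query_ball_point(y, r=radius, p=np.inf, return_length=True))
    # ball queries count the point itself
    n_x = np.maximum(n_x - 1, 0)
    n_y = np.maximum(n_y - 1, 0)
    raw = float(
        digamma(k) + digamma(n) - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
    )
    clipped = max(raw, 0.0)
    if return_raw:
        return clipped, raw
    return clipped


def knn_density(sample, query_points, k: int) -> np.ndarray:
    """Distance-based density p(x) = k/(N-1) / (c1(d) rho_k(x)^d).

    Included for completeness; as a plug-in density it is high-variance
    and not recommended for entropy estimation.
    """
    pts = _as_matrix(sample)
    query = _as_matrix(query_points)
    n, d = pts.shape
    rho = knn_distances(query, pts, k=k + 1, norm="euclidean", mode="cross")
    # a query point coinciding with a sample point contributes a zero
    # distance; treat queries as in-sample (self-excluded) by using the
    # (k+1)-th distance when the nearest distance is zero, k-th otherwise
    near, _ = cKDTree(pts).query(query, k=1)
    k_eff = knn_distances(query, pts, k=k, norm="euclidean", mode="cross")
    rho = np.where(np.asarray(near) == 0.0, rho, k_eff)
    if np.any(rho == 0.0):
        raise ValueError("zero k-th neighbor distance at a query point")
    return (k / (n - 1.0)) / (unit_ball_volume(d) * rho**d)
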