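"""Benchmark distributions, seeded samplers and reference values.

The estimator benchmark runs on eight synthetic test cases built from five
distribution families: a 1-D uniform, a 1-D normal, mixtures of (possibly
multivariate) normals, multivariate normals in 2/4/10 dimensions, and a
skewed 2-D gamma-exponential.  Each family knows how to draw a seeded
sample, evaluate its exact pdf, and — where a closed form exists — report
the true differential entropy, KL divergence and mutual information in
nats.  Where no closed form exists the truth is obtained by adaptive
quadrature over the true support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import digamma, gammaln

__all__ = [
    "Uniform",
    "Normal",
    "MultivariateNormal",
    "NormalMixture",
    "GammaExponential",
    "ReferenceValue",
    "BenchmarkCase",
    "sample",
    "pdf",
    "analytic_reference",
    "numeric_reference",
    "builtin_cases",
    "write_sample",
    "read_sample",
]

QUAD_TOL = 1.49e-8  # absolute and relative quadrature tolerance

_QUANTITIES = ("entropy", "kl", "mi")


class InvalidSpecError(ValueError):
    """A distribution specification violates one of its invariants."""


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Uniform:
    """Continuous uniform on [a, b], b > a."""

    a: float
    b: float
    family = "uniform1d"

    def __post_init__(self) -> None:
        if not self.b > self.a:
            raise InvalidSpecError(f"uniform requires b > a, got a={self.a}, b={self.b}")

    @property
    def dim(self) -> int:
        return 1

    def _rv(self):
        return stats.uniform(loc=self.a, scale=self.b - self.a)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.a, self.b, size=(n, 1))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self._rv().pdf(x[:, 0])

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return self._rv().logpdf(x[:, 0])

    def entropy(self) -> float:
        return math.log(self.b - self.a)

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(self.a, self.b)]


@dataclass(frozen=True)
class Normal:
    """1-D normal N(mu, sigma^2), sigma > 0."""

    mu: float
    sigma: float
    family = "normal1d"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidSpecError(f"normal requires sigma > 0, got {self.sigma}")

    @property
    def dim(self) -> int:
        return 1

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size=(n, 1))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return stats.norm.pdf(x[:, 0], loc=self.mu, scale=self.sigma)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return stats.norm.logpdf(x[:, 0], loc=self.mu, scale=self.sigma)

    def entropy(self) -> float:
        # H = 1/2 ln(2 pi sigma^2) + 1/2
        return 0.5 * math.log(2.0 * math.pi * self.sigma**2) + 0.5

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(-np.inf, np.inf)]


@dataclass(frozen=True)
class MultivariateNormal:
    """d-dimensional normal with mean vector and positive-definite covariance."""

    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]
    family = "mv_normal"

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise InvalidSpecError(
                f"covariance shape {cov.shape} does not match mean length {mean.size}"
            )
        if not np.allclose(cov, cov.T):
            raise InvalidSpecError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise InvalidSpecError(
                f"covariance must be positive-definite (min eigenvalue {eigvals.min():g})"
            )
        object.__setattr__(self, "mean", tuple(mean.tolist()))
        object.__setattr__(self, "cov", tuple(map(tuple, cov.tolist())))

    @property
    def dim(self) -> int:
        return len(self.mean)

    @property
    def mean_arr(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def cov_arr(self) -> np.ndarray:
        return np.asarray(self.cov, dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean_arr, self.cov_arr, size=n, method="cholesky")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_1d(
            stats.multivariate_normal.pdf(x, mean=self.mean_arr, cov=self.cov_arr)
        )

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_1d(
            stats.multivariate_normal.logpdf(x, mean=self.mean_arr, cov=self.cov_arr)
        )

    def entropy(self) -> float:
        # H = 1/2 ln((2 pi e)^d det Sigma)
        d = self.dim
        sign, logdet = np.linalg.slogdet(self.cov_arr)
        return 0.5 * (d * math.log(2.0 * math.pi * math.e) + logdet)

    def marginal(self, dims: Sequence[int]) -> "MultivariateNormal | Normal":
        dims = list(dims)
        mean = self.mean_arr[dims]
        cov = self.cov_arr[np.ix_(dims, dims)]
        if len(dims) == 1:
            return Normal(mu=float(mean[0]), sigma=float(math.sqrt(cov[0, 0])))
        return MultivariateNormal(mean=tuple(mean), cov=tuple(map(tuple, cov)))

    def mutual_information(self, split: int) -> float:
        """I(X;Y) for X = leading `split` dims, Y = the rest.

        I = 1/2 ln(det Sxx * det Syy / det S).
        """
        d = self.dim
        if not 1 <= split < d:
            raise InvalidSpecError(f"split must be in [1, {d - 1}], got {split}")
        cov = self.cov_arr
        _, ld_xx = np.linalg.slogdet(cov[:split, :split])
        _, ld_yy = np.linalg.slogdet(cov[split:, split:])
        _, ld = np.linalg.slogdet(cov)
        return 0.5 * (ld_xx + ld_yy - ld)

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(-np.inf, np.inf)] * self.dim


@dataclass(frozen=True)
class NormalMixture:
    """Weighted mixture of normal components (1-D or multivariate, equal dim)."""

    weights: tuple[float, ...]
    components: tuple["Normal | MultivariateNormal", ...]
    family = "normal_mixture"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.components) != w.size:
            raise InvalidSpecError("one weight per component required")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-12):
            raise InvalidSpecError(f"weights must be >= 0 and sum to 1, got {w.tolist()}")
        dims = {c.dim for c in self.components}
        if len(dims) != 1:
            raise InvalidSpecError("components must share a common dimension")
        object.__setattr__(self, "weights", tuple(w.tolist()))
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # Categorical component choice first, then component draws; one RNG
        # stream consumed in fixed order so a seed fully determines the output.
        choice = rng.choice(len(self.components), size=n, p=np.asarray(self.weights))
        out = np.empty((n, self.dim))
        for i, comp in enumerate(self.components):
            mask = choice == i
            k = int(mask.sum())
            if k:
                out[mask] = comp.sample(k, rng)
        return out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        dens = np.zeros(x.shape[0])
        for w, comp in zip(self.weights, self.components):
            dens += w * comp.pdf(x)
        return dens

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        stacked = np.stack(
            [math.log(w) + comp.logpdf(x) for w, comp in zip(self.weights, self.components)]
        )
        return logsumexp(stacked, axis=0)

    def marginal(self, dims: Sequence[int]) -> "NormalMixture":
        comps = []
        for comp in self.components:
            if isinstance(comp, Normal):
                raise InvalidSpecError("marginal of a 1-D mixture is itself")
            comps.append(comp.marginal(dims))
        return NormalMixture(weights=self.weights, components=tuple(comps))

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(-np.inf, np.inf)] * self.dim


@dataclass(frozen=True)
class GammaExponential:
    """Skewed 2-D density p(x1,x2) = x1^theta exp(-x1 - x1*x2) / Gamma(theta).

    Equivalent factorization: x1 ~ Gamma(shape theta, scale 1) and
    x2 | x1 ~ Exponential(rate x1); both coordinates are positive.
    """

    theta: float
    family = "gamma_exponential"

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise InvalidSpecError(f"gamma-exponential requires theta > 0, got {self.theta}")

    @property
    def dim(self) -> int:
        return 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x1 = rng.gamma(shape=self.theta, scale=1.0, size=n)
        x2 = rng.exponential(scale=1.0 / x1)
        return np.column_stack([x1, x2])

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = x[:, 0], x[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = self.theta * np.log(x1) - x1 - x1 * x2 - gammaln(self.theta)
        dens = np.where((x1 > 0) & (x2 > 0), np.exp(logp), 0.0)
        return dens

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = x[:, 0], x[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = self.theta * np.log(x1) - x1 - x1 * x2 - gammaln(self.theta)
        return np.where((x1 > 0) & (x2 > 0), logp, -np.inf)

    def entropy(self) -> float:
        # H = 1 + theta - theta*psi(theta) + ln Gamma(theta); the printed
        # trailing "-ln 1" is identically zero.
        t = self.theta
        return 1.0 + t - t * digamma(t) + gammaln(t)

    def mutual_information(self) -> float:
        # I = psi(theta) - ln(theta) + 1/theta
        t = self.theta
        return float(digamma(t) - math.log(t) + 1.0 / t)

    def marginal_pdf(self, index: int) -> Callable[[np.ndarray], np.ndarray]:
        """Exact marginal density of coordinate `index` (0 or 1)."""
        t = self.theta
        if index == 0:
            return lambda x: stats.gamma.pdf(x, a=t, scale=1.0)
        # integrate x1 out: theta / (1 + x2)^(theta+1) on x2 > 0
        return lambda x: np.where(x > 0, t * (1.0 + np.maximum(x, 0.0)) ** (-(t + 1.0)), 0.0)

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(0.0, np.inf), (0.0, np.inf)]


Distribution = Uniform | Normal | MultivariateNormal | NormalMixture | GammaExponential


# ---------------------------------------------------------------------------
# samples and references
# ---------------------------------------------------------------------------


def sample(spec: Distribution, n: int, seed) -> np.ndarray:
    """Draw an (n, d) sample matrix; identical (spec, n, seed) -> identical bits."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return spec.sample(n, rng)


def pdf(spec: Distribution, points: np.ndarray) -> np.ndarray:
    """Exact density of `spec` at each row of `points`."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != spec.dim:
        raise ValueError(
            f"points have {points.shape[1]} columns but spec has dimension {spec.dim}"
        )
    return spec.pdf(points)


@dataclass(frozen=True)
class ReferenceValue:
    """A true value of one quantity, in nats."""

    quantity: str
    value: float
    method: str  # "analytic" | "quadrature"
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")


def _check_kl_support(p: Distribution, q: Distribution) -> None:
    """KL(p||q) needs support(q) to cover support(p)."""
    for (plo, phi), (qlo, qhi) in zip(p.support, q.support):
        if qlo > plo or qhi < phi:
            raise ValueError(
                "KL divergence requires the support of q to contain the support "
                f"of p; q covers [{qlo}, {qhi}] but p needs [{plo}, {phi}]"
            )


def analytic_reference(
    quantity: str,
    spec_p: Distribution,
    spec_q: Distribution | None = None,
    split: int | None = None,
) -> ReferenceValue | None:
    """Closed-form reference, or None where no closed form exists.

    Mixtures have no closed form for any quantity; the gamma-exponential has
    none for KL divergence.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")

    if quantity == "entropy":
        if isinstance(spec_p, NormalMixture):
            return None
        return ReferenceValue("entropy", float(spec_p.entropy()), "analytic")

    if quantity == "kl":
        if spec_q is None:
            raise ValueError("kl requires a second distribution q")
        if isinstance(spec_p, (NormalMixture, GammaExponential)) or isinstance(
            spec_q, (NormalMixture, GammaExponential)
        ):
            return None
        if type(spec_p) is not type(spec_q):
            raise ValueError("analytic KL implemented for same-family pairs only")
        _check_kl_support(spec_p, spec_q)
        if isinstance(spec_p, Uniform):
            value = math.log((spec_q.b - spec_q.a) / (spec_p.b - spec_p.a))
        elif isinstance(spec_p, Normal):
            sp2, sq2 = spec_p.sigma**2, spec_q.sigma**2
            value = 0.5 * (
                sp2 / sq2 + (spec_q.mu - spec_p.mu) ** 2 / sq2 - 1.0 + math.log(sq2 / sp2)
            )
        else:  # multivariate normal
            d = spec_p.dim
            cp, cq = spec_p.cov_arr, spec_q.cov_arr
            dmu = spec_q.mean_arr - spec_p.mean_arr
            cq_inv = np.linalg.inv(cq)
            _, ld_p = np.linalg.slogdet(cp)
            _, ld_q = np.linalg.slogdet(cq)
            value = 0.5 * (ld_q - ld_p + np.trace(cq_inv @ cp) + dmu @ cq_inv @ dmu - d)
        return ReferenceValue("kl", float(value), "analytic")

    # mutual information
    if isinstance(spec_p, MultivariateNormal):
        if split is None:
            raise ValueError("mi for a multivariate normal requires a dimension split")
        return ReferenceValue("mi", float(spec_p.mutual_information(split)), "analytic")
    if isinstance(spec_p, GammaExponential):
        return ReferenceValue("mi", spec_p.mutual_information(), "analytic")
    if isinstance(spec_p, NormalMixture):
        return None
    raise ValueError(f"mutual information undefined for 1-D family {spec_p.family}")


def _quad_1d(fn: Callable[[float], float], lo: float, hi: float, tol: float):
    return integrate.quad(fn, lo, hi, epsabs=tol, epsrel=tol, limit=200)


def _quad(fn: Callable[..., float], ranges, tol: float):
    if len(ranges) == 1:
        return _quad_1d(fn, ranges[0][0], ranges[0][1], tol)
    value, err = integrate.nquad(
        fn, ranges, opts={"epsabs": tol, "epsrel": tol, "limit": 200}
    )
    return value, err


def _point(args) -> np.ndarray:
    return np.asarray(args, dtype=float).reshape(1, -1)


def numeric_reference(
    quantity: str,
    spec_p: Distribution,
    spec_q: Distribution | None = None,
    split: int | None = None,
    tol: float = QUAD_TOL,
) -> ReferenceValue:
    """Adaptive-quadrature reference over the true support (d <= 2 only)."""
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")
    if spec_p.dim > 2:
        raise ValueError("quadrature references are supported for d <= 2 only")
    ranges = spec_p.support

    if quantity == "entropy":

        def integrand(*args):
            p = float(pdf(spec_p, _point(args))[0])
            return 0.0 if p <= 0.0 else -p * math.log(p)

    elif quantity == "kl":
        if spec_q is None:
            raise ValueError("kl requires a second distribution q")
        _check_kl_support(spec_p, spec_q)

        # log densities keep the tails finite where the raw pdf underflows
        def integrand(*args):
            x = _point(args)
            log_p = float(spec_p.logpdf(x)[0])
            if not math.isfinite(log_p):
                return 0.0
            p = math.exp(log_p)
            if p == 0.0:  # underflow: the region contributes nothing
                return 0.0
            log_q = float(spec_q.logpdf(x)[0])
            return p * (log_p - log_q)

    else:  # mi, 2-D joint against product of exact marginals
        if spec_p.dim != 2:
            raise ValueError("quadrature mutual information requires a 2-D joint")
        if isinstance(spec_p, GammaExponential):
            marg = [spec_p.marginal_pdf(0), spec_p.marginal_pdf(1)]

            def log_marginal(i, v):
                with np.errstate(divide="ignore"):
                    return float(np.log(marg[i](np.asarray([v])))[0])

        else:
            marginals = [spec_p.marginal([0]), spec_p.marginal([1])]

            def log_marginal(i, v):
                return float(marginals[i].logpdf(np.asarray([[v]]))[0])

        def integrand(*args):
            x = _point(args)
            log_p = float(spec_p.logpdf(x)[0])
            if not math.isfinite(log_p):
                return 0.0
            p = math.exp(log_p)
            if p == 0.0:
                return 0.0
            log_m = log_marginal(0, args[0]) + log_marginal(1, args[1])
            return p * (log_p - log_m)

    value, err = _quad(integrand, ranges, tol)
    return ReferenceValue(quantity, float(value), "quadrature", tolerance=float(err))


def reference(
    quantity: str,
    spec_p: Distribution,
    spec_q: Distribution | None = None,
    split: int | None = None,
    tol: float = QUAD_TOL,
) -> ReferenceValue:
    """Analytic reference where available, quadrature otherwise."""
    ref = analytic_reference(quantity, spec_p, spec_q, split)
    if ref is None:
        ref = numeric_reference(quantity, spec_p, spec_q, split, tol)
    return ref


# ---------------------------------------------------------------------------
# the eight benchmark cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkCase:
    """One benchmark scenario: a true distribution p, an approximating q for
    KL, the applicable quantities, and the MI dimension split (X = leading
    dims, Y = trailing dims)."""

    case_id: int
    name: str
    p: Distribution
    q: Distribution | None
    quantities: tuple[str, ...]
    mi_split: int | None = None

    @property
    def dim(self) -> int:
        return self.p.dim

    def reference(self, quantity: str, tol: float = QUAD_TOL) -> ReferenceValue:
        if quantity not in self.quantities:
            raise ValueError(f"case {self.case_id} does not define {quantity!r}")
        return reference(quantity, self.p, self.q, self.mi_split, tol)

    def to_config(self) -> dict:
        return {
            "case_id": self.case_id,
            "name": self.name,
            "family": self.p.family,
            "dim": self.dim,
            "quantities": list(self.quantities),
            "mi_split": self.mi_split,
            "p": _spec_params(self.p),
            "q": _spec_params(self.q) if self.q is not None else None,
        }


def _spec_params(spec: Distribution) -> dict:
    if isinstance(spec, Uniform):
        return {"family": spec.family, "a": spec.a, "b": spec.b}
    if isinstance(spec, Normal):
        return {"family": spec.family, "mu": spec.mu, "sigma": spec.sigma}
    if isinstance(spec, MultivariateNormal):
        return {"family": spec.family, "mean": list(spec.mean), "cov": [list(r) for r in spec.cov]}
    if isinstance(spec, NormalMixture):
        return {
            "family": spec.family,
            "weights": list(spec.weights),
            "components": [_spec_params(c) for c in spec.components],
        }
    return {"family": spec.family, "theta": spec.theta}


def _equicorrelated(d: int, rho: float) -> tuple[tuple[float, ...], ...]:
    cov = np.full((d, d), rho)
    np.fill_diagonal(cov, 1.0)
    return tuple(map(tuple, cov.tolist()))


def builtin_cases() -> list[BenchmarkCase]:
    """The eight configured benchmark cases.

    The 1-D cases (1-3) carry entropy and KL only: a single scalar has no
    second variable to share information with.
    """
    cases = [
        BenchmarkCase(
            1,
            "1D uniform",
            p=Uniform(0.5, 2.0),
            q=Uniform(0.0, 2.0),
            quantities=("entropy", "kl"),
        ),
        BenchmarkCase(
            2,
            "1D normal",
            p=Normal(-2.5, 2.5),
            q=Normal(0.0, 3.15),
            quantities=("entropy", "kl"),
        ),
        BenchmarkCase(
            3,
            "1D normal mixture",
            p=NormalMixture(
                weights=(0.5, 0.5),
                components=(Normal(-2.5, 2.5), Normal(2.5, 1.0)),
            ),
            q=Normal(0.0, 3.15),
            quantities=("entropy", "kl"),
        ),
        BenchmarkCase(
            4,
            "2D normal",
            p=MultivariateNormal(mean=(-2.0, 0.0), cov=((1.0, -0.5), (-0.5, 1.0))),
            q=MultivariateNormal(mean=(0.0, 0.0), cov=((5.0, 0.0), (0.0, 1.0))),
            quantities=("entropy", "kl", "mi"),
            mi_split=1,
        ),
        BenchmarkCase(
            5,
            "2D normal mixture",
            p=NormalMixture(
                weights=(0.5, 0.5),
                components=(
                    MultivariateNormal(mean=(-2.0, 0.0), cov=((1.0, -0.5), (-0.5, 1.0))),
                    MultivariateNormal(mean=(2.0, 0.0), cov=((1.0, 0.5), (0.5, 1.0))),
                ),
            ),
            q=MultivariateNormal(mean=(0.0, 0.0), cov=((5.0, 0.0), (0.0, 1.0))),
            quantities=("entropy", "kl", "mi"),
            mi_split=1,
        ),
        BenchmarkCase(
            6,
            "2D gamma-exponential",
            p=GammaExponential(theta=3.0),
            q=GammaExponential(theta=4.0),
            quantities=("entropy", "kl", "mi"),
            mi_split=1,
        ),
        BenchmarkCase(
            7,
            "4D normal",
            p=MultivariateNormal(mean=(0.1, 0.3, 0.6, 0.9), cov=_equicorrelated(4, 0.5)),
            q=MultivariateNormal(mean=(0.0,) * 4, cov=_equicorrelated(4, 0.1)),
            quantities=("entropy", "kl", "mi"),
            mi_split=3,
        ),
        BenchmarkCase(
            8,
            "10D normal",
            p=MultivariateNormal(mean=(0.0,) * 10, cov=_equicorrelated(10, 0.9)),
            q=MultivariateNormal(mean=(0.0,) * 10, cov=_equicorrelated(10, 0.1)),
            quantities=("entropy", "kl", "mi"),
            mi_split=9,
        ),
    ]
    return cases


def get_case(case_id: int) -> BenchmarkCase:
    for case in builtin_cases():
        if case.case_id == case_id:
            return case
    raise KeyError(f"no benchmark case with id {case_id}")


# ---------------------------------------------------------------------------
# delimited-text sample IO
# ---------------------------------------------------------------------------


def write_sample(path, values: np.ndarray, header: bool = False, delimiter: str = ",") -> None:
    """Write an (n, d) sample matrix as delimited text, one row per observation."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    hdr = delimiter.join(f"x{j + 1}" for j in range(values.shape[1])) if header else ""
    np.savetxt(path, values, delimiter=delimiter, header=hdr, comments="")


def read_sample(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a delimited-text sample matrix back into an (n, d) array."""
    arr = np.loadtxt(path, delimiter=delimiter, skiprows=1 if header else 0, ndmin=2)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample matrix {path} contains non-finite entries")
    return arr
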