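"""Gaussian process regression with an ARD squared-exponential kernel.

This engine backs both uses of GPR in the workflow:

* multiband green-LAI retrieval, where the inputs are reflectance vectors
  (D = 6 or 10 bands) and the inverse lengthscale of each band measures its
  relevance to the prediction; and
* 1-D time-series gap-filling, where the single input is acquisition time
  and the lengthscale is a temporal correlation scale in days.

Model
-----
Observations ``y = f(x) + eps`` with ``eps ~ N(0, sigma_n^2)`` and a
zero-mean GP prior on ``f`` with covariance

    k(x_i, x_j) = sigma_s^2 * exp(-1/2 * sum_b ((x_ib - x_jb)/sigma_b)^2).

The predictive distribution at ``x*`` is Gaussian with

    mean = k*^T (K + sigma_n^2 I)^-1 y
    var  = c* - k*^T (K + sigma_n^2 I)^-1 k*,   c* = k(x*,x*) + sigma_n^2,

and the hyperparameters ``theta = (sigma_s^2, sigma_1..sigma_D, sigma_n^2)``
are trained by maximising the log marginal likelihood

    log p(y|X,theta) = -1/2 y^T A^-1 y - 1/2 log|A| - N/2 log 2pi,
    A = K + sigma_n^2 I,

via L-BFGS-B in log-parameter space with analytic gradients and seeded
random restarts. Targets are mean-centred internally (the prior assumes a
zero mean; LAI is non-negative) and the centre is added back at prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPRHyperparams",
    "GaussianProcess",
    "GPRResults",
    "se_kernel",
    "fit_gpr",
    "log_marginal_likelihood",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GPRHyperparams:
    """Kernel and noise hyperparameters.

    sigma_s2 : signal (output) variance, > 0
    lengthscales : per-input-dimension scale sigma_b, > 0, length D
    sigma_n2 : observation noise variance, >= 0
    """

    sigma_s2: float
    lengthscales: np.ndarray
    sigma_n2: float

    def __post_init__(self):
        object.__setattr__(self, "lengthscales",
                           np.atleast_1d(np.asarray(self.lengthscales, dtype=float)))
        if self.sigma_s2 <= 0:
            raise ValueError("sigma_s2 must be > 0")
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be > 0")
        if self.sigma_n2 < 0:
            raise ValueError("sigma_n2 must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.lengthscales)

    def to_log_vector(self) -> np.ndarray:
        return np.log(np.concatenate(
            [[self.sigma_s2], self.lengthscales, [max(self.sigma_n2, 1e-300)]]))

    @classmethod
    def from_log_vector(cls, v: np.ndarray) -> "GPRHyperparams":
        v = np.asarray(v, dtype=float)
        return cls(float(np.exp(v[0])), np.exp(v[1:-1]), float(np.exp(v[-1])))


def se_kernel(Xa: np.ndarray, Xb: np.ndarray, theta: GPRHyperparams) -> np.ndarray:
    """ARD squared-exponential covariance between two input sets.

    Entry (i, j) is ``sigma_s^2 exp(-1/2 sum_b ((xa_ib - xb_jb)/sigma_b)^2)``.
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    D = theta.ndim
    if Xa.shape[1] != D or Xb.shape[1] != D:
        raise ValueError(
            f"input dimension mismatch: Xa has {Xa.shape[1]} columns, "
            f"Xb has {Xb.shape[1]}, kernel expects D={D}"
        )
    Sa = Xa / theta.lengthscales
    Sb = Xb / theta.lengthscales
    d2 = (
        np.sum(Sa**2, axis=1)[:, None]
        + np.sum(Sb**2, axis=1)[None, :]
        - 2.0 * Sa @ Sb.T
    )
    np.maximum(d2, 0.0, out=d2)
    return theta.sigma_s2 * np.exp(-0.5 * d2)


def _chol_with_jitter(A: np.ndarray, sigma_s2: float):
    """Cholesky of A, escalating diagonal jitter 1e-8..1e-4 x sigma_s2."""
    try:
        return linalg.cholesky(A, lower=True), 0.0
    except linalg.LinAlgError:
        pass
    jitter = 1e-8 * sigma_s2
    while jitter <= 1e-4 * sigma_s2:
        try:
            L = linalg.cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        "kernel system singular even after jitter up to 1e-4*sigma_s2; "
        f"matrix size {A.shape[0]}, sigma_s2={sigma_s2:.3g}"
    )


class GaussianProcess:
    """GP regression model on training inputs X (N x D) and targets y (N).

    Exactly duplicated input rows are collapsed by averaging their targets
    before fitting: duplicates make the kernel matrix singular and, under
    marginal-likelihood training, drive the noise variance to its floor
    (the duplicates "prove" zero noise), which destabilises the fit.
    Averaging keeps the system full rank and the noise estimate honest.
    """

    def __init__(self, X, y, input_names: list[str] | None = None,
                 metadata: dict | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(y) < 1:
            raise ValueError("need at least one training sample")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("training data must be finite")
        uniq, inverse = np.unique(X, axis=0, return_inverse=True)
        if len(uniq) < len(X):
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, y)
            y = sums / np.bincount(inverse)
            X = uniq
        self.X = X
        self.y = y
        self.nobs, self.ndim = X.shape
        self.input_names = input_names or [f"x{b}" for b in range(self.ndim)]
        self.metadata = dict(metadata or {})

    # -- likelihood ---------------------------------------------------------

    def _factorize(self, theta: GPRHyperparams):
        K = se_kernel(self.X, self.X, theta)
        A = K + theta.sigma_n2 * np.eye(self.nobs)
        L, jitter = _chol_with_jitter(A, theta.sigma_s2)
        yc = self.y - self.y.mean()
        alpha = linalg.cho_solve((L, True), yc)
        return K, L, alpha, jitter

    def loglike(self, theta: GPRHyperparams) -> float:
        """Log marginal likelihood of the centred targets under theta."""
        _, L, alpha, _ = self._factorize(theta)
        yc = self.y - self.y.mean()
        ll = (-0.5 * yc @ alpha
              - np.sum(np.log(np.diag(L)))
              - 0.5 * self.nobs * _LOG2PI)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log marginal likelihood")
        return float(ll)

    def loglike_terms(self, theta: GPRHyperparams) -> dict[str, float]:
        """The data-fit, complexity and constant terms separately."""
        _, L, alpha, _ = self._factorize(theta)
        yc = self.y - self.y.mean()
        return {
            "data_fit": float(-0.5 * yc @ alpha),
            "complexity": float(-np.sum(np.log(np.diag(L)))),
            "constant": float(-0.5 * self.nobs * _LOG2PI),
        }

    def loglike_and_grad(self, log_theta: np.ndarray):
        """Log marginal likelihood and its gradient in log-hyperparameters."""
        theta = GPRHyperparams.from_log_vector(log_theta)
        K, L, alpha, jitter = self._factorize(theta)
        yc = self.y - self.y.mean()
        ll = (-0.5 * yc @ alpha - np.sum(np.log(np.diag(L)))
              - 0.5 * self.nobs * _LOG2PI)
        Ainv = linalg.cho_solve((L, True), np.eye(self.nobs))
        W = np.outer(alpha, alpha) - Ainv
        grad = np.empty(2 + theta.ndim)
        # d A / d log sigma_s2 = K (the SE block scales linearly in sigma_s2)
        grad[0] = 0.5 * np.sum(W * K)
        for b in range(theta.ndim):
            diff = self.X[:, b][:, None] - self.X[:, b][None, :]
            dA = K * (diff**2) / theta.lengthscales[b] ** 2
            grad[1 + b] = 0.5 * np.sum(W * dA)
        grad[-1] = 0.5 * theta.sigma_n2 * np.trace(W)
        return float(ll), grad

    # -- fitting ------------------------------------------------------------

    def default_init(self) -> GPRHyperparams:
        """Moment-based starting point: lengthscale = input sd, sigma_s2 =
        var(y), sigma_n2 = 0.1 var(y)."""
        ls = np.std(self.X, axis=0)
        ls[ls == 0] = 1.0
        vy = float(np.var(self.y))
        if vy == 0:
            vy = 1.0
        return GPRHyperparams(vy, ls, 0.1 * vy)

    def fit(self, init: GPRHyperparams | None = None, bounds=None,
            n_restarts: int = 3, seed: int = 0, optimize_hyperparams: bool = True,
            ) -> "GPRResults":
        """Train by maximum marginal likelihood (L-BFGS-B, log space).

        ``n_restarts`` additional starts perturb the initial point
        log-uniformly within a factor of 10; the best optimum is kept.
        Deterministic for a fixed seed. With ``optimize_hyperparams=False``
        the model is conditioned on ``init`` as-is.
        """
        theta0 = init or self.default_init()
        if not optimize_hyperparams:
            return GPRResults(self, theta0)
        if self.nobs < 2:
            raise ValueError("hyperparameter optimization needs N >= 2")

        if bounds is None:
            v0 = theta0.to_log_vector()
            lo = np.concatenate([[v0[0] - np.log(1e6)],
                                 v0[1:-1] - np.log(1e3),
                                 [np.log(1e-9 * theta0.sigma_s2)]])
            hi = np.concatenate([[v0[0] + np.log(1e6)],
                                 v0[1:-1] + np.log(1e3),
                                 [np.log(10.0 * max(theta0.sigma_s2, 1e-12))]])
            bounds = list(zip(lo, hi))
        bounds = [(float(a), float(b)) for a, b in bounds]

        def objective(v):
            try:
                ll, g = self.loglike_and_grad(v)
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e25, np.zeros_like(v)
            if not np.isfinite(ll):
                return 1e25, np.zeros_like(v)
            return -ll, -g

        rng = np.random.default_rng(seed)
        v0 = np.clip(theta0.to_log_vector(), [b[0] for b in bounds],
                     [b[1] for b in bounds])
        starts = [v0]
        for _ in range(n_restarts):
            pert = rng.uniform(-np.log(10.0), np.log(10.0), size=v0.shape)
            starts.append(np.clip(v0 + pert, [b[0] for b in bounds],
                                  [b[1] for b in bounds]))

        best = None
        failures = []
        for s in starts:
            res = optimize.minimize(objective, s, jac=True, method="L-BFGS-B",
                                    bounds=bounds)
            if not np.isfinite(res.fun) or res.fun >= 1e24:
                failures.append(res.message)
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"GPR training failed in all {len(starts)} starts: {failures}")
        return GPRResults(self, GPRHyperparams.from_log_vector(best.x))


class GPRResults:
    """A trained GP: hyperparameters plus the cached kernel-system solve."""

    def __init__(self, model: GaussianProcess, theta: GPRHyperparams):
        if theta.ndim != model.ndim:
            raise ValueError("theta dimension does not match training inputs")
        self.model = model
        self.theta = theta
        self.y_center = float(model.y.mean())
        _, self._L, self._alpha, self.jitter = model._factorize(theta)
        self.llf = model.loglike(theta)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, Xstar) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance at the query inputs.

        Returns (mean, variance); variance includes the noise term via
        ``c* = k(x*,x*) + sigma_n^2`` and is strictly positive.
        """
        Xstar = np.asarray(Xstar, dtype=float)
        if Xstar.ndim == 1:
            Xstar = Xstar[:, None] if self.model.ndim == 1 else Xstar[None, :]
        ks = se_kernel(Xstar, self.model.X, self.theta)  # Q x N
        mean = ks @ self._alpha + self.y_center
        v = linalg.solve_triangular(self._L, ks.T, lower=True)
        cstar = self.theta.sigma_s2 + self.theta.sigma_n2 + self.jitter
        var = cstar - np.sum(v**2, axis=0)
        return mean, np.maximum(var, 1e-300)

    def band_relevance(self) -> dict[str, float]:
        """Per-input relevance 1/sigma_b (larger = more informative)."""
        return {name: 1.0 / float(ls)
                for name, ls in zip(self.model.input_names, self.theta.lengthscales)}

    def summary(self) -> str:
        lines = [
            "Gaussian Process Regression Results",
            "=" * 43,
            f"No. observations: {self.nobs:>10d}   input dim: {self.model.ndim}",
            f"Log marginal likelihood: {self.llf:.4f}",
            f"sigma_s^2: {self.theta.sigma_s2:.6g}",
            f"sigma_n^2: {self.theta.sigma_n2:.6g}",
            "-" * 43,
            f"{'input':<12}{'lengthscale':>14}{'relevance':>14}",
        ]
        for name, ls in zip(self.model.input_names, self.theta.lengthscales):
            lines.append(f"{name:<12}{ls:>14.6g}{1.0 / ls:>14.6g}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "theta": {
                "sigma_s2": self.theta.sigma_s2,
                "lengthscales": self.theta.lengthscales.tolist(),
                "sigma_n2": self.theta.sigma_n2,
            },
            "X": self.model.X.tolist(),
            "y_centered": (self.model.y - self.y_center).tolist(),
            "y_center": self.y_center,
            "input_names": self.model.input_names,
            "metadata": self.model.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "GPRResults":
        with open(path) as fh:
            doc = json.load(fh)
        y = np.asarray(doc["y_centered"]) + doc["y_center"]
        model = GaussianProcess(np.asarray(doc["X"]), y,
                                input_names=doc.get("input_names"),
                                metadata=doc.get("metadata"))
        t = doc["theta"]
        theta = GPRHyperparams(t["sigma_s2"], np.asarray(t["lengthscales"]),
                               t["sigma_n2"])
        return cls(model, theta)


def fit_gpr(X, y, init: GPRHyperparams | None = None, bounds=None,
            n_restarts: int = 3, seed: int = 0, **kw) -> GPRResults:
    """Convenience: build a GaussianProcess and train it."""
    return GaussianProcess(X, y, **kw).fit(init=init, bounds=bounds,
                                           n_restarts=n_restarts, seed=seed)


def log_marginal_likelihood(results: GPRResults) -> float:
    return results.llf
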