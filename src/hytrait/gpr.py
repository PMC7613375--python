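"""Gaussian process regression with the ARD Rational Quadratic kernel.

The regressor at the heart of the retrieval workflow.  A zero-mean GP prior
(after target centering) with the automatic-relevance-determination (ARD)
Rational Quadratic covariance

    K(x_i, x_j) = sigma_f^2 (1 + (1/2 alpha) sum_m (x_im - x_jm)^2 / l_m^2)^(-alpha)

is combined with i.i.d. Gaussian observation noise sigma_n^2.  Hyperparameters
are selected by type-II maximum likelihood (evidence maximization) in
log-parameter space with analytic gradients and multi-start L-BFGS.  The
predictive distribution is analytic:

    mu*     = k*^T (K + sigma_n^2 I)^-1 y
    sigma*^2 = k** - k*^T (K + sigma_n^2 I)^-1 k*

The fitted per-feature lengthscales l_m^2 double as a band-relevance measure:
a large lengthscale means the output is insensitive to that feature, so
relevance is reported as r_m = 100 (1 - l_m^2 / max_m l_m^2) (or, optionally,
normalized by the sum of the lengthscales).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .errors import NumericalError, ValidationError

__all__ = ["GPRHyperparams", "GPRModel", "Prediction", "kernel_matrix",
           "log_marginal_likelihood", "fit", "predict", "band_relevance"]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

#: Box constraints on every log-parameter during evidence maximization —
#: wide enough to be inactive for any reasonable fit, tight enough to keep
#: exp() finite (e^30 ~ 1e13).
_LOG_BOUND = (-30.0, 30.0)


@dataclass
class GPRHyperparams:
    """ARD Rational Quadratic kernel + noise hyperparameters.

    ``lengthscales2`` stores the squared per-feature lengthscales l_m^2
    (the quantity the relevance measure is defined on).
    """

    signal_var: float            # sigma_f^2
    alpha_mix: float             # mixture exponent alpha > 0
    lengthscales2: np.ndarray    # l_m^2, shape (B,)
    noise_var: float             # sigma_n^2

    def __post_init__(self):
        self.lengthscales2 = np.asarray(self.lengthscales2, dtype=float)
        if self.signal_var <= 0 or self.alpha_mix <= 0 or self.noise_var < 0:
            raise ValidationError("signal_var and alpha_mix must be > 0, noise_var >= 0")
        if np.any(self.lengthscales2 <= 0):
            raise ValidationError("lengthscales must be strictly positive")

    @property
    def n_features(self) -> int:
        return self.lengthscales2.size

    def to_vector(self) -> np.ndarray:
        """Pack as log-parameters [log sf2, log alpha, log l2_1..B, log sn2]."""
        return np.concatenate([
            [np.log(self.signal_var), np.log(self.alpha_mix)],
            np.log(self.lengthscales2),
            [np.log(max(self.noise_var, 1e-12))],
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "GPRHyperparams":
        v = np.clip(np.asarray(v, dtype=float), _LOG_BOUND[0], _LOG_BOUND[1])
        return cls(signal_var=float(np.exp(v[0])), alpha_mix=float(np.exp(v[1])),
                   lengthscales2=np.exp(v[2:-1]), noise_var=float(np.exp(v[-1])))


def kernel_matrix(X_a, X_b, theta: GPRHyperparams) -> np.ndarray:
    """Evaluate the ARD-RQ kernel between two sample sets."""
    X_a = np.atleast_2d(np.asarray(X_a, float))
    X_b = np.atleast_2d(np.asarray(X_b, float))
    if X_a.shape[1] != theta.n_features or X_b.shape[1] != theta.n_features:
        raise ValidationError(
            f"feature dimension mismatch: inputs have {X_a.shape[1]}/{X_b.shape[1]} "
            f"features, kernel has {theta.n_features} lengthscales"
        )
    q = _scaled_sqdist(X_a, X_b, theta.lengthscales2)
    return theta.signal_var * (1.0 + q / (2.0 * theta.alpha_mix)) ** (-theta.alpha_mix)


def _scaled_sqdist(X_a, X_b, l2):
    """sum_m (x_im - x_jm)^2 / l_m^2 for all pairs, clipped at 0."""
    A = X_a / np.sqrt(l2)
    B = X_b / np.sqrt(l2)
    q = (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * A @ B.T
    return np.clip(q, 0.0, None)


def _chol_with_jitter(K_y, signal_var):
    """Cholesky with an escalating jitter ladder on failure."""
    jitters = [0.0, 1e-10, 1e-8, 1e-6]
    for j in jitters:
        try:
            return cho_factor(K_y + j * signal_var * np.eye(K_y.shape[0]), lower=True), j
        except np.linalg.LinAlgError:
            continue
    raise NumericalError(
        "covariance matrix stayed non-positive-definite after jitter escalation "
        f"(n={K_y.shape[0]}, max jitter {jitters[-1]:.0e} x signal variance)"
    )


def log_marginal_likelihood(X, y, theta: GPRHyperparams, with_grad: bool = False):
    """Gaussian evidence of centered targets y under K(theta) + sigma_n^2 I.

    With ``with_grad=True`` also returns the gradient with respect to the
    log-parameter vector (order matching :meth:`GPRHyperparams.to_vector`).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    l2 = theta.lengthscales2
    q = _scaled_sqdist(X, X, l2)
    u = 1.0 + q / (2.0 * theta.alpha_mix)
    K = theta.signal_var * u ** (-theta.alpha_mix)
    K_y = K + theta.noise_var * np.eye(n)
    cf, _ = _chol_with_jitter(K_y, theta.signal_var)
    alpha_vec = cho_solve(cf, y)
    L = np.tril(cf[0])
    lml = -0.5 * y @ alpha_vec - np.log(np.diag(L)).sum() - 0.5 * n * _LOG2PI
    if not with_grad:
        return lml
    # d lml / d theta_k = 0.5 tr((alpha alpha^T - K_y^-1) dK_y/dtheta_k)
    Kinv = cho_solve(cf, np.eye(n))
    W = np.outer(alpha_vec, alpha_vec) - Kinv
    grad = np.empty(theta.n_features + 3)
    grad[0] = 0.5 * (W * K).sum()                       # d/d log sigma_f^2
    logu = np.log(u)
    dK_dalpha = K * (-logu + q / (2.0 * theta.alpha_mix * u))
    grad[1] = 0.5 * (W * dK_dalpha).sum() * theta.alpha_mix  # d/d log alpha
    Ku = K / u
    WKu = W * Ku
    for m in range(theta.n_features):
        d = X[:, m][:, None] - X[:, m][None, :]
        # d/d log l_m = K/u * D_m / l_m^2  (note: log of l_m^2 gives half)
        grad[2 + m] = 0.25 * (WKu * (d * d)).sum() / l2[m]
    grad[-1] = 0.5 * np.trace(W) * theta.noise_var      # d/d log sigma_n^2
    return lml, grad


@dataclass
class GPRModel:
    """Trained GP regressor with cached factorization and weight vector."""

    X: np.ndarray                      # standardized training inputs (N x B)
    y_centered: np.ndarray             # centered training targets
    theta: GPRHyperparams
    x_mean: np.ndarray                 # per-feature standardization constants
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray = field(repr=False, default=None)  # (K+sn2 I)^-1 y
    _chol: tuple = field(repr=False, default=None)
    lml: float = np.nan

    def __post_init__(self):
        if self.weights is None:
            self._refactor()

    def _refactor(self):
        K = kernel_matrix(self.X, self.X, self.theta)
        K_y = K + self.theta.noise_var * np.eye(self.X.shape[0])
        cf, _ = _chol_with_jitter(K_y, self.theta.signal_var)
        self._chol = cf
        self.weights = cho_solve(cf, self.y_centered)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def standardize(self, X_raw) -> np.ndarray:
        X_raw = np.atleast_2d(np.asarray(X_raw, float))
        if X_raw.shape[1] != self.n_features:
            raise ValidationError(
                f"input has {X_raw.shape[1]} features, model expects {self.n_features}"
            )
        return (X_raw - self.x_mean) / self.x_scale

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta": {
                "signal_var": self.theta.signal_var,
                "alpha_mix": self.theta.alpha_mix,
                "lengthscales2": self.theta.lengthscales2.tolist(),
                "noise_var": self.theta.noise_var,
            },
            "X": self.X.tolist(),
            "y_centered": self.y_centered.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "lml": None if np.isnan(self.lml) else self.lml,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPRModel":
        th = GPRHyperparams(
            signal_var=d["theta"]["signal_var"],
            alpha_mix=d["theta"]["alpha_mix"],
            lengthscales2=np.asarray(d["theta"]["lengthscales2"]),
            noise_var=d["theta"]["noise_var"],
        )
        return cls(X=np.asarray(d["X"]), y_centered=np.asarray(d["y_centered"]),
                   theta=th, x_mean=np.asarray(d["x_mean"]),
                   x_scale=np.asarray(d["x_scale"]), y_mean=float(d["y_mean"]),
                   lml=d.get("lml") if d.get("lml") is not None else np.nan)

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GPRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Prediction:
    """Predictive mean, variance, SD and relative uncertainty per query row."""

    mean: np.ndarray
    variance: np.ndarray
    sd: np.ndarray
    cv_percent: np.ndarray  # 100 SD / |mean|; NaN where mean == 0


def _default_init(X, y) -> GPRHyperparams:
    var_y = max(float(np.var(y)), 1e-12)
    sd_x = X.std(axis=0)
    l2 = np.where(sd_x > 1e-12, sd_x, 1.0) ** 2
    return GPRHyperparams(signal_var=var_y, alpha_mix=1.0,
                          lengthscales2=l2, noise_var=0.01 * var_y)


def fit(X, y, init: GPRHyperparams | None = None, restarts: int = 3,
        seed: int = 0, maxiter: int = 200, standardize: bool = True,
        fixed_noise: float | None = None) -> GPRModel:
    """Train a GP regressor by multi-start evidence maximization.

    Features are z-scored and targets centered with training statistics (the
    constants are stored so predictions come back in original units).
    ``fixed_noise`` pins sigma_n^2 (in centered-target units) instead of
    optimizing it — used for noiseless interpolation studies.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("X and y disagree on sample count")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("training data must be finite")

    if standardize:
        x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        x_scale = np.where(sd > 1e-12, sd, 1.0)
    else:
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    theta0 = init if init is not None else _default_init(Xs, yc)
    if fixed_noise is not None:
        theta0 = GPRHyperparams(theta0.signal_var, theta0.alpha_mix,
                                theta0.lengthscales2, fixed_noise)

    noise_fixed = fixed_noise is not None

    def pack(th):
        v = th.to_vector()
        return v[:-1] if noise_fixed else v

    def unpack(v):
        if noise_fixed:
            v = np.concatenate([v, [np.log(max(fixed_noise, 1e-300))]])
            th = GPRHyperparams.from_vector(v)
            th.noise_var = fixed_noise
            return th
        return GPRHyperparams.from_vector(v)

    def objective(v):
        th = unpack(v)
        try:
            lml, g = log_marginal_likelihood(Xs, yc, th, with_grad=True)
        except NumericalError:
            return 1e25, np.zeros_like(v)
        g = g if not noise_fixed else g[:-1]
        return -lml, -g

    rng = np.random.default_rng(seed)
    best_v, best_f = None, np.inf
    v0 = pack(theta0)
    starts = [v0] + [v0 + rng.normal(0.0, 0.7, v0.size) for _ in range(max(restarts - 1, 0))]
    converged = False
    for s in starts:
        res = minimize(objective, s, jac=True, method="L-BFGS-B",
                       bounds=[_LOG_BOUND] * s.size,
                       options={"maxiter": maxiter})
        if res.fun < best_f:
            best_f, best_v = res.fun, res.x
            # status 1 is the deliberate iteration cap; status 2 with a
            # finite objective is a line-search stall on a flat evidence
            # surface — both leave a usable optimum.
            converged = converged or res.success or (
                res.status in (1, 2) and np.isfinite(res.fun))
    if not converged or not np.isfinite(best_f):
        log.warning("GPR evidence optimization did not converge; "
                    "returning best-found hyperparameters (neg-lml %.4g)", best_f)
    theta = unpack(best_v)
    model = GPRModel(X=Xs, y_centered=yc, theta=theta, x_mean=x_mean,
                     x_scale=x_scale, y_mean=y_mean, lml=-best_f)
    return model


def refit_weights(model: GPRModel, X_raw, y) -> GPRModel:
    """New model on different data but the *same* hyperparameters.

    Only the kernel factorization and weight vector are recomputed — an exact
    operation given theta.  Used inside the active-learning loop where full
    evidence re-optimization at every proposal would be wasteful.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, float))
    y = np.asarray(y, float).ravel()
    Xs = (X_raw - model.x_mean) / model.x_scale
    y_mean = float(y.mean())
    return GPRModel(X=Xs, y_centered=y - y_mean, theta=model.theta,
                    x_mean=model.x_mean, x_scale=model.x_scale, y_mean=y_mean)


def predict(model: GPRModel, X_star) -> Prediction:
    """Analytic GP posterior mean and variance at query points."""
    Xs = model.standardize(X_star)
    k_star = kernel_matrix(Xs, model.X, model.theta)       # (M, N)
    mean = k_star @ model.weights + model.y_mean
    v = cho_solve(model._chol, k_star.T)                   # (N, M)
    k_ss = model.theta.signal_var                          # k(x*, x*) at zero distance
    var = k_ss - np.einsum("mn,nm->m", k_star, v)
    neg = var < 0
    if np.any(neg):
        if np.any(var < -1e-8 * model.theta.signal_var):
            warnings.warn("predictive variance clipped at 0 (numerically negative)",
                          stacklevel=2)
        var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, 100.0 * sd / np.abs(mean), np.nan)
    return Prediction(mean=mean, variance=var, sd=sd, cv_percent=cv)


def band_relevance(model: GPRModel, normalize: str = "max") -> np.ndarray:
    """Per-feature relevance r_m in [0, 100] from the fitted ARD lengthscales.

    The squared lengthscale l_m^2 is inversely proportional to the relevance
    of feature m (a huge lengthscale flattens the kernel along that axis).

    normalize="max":  r_m = 100 (1 - l_m^2 / max_m l_m^2)   (default)
    normalize="sum":  r_m = 100 (1 - l_m^2 / sum_m l_m^2)
    """
    l2 = model.theta.lengthscales2
    if l2.size == 1:
        warnings.warn("single-feature model: relevance is 0 by convention",
                      stacklevel=2)
        return np.zeros(1)
    if normalize == "max":
        return 100.0 * (1.0 - l2 / l2.max())
    if normalize == "sum":
        return 100.0 * (1.0 - l2 / l2.sum())
    raise ValidationError(f"unknown relevance normalization {normalize!r}")
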