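"""Circular statistics and a von Mises mixture model with BIC selection.

Relative walking phase lives on the circle, so population summaries use the
mean resultant vector: for angles θ_1..θ_n the circular mean is
arg(Σ e^{iθ}) and the circular variance is 1 − R̄ where R̄ is the mean
resultant length.  The population distribution of per-pair mean phases is
modelled as a mixture of von Mises components vM(μ, κ) — the circular
analogue of a Gaussian mixture — fitted by EM, with the number of
components chosen by BIC over K = 1..4.

All angles are wrapped to the half-open interval (−π, π], with −π mapping
to +π.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e
from sklearn.base import BaseEstimator, DensityMixin

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) to (−π, π]; wrap(−π) = π."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite")
    wrapped = np.pi - np.mod(np.pi - theta, TWO_PI)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def _resultant(angles, weights=None):
    """Summed phasor components (C, S) and the total weight."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        return np.cos(angles).sum(), np.sin(angles).sum(), float(angles.size)
    w = np.asarray(weights, dtype=float)
    return (w * np.cos(angles)).sum(), (w * np.sin(angles)).sum(), float(w.sum())


def circular_mean(angles, weights=None, eps: float = 1e-9) -> float:
    """Direction of the mean unit phasor; undefined when the resultant
    nearly vanishes (e.g. {0, π})."""
    c, s, tot = _resultant(angles, weights)
    if np.hypot(c, s) / tot <= eps:
        raise ValueError("circular mean undefined: mean resultant length ~ 0")
    return wrap_angle(np.arctan2(s, c))


def circular_variance(angles, weights=None) -> float:
    """1 − mean resultant length, in [0, 1]; 0 iff all angles coincide."""
    c, s, tot = _resultant(angles, weights)
    return float(min(max(1.0 - np.hypot(c, s) / tot, 0.0), 1.0))


def vm_logpdf(theta, mu: float, kappa: float):
    """Log density of vM(μ, κ).

    κ·cos(θ−μ) − ln(2π·I0(κ)), computed with the exponentially scaled
    Bessel function so large κ stays finite.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    theta = np.asarray(theta, dtype=float)
    log_norm = np.log(TWO_PI) + np.log(i0e(kappa)) + kappa
    out = kappa * np.cos(theta - mu) - log_norm
    return float(out) if out.ndim == 0 else out


def _a1(kappa: float) -> float:
    """A1(κ) = I1(κ)/I0(κ), the mean resultant length of vM(·, κ)."""
    return i1e(kappa) / i0e(kappa)


def _a1_inv(rbar: float, kappa_max: float = 1e3) -> float:
    """Invert the monotone A1 (Banerjee starting value + Newton), capped."""
    if rbar <= 0.0:
        return 0.0
    if rbar >= _a1(kappa_max):
        return kappa_max
    k = rbar * (2.0 - rbar**2) / (1.0 - rbar**2)  # classic approximation
    k = min(max(k, 1e-12), kappa_max)
    for _ in range(25):
        a = _a1(k)
        # dA1/dκ = 1 − A1/κ − A1²
        deriv = 1.0 - a / k - a * a
        if deriv <= 0:
            break
        step = (a - rbar) / deriv
        k_new = min(max(k - step, 1e-12), kappa_max)
        if abs(k_new - k) < 1e-12 * (1.0 + k):
            k = k_new
            break
        k = k_new
    return k


def _logsumexp_rows(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=1)
    return mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))


@dataclass(frozen=True)
class VonMisesComponent:
    mu: float  # mean direction, radians in (−π, π]
    kappa: float  # concentration >= 0
    weight: float  # mixing proportion


@dataclass(frozen=True)
class VonMisesMixtureFit:
    components: tuple[VonMisesComponent, ...]
    log_likelihood: float
    bic: float
    n: int
    converged: bool
    seed: int
    n_iter: int = 0
    bic_table: dict = field(default_factory=dict)  # K -> BIC, filled by select_model

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def kappas(self) -> np.ndarray:
        return np.array([c.kappa for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


class VonMisesMixture(DensityMixin, BaseEstimator):
    """Mixture of von Mises distributions on the circle, fitted by EM.

    Parameters
    ----------
    n_components : int
        Number of mixture components K.
    n_init : int
        Seeded random restarts; the fit with the best log-likelihood wins.
    max_iter, tol : int, float
        EM stops when the log-likelihood improves by less than ``tol`` or
        after ``max_iter`` iterations.
    kappa_max : float
        Numerical cap on the concentration parameter.
    random_state : int or None
        Base seed for the restarts.

    Attributes (after ``fit``)
    --------------------------
    means_, concentrations_, weights_ : (K,) arrays
    log_likelihood_ : float (nats)
    bic_ : float, (3K − 1)·ln n − 2·log_likelihood
    converged_ : bool
    n_iter_ : int, iterations of the winning restart
    """

    def __init__(self, n_components: int = 1, n_init: int = 20, max_iter: int = 500,
                 tol: float = 1e-8, kappa_max: float = 1e3, random_state: int | None = None):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.kappa_max = kappa_max
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _component_loglik(self, theta, means, kappas, weights):
        """(n, K) matrix of log(w_k) + log vM(θ | μ_k, κ_k)."""
        log_norm = np.log(TWO_PI) + np.log(i0e(kappas)) + kappas
        return (
            np.log(np.maximum(weights, 1e-300))[None, :]
            + kappas[None, :] * np.cos(theta[:, None] - means[None, :])
            - log_norm[None, :]
        )

    def _em(self, theta, rng):
        n, K = theta.size, self.n_components
        means = theta[rng.integers(0, n, size=K)]
        kappas = np.ones(K)
        weights = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            logp = self._component_loglik(theta, means, kappas, weights)
            norm = _logsumexp_rows(logp)
            ll = float(norm.sum())
            if ll < prev_ll - 1e-7:
                raise RuntimeError("EM log-likelihood decreased — implementation bug")
            if ll - prev_ll < self.tol:
                converged = True
                break
            prev_ll = ll
            resp = np.exp(logp - norm[:, None])
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            weights = nk / n
            S = resp.T @ np.sin(theta)
            C = resp.T @ np.cos(theta)
            means = np.arctan2(S, C)
            rbar = np.sqrt(S**2 + C**2) / nk
            kappas = np.array([_a1_inv(min(r, 1.0 - 1e-12), self.kappa_max) for r in rbar])
        return means, kappas, weights, ll, converged, it

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y=None):
        theta = np.asarray(X, dtype=float).reshape(-1)
        theta = wrap_angle(theta)
        n, K = theta.size, self.n_components
        if n < 3 * K:
            raise ValueError(f"need at least 3K = {3 * K} angles, got {n}")
        base = 0 if self.random_state is None else int(self.random_state)
        best = None
        for restart in range(self.n_init):
            rng = np.random.default_rng((base + restart) % (2**31))
            out = self._em(theta, rng)
            if best is None or out[3] > best[3]:
                best = out
        means, kappas, weights, ll, converged, n_iter = best
        order = np.argsort(wrap_angle(means))
        self.means_ = wrap_angle(means[order])
        self.concentrations_ = kappas[order]
        self.weights_ = weights[order]
        self.log_likelihood_ = ll
        self.n_samples_ = n
        self.bic_ = (3 * K - 1) * np.log(n) - 2 * ll
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    def score_samples(self, X):
        theta = wrap_angle(np.asarray(X, dtype=float).reshape(-1))
        logp = self._component_loglik(theta, self.means_, self.concentrations_, self.weights_)
        return _logsumexp_rows(logp)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def predict_proba(self, X):
        theta = wrap_angle(np.asarray(X, dtype=float).reshape(-1))
        logp = self._component_loglik(theta, self.means_, self.concentrations_, self.weights_)
        return np.exp(logp - _logsumexp_rows(logp)[:, None])

    def to_fit(self, seed: int = 0, bic_table: dict | None = None) -> VonMisesMixtureFit:
        comps = tuple(
            VonMisesComponent(float(m), float(k), float(w))
            for m, k, w in zip(self.means_, self.concentrations_, self.weights_)
        )
        return VonMisesMixtureFit(
            components=comps,
            log_likelihood=float(self.log_likelihood_),
            bic=float(self.bic_),
            n=int(self.n_samples_),
            converged=bool(self.converged_),
            seed=seed,
            n_iter=int(self.n_iter_),
            bic_table=dict(bic_table or {}),
        )


def fit_vm_mixture(angles, K: int, n_restarts: int = 20, seed: int = 0) -> VonMisesMixtureFit:
    """Fit a K-component von Mises mixture (best of ``n_restarts`` EM runs)."""
    est = VonMisesMixture(n_components=K, n_init=n_restarts, random_state=seed)
    est.fit(angles)
    return est.to_fit(seed=seed)


def select_model(angles, k_max: int = 4, n_restarts: int = 20, seed: int = 0) -> VonMisesMixtureFit:
    """Fit K = 1..k_max mixtures and return the one with minimal BIC.

    The full BIC table is kept on the returned fit for reporting.
    """
    fits = {K: fit_vm_mixture(angles, K, n_restarts=n_restarts, seed=seed + 1000 * K) for K in range(1, k_max + 1)}
    table = {K: f.bic for K, f in fits.items()}
    best_K = min(table, key=table.get)
    best = fits[best_K]
    return VonMisesMixtureFit(
        components=best.components,
        log_likelihood=best.log_likelihood,
        bic=best.bic,
        n=best.n,
        converged=best.converged,
        seed=best.seed,
        n_iter=best.n_iter,
        bic_table=table,
    )


def sample_vm_mixture(n: int, means, kappas, weights, rng: np.random.Generator) -> np.ndarray:
    """Draw angles from a von Mises mixture (for simulations and tests)."""
    means = np.asarray(means, float)
    kappas = np.asarray(kappas, float)
    weights = np.asarray(weights, float)
    comp = rng.choice(len(means), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for k in range(len(means)):
        m = comp == k
        if kappas[k] == 0:
            out[m] = rng.uniform(-np.pi, np.pi, size=m.sum())
        else:
            out[m] = rng.vonmises(means[k], kappas[k], size=m.sum())
    return wrap_angle(out)
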