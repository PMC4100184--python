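"""Log-densities, normalizers and samplers for the non-Gaussian families.

The toolkit models DNA methylation beta-values (bounded in [0,1]) with beta
and gamma laws, and unit-norm embedded features with the von Mises-Fisher
(directional) and Watson (axial) distributions on the hypersphere.  All
quantities are evaluated in log-space: concentrations up to several hundred
(the regime illustrated by highly concentrated spherical samples) overflow
any naive evaluation of the Bessel / Kummer normalizing constants.

Conventions
-----------
* ``gamma_logpdf`` uses the shape/rate parameterisation (mean = k/theta).
* vMF concentration is written ``lam`` (lambda), Watson concentration
  ``kappa``; Watson ``kappa`` may be negative (girdle form).
* Direction vectors are validated to unit l2 norm at tolerance 1e-8 and
  silently re-normalized within that tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ive, logsumexp

__all__ = [
    "BetaShape",
    "GammaShapeRate",
    "VmfParams",
    "WatsonParams",
    "beta_logpdf",
    "gamma_logpdf",
    "log_kummer_1f1",
    "vmf_log_normalizer",
    "vmf_logpdf",
    "watson_log_normalizer",
    "watson_logpdf",
    "sample_vmf",
    "sample_watson",
    "sample_uniform_sphere",
]

_UNIT_TOL = 1e-8


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class BetaShape:
    """Two positive shape parameters (u, v) of a beta law."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (self.u > 0 and self.v > 0):
            raise ValueError(f"beta shapes must be positive, got u={self.u}, v={self.v}")


@dataclass(frozen=True)
class GammaShapeRate:
    """Gamma law with shape ``k`` and rate ``theta``; mean k/theta."""

    k: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.theta > 0):
            raise ValueError(f"gamma parameters must be positive, got k={self.k}, theta={self.theta}")


def _as_unit(mu: np.ndarray, name: str) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    nrm = float(np.linalg.norm(mu))
    if abs(nrm - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be unit l2 norm (|1-norm|={abs(nrm - 1.0):.2e} > {_UNIT_TOL})")
    return mu / nrm


@dataclass(frozen=True)
class VmfParams:
    """von Mises-Fisher parameters: unit mean direction and concentration >= 0."""

    mu: np.ndarray
    lam: float
    K: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _as_unit(self.mu, "mu"))
        object.__setattr__(self, "K", int(self.mu.shape[0]))
        if self.K < 2:
            raise ValueError("vMF requires dimension K >= 2")
        if self.lam < 0:
            raise ValueError("vMF concentration must be nonnegative")


@dataclass(frozen=True)
class WatsonParams:
    """Watson parameters: unit mean axis and real concentration (either sign).

    kappa > 0 concentrates probability around the +/-mu axis; kappa < 0
    concentrates it around the great circle orthogonal to mu.
    """

    mu: np.ndarray
    kappa: float
    p: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _as_unit(self.mu, "mu"))
        object.__setattr__(self, "p", int(self.mu.shape[0]))
        if self.p < 2:
            raise ValueError("Watson requires ambient dimension p >= 2")


# ---------------------------------------------------------------------------
# scalar log-densities


def beta_logpdf(x, shape: BetaShape):
    """Log-density of Beta(u, v) at ``x`` in (0, 1), via log-gamma only."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("beta_logpdf requires 0 < x < 1 (clip beta-values first)")
    u, v = shape.u, shape.v
    out = (
        gammaln(u + v) - gammaln(u) - gammaln(v)
        + (u - 1.0) * np.log(x) + (v - 1.0) * np.log1p(-x)
    )
    return out if out.ndim else float(out)


def gamma_logpdf(x, par: GammaShapeRate):
    """Log-density of Gamma(shape k, rate theta) at ``x`` > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("gamma_logpdf requires x > 0")
    k, th = par.k, par.theta
    out = k * np.log(th) - gammaln(k) + (k - 1.0) * np.log(x) - th * x
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Kummer's confluent hypergeometric function, log-space


def log_kummer_1f1(r: float, p: float, kappa: float) -> float:
    """``ln 1F1(r, p, kappa)`` by log-sum-exp over the ascending series.

    Stable for |kappa| up to (at least) several hundred.  Negative arguments
    go through the Kummer transformation ``1F1(r,p,k) = e^k 1F1(p-r,p,-k)``
    so the accumulated series always has positive terms.
    """
    r, p, kappa = float(r), float(p), float(kappa)
    if p <= 0:
        raise ValueError("Kummer p-parameter must be positive")
    if kappa == 0.0:
        return 0.0
    if kappa < 0.0:
        if p - r <= 0:
            raise ValueError(
                f"log_kummer_1f1 does not converge via Kummer transform for r={r} >= p={p} with kappa<0"
            )
        return kappa + log_kummer_1f1(p - r, p, -kappa)
    if r <= 0:
        raise ValueError("log_kummer_1f1 requires r > 0 (series would alternate)")
    # terms t_j = (r)_j / (p)_j * kappa^j / j!; peak near j ~ kappa
    n_terms = int(kappa + 14.0 * np.sqrt(kappa + 1.0) + 80.0)
    j = np.arange(n_terms + 1, dtype=float)
    log_t = (
        gammaln(r + j) - gammaln(r)
        - (gammaln(p + j) - gammaln(p))
        + j * np.log(kappa) - gammaln(j + 1.0)
    )
    total = float(logsumexp(log_t))
    if log_t[-1] > total - 36.0:  # tail not negligible
        raise ArithmeticError(
            f"log_kummer_1f1 series truncated before convergence (r={r}, p={p}, kappa={kappa})"
        )
    return total


# ---------------------------------------------------------------------------
# directional normalizers and densities


def _log_sphere_area(K: int) -> float:
    # surface area of the unit (K-1)-sphere embedded in R^K
    return np.log(2.0) + (K / 2.0) * np.log(np.pi) - gammaln(K / 2.0)


def vmf_log_normalizer(K: int, lam: float) -> float:
    """``ln c_K(lam)`` for the vMF density c_K(lam) exp(lam mu.x).

    c_K(lam) = lam^{K/2-1} / ((2 pi)^{K/2} I_{K/2-1}(lam)); evaluated with the
    exponentially scaled Bessel function so lam = 400 does not overflow.  At
    lam = 0 this is the reciprocal surface area of the (K-1)-sphere.
    """
    K = int(K)
    if K < 2:
        raise ValueError("vMF dimension must be >= 2")
    if lam < 0:
        raise ValueError("vMF concentration must be nonnegative")
    if lam < 1e-12:
        return -_log_sphere_area(K)
    nu = K / 2.0 - 1.0
    scaled = ive(nu, lam)  # = I_nu(lam) * exp(-lam)
    return nu * np.log(lam) - (K / 2.0) * np.log(2.0 * np.pi) - (np.log(scaled) + lam)


def vmf_logpdf(x, par: VmfParams):
    """vMF log-density ``ln c_K(lam) + lam * mu.x`` for unit vector(s) x."""
    x = _validate_unit_rows(np.atleast_2d(np.asarray(x, dtype=float)))
    out = vmf_log_normalizer(par.K, par.lam) + par.lam * (x @ par.mu)
    return _maybe_scalar(out)


def watson_log_normalizer(p: int, kappa: float) -> float:
    """Log normalizer of the Watson density on the (p-1)-sphere.

    W_p(x; mu, kappa) = Gamma(p/2) / (2 pi^{p/2}) * 1F1(1/2, p/2, kappa)^{-1}
                        * exp(kappa (mu.x)^2)
    """
    p = int(p)
    if p < 2:
        raise ValueError("Watson dimension must be >= 2")
    return -_log_sphere_area(p) - log_kummer_1f1(0.5, p / 2.0, kappa)


def watson_logpdf(x, par: WatsonParams):
    """Axially symmetric Watson log-density; exact under x -> -x."""
    x = _validate_unit_rows(np.atleast_2d(np.asarray(x, dtype=float)))
    t2 = (x @ par.mu) ** 2
    out = watson_log_normalizer(par.p, par.kappa) + par.kappa * t2
    return _maybe_scalar(out)


def _maybe_scalar(out: np.ndarray):
    return float(out[0]) if out.shape == (1,) else out


def _validate_unit_rows(x: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(x, axis=-1)
    if np.any(np.abs(nrm - 1.0) > _UNIT_TOL):
        worst = float(np.max(np.abs(nrm - 1.0)))
        raise ValueError(f"inputs must be unit vectors (worst |1-norm| = {worst:.2e})")
    return x / nrm[..., None]


# ---------------------------------------------------------------------------
# samplers


def sample_uniform_sphere(K: int, n: int, rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_normal((n, K))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _tangent_frame(mu: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the tangent space at mu (columns orthogonal to mu)."""
    K = mu.shape[0]
    # Householder reflection mapping e1 -> mu; remaining columns span mu-perp
    e1 = np.zeros(K)
    e1[0] = 1.0
    w = mu - e1
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        H = np.eye(K)
    else:
        w = w / nw
        H = np.eye(K) - 2.0 * np.outer(w, w)
    return H[:, 1:]


def sample_vmf(par: VmfParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` unit vectors from vMF(mu, lam) (Ulrich/Wood rejection)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K, lam, mu = par.K, par.lam, par.mu
    if lam < 1e-12:
        return sample_uniform_sphere(K, n, rng)
    d = K - 1.0
    b = (-2.0 * lam + np.sqrt(4.0 * lam**2 + d**2)) / d
    x0 = (1.0 - b) / (1.0 + b)
    c = lam * x0 + d * np.log(1.0 - x0**2)
    ws = np.empty(0)
    while ws.size < n:
        m = max(2 * (n - ws.size), 64)
        z = rng.beta(d / 2.0, d / 2.0, size=m)
        w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.random(m)
        keep = lam * w + d * np.log1p(-x0 * w) - c >= np.log(u)
        ws = np.concatenate([ws, w[keep]])
    w = ws[:n]
    tangent = sample_uniform_sphere(K - 1, n, rng) if K > 2 else rng.choice([-1.0, 1.0], size=(n, 1))
    frame = _tangent_frame(mu)
    x = w[:, None] * mu[None, :] + np.sqrt(np.clip(1.0 - w**2, 0.0, None))[:, None] * (tangent @ frame.T)
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def sample_watson(par: WatsonParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` axial unit vectors from Watson(mu, kappa).

    The squared projection s = (mu.x)^2 has density proportional to
    s^{-1/2} (1-s)^{(p-3)/2} e^{kappa s}; it is drawn by rejection from
    Beta(1/2, (p-1)/2) with the exponential tilt as acceptance weight.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p, kap, mu = par.p, par.kappa, par.mu
    a, bpar = 0.5, (p - 1.0) / 2.0
    ss = np.empty(0)
    # acceptance weight e^{kappa(s-1)} (kappa>0) or e^{kappa s} (kappa<=0), both <= 1
    batch = max(4 * n, 256)
    while ss.size < n:
        s = rng.beta(a, bpar, size=batch)
        u = rng.random(batch)
        logw = kap * (s - 1.0) if kap > 0 else kap * s
        keep = np.log(u) <= logw
        ss = np.concatenate([ss, s[keep]])
        acc = max(keep.mean(), 1.0 / batch)
        batch = int(min(max((n - ss.size + 1) / acc * 1.5, 256), 2_000_000))
    s = np.clip(ss[:n], 0.0, 1.0)
    t = np.sqrt(s) * rng.choice([-1.0, 1.0], size=n)
    tangent = sample_uniform_sphere(p - 1, n, rng) if p > 2 else rng.choice([-1.0, 1.0], size=(n, 1))
    frame = _tangent_frame(mu)
    x = t[:, None] * mu[None, :] + np.sqrt(1.0 - s)[:, None] * (tangent @ frame.T)
    return x / np.linalg.norm(x, axis=1, keepdims=True)
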