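"""Beta-gamma nonnegative matrix factorization (BG-NMF) for bounded data.

Methylation beta-values live in [0,1], so the usual NMF "X ~ WV" story is a
model mismatch.  BG-NMF instead places the factorization one level up: each
entry X_pt is Beta(a_pt, b_pt) distributed, and the two beta shape-parameter
matrices factor through shared nonnegative bases,

    a ~ A H,    b ~ B H,

with independent gamma priors on every entry of A (P x K), B (P x K) and
H (K x T).  Posterior inference is variational: every factor is kept gamma,
and the intractable E[ln Gamma(.)] terms of the beta log-likelihood are
replaced by a first-order lower bound at the current posterior means
(together with a Jensen split of ln(sum_k A_pk H_kt)), which yields
closed-form shape/rate updates:

    shape(A_pk) = mu0 + Abar_pk * [Psi_a Hbar^T]_pk
    rate(A_pk)  = alpha0 + [(-ln X) Hbar^T]_pk

with Psi_a = psi(abar + bbar) - psi(abar) evaluated at the current mean
shape matrices abar = Abar Hbar, bbar = Bbar Hbar (and symmetrically for B
with ln(1-X), and for H collecting both sides).  A damped backtracking guard
keeps the recorded ELBO surrogate monotone.

The derived low-dimensional representation is the *pseudo-basis*

    Wbar = Abar / (Abar + Bbar),

whose entries stay in (0,1) — i.e. the reduction itself respects the bounded
support of the data, which is the point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi

__all__ = ["BGNMFPriors", "BGNMF", "BGNMFResults", "fit_bgnmf", "EPS"]

#: shared clipping constant for beta-values (single source of truth)
EPS = 1e-6


@dataclass(frozen=True)
class BGNMFPriors:
    """Gamma hyperparameters (shape, rate) for A, B and H entries.

    ``rho0 < 1`` puts a sparsity-inducing sub-unit gamma shape on the
    excitation matrix H, the mechanism behind the sparsity constraint on H
    columns that makes Wbar Hbar a faithful bounded reconstruction.
    """

    mu0: float = 1.0
    alpha0: float = 1.0
    nu0: float = 1.0
    beta0: float = 1.0
    rho0: float = 0.5
    zeta0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu0", "alpha0", "nu0", "beta0", "rho0", "zeta0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


@dataclass
class BGNMFResults:
    """Fitted gamma variational posterior of a BG-NMF model."""

    A_shape: np.ndarray
    A_rate: np.ndarray
    B_shape: np.ndarray
    B_rate: np.ndarray
    H_shape: np.ndarray
    H_rate: np.ndarray
    elbo_trace: np.ndarray
    K: int
    iterations_run: int
    converged: bool
    priors: BGNMFPriors
    row_ids: list | None = None
    col_ids: list | None = None

    @property
    def A_mean(self) -> np.ndarray:
        return self.A_shape / self.A_rate

    @property
    def B_mean(self) -> np.ndarray:
        return self.B_shape / self.B_rate

    @property
    def H_mean(self) -> np.ndarray:
        return self.H_shape / self.H_rate

    def reconstruct_mean(self) -> np.ndarray:
        """Posterior-mean reconstruction Xbar = (A H) / (A H + B H), in (0,1)."""
        a = self.A_mean @ self.H_mean
        b = self.B_mean @ self.H_mean
        return a / (a + b)

    def pseudo_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounded pseudo-basis Wbar = A/(A+B) in (0,1) and excitations Hbar."""
        A, B = self.A_mean, self.B_mean
        return A / (A + B), self.H_mean

    def summary(self) -> str:
        P, K = self.A_shape.shape
        T = self.H_shape.shape[1]
        W, _ = self.pseudo_basis()
        lines = [
            "BG-NMF variational posterior",
            "=" * 40,
            f"data shape           : {P} x {T}",
            f"inner dimension K    : {K}",
            f"iterations           : {self.iterations_run} (converged={self.converged})",
            f"final ELBO surrogate : {self.elbo_trace[-1]:.4f}",
            f"pseudo-basis range   : [{W.min():.4f}, {W.max():.4f}]",
        ]
        return "\n".join(lines)


class BGNMF:
    """BG-NMF model for a bounded matrix X (P rows x T columns, values in (0,1)).

    Parameters
    ----------
    X : array-like or pandas.DataFrame, shape (P, T)
        Bounded observations.  Entries must lie in [EPS, 1-EPS]; exact 0/1
        must be clipped by the caller (``methclust.io.read_beta_matrix``
        does this for files).
    n_components : int
        Inner dimension K, 1 <= K <= min(P, T).
    priors : BGNMFPriors, optional
    """

    def __init__(self, X, n_components: int, priors: BGNMFPriors | None = None):
        self.row_ids = self.col_ids = None
        if hasattr(X, "to_numpy"):  # DataFrame
            self.row_ids = list(X.index)
            self.col_ids = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if np.any(X <= 0.0) or np.any(X >= 1.0):
            raise ValueError(
                "X contains entries at or beyond 0/1; clip to [1e-6, 1-1e-6] before fitting"
            )
        P, T = X.shape
        K = int(n_components)
        if not 1 <= K <= min(P, T):
            raise ValueError(f"n_components must satisfy 1 <= K <= min(P,T)={min(P, T)}, got {K}")
        self.X = X
        self.K = K
        self.priors = priors or BGNMFPriors()

    # -- surrogate objective -------------------------------------------------

    def _surrogate(self, Am, Bm, Hm) -> float:
        """ELBO surrogate: beta log-likelihood at posterior means + log-priors."""
        pr = self.priors
        a = Am @ Hm
        b = Bm @ Hm
        ll = np.sum(
            gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1.0) * self._lx + (b - 1.0) * self._l1mx
        )
        lp = (
            np.sum((pr.mu0 - 1.0) * np.log(Am) - pr.alpha0 * Am)
            + np.sum((pr.nu0 - 1.0) * np.log(Bm) - pr.beta0 * Bm)
            + np.sum((pr.rho0 - 1.0) * np.log(Hm) - pr.zeta0 * Hm)
        )
        return float(ll + lp)

    def _init_means(self, rng: np.random.Generator):
        X, K = self.X, self.K
        m = X.mean(axis=1)
        s2 = X.var(axis=1)
        conc = np.clip(m * (1.0 - m) / np.maximum(s2, 1e-8) - 1.0, 0.1, 1e4)
        a_row = np.clip(m * conc, 1e-3, None)
        b_row = np.clip((1.0 - m) * conc, 1e-3, None)
        Hm = rng.gamma(1.0, 1.0, size=(K, X.shape[1])) + 1e-3
        Hm /= Hm.sum(axis=0, keepdims=True)  # column sums 1 so a ~ AH matches row fits
        jitter = rng.uniform(0.7, 1.3, size=(X.shape[0], K))
        Am = a_row[:, None] * jitter
        Bm = b_row[:, None] * jitter
        return Am, Bm, Hm

    def fit(self, max_iter: int = 500, tol: float = 1e-5, seed: int = 0) -> BGNMFResults:
        """Run the variational sweeps (A -> B -> H per sweep) until the
        relative change of the ELBO surrogate drops below ``tol``."""
        pr = self.priors
        X = self.X
        self._lx = np.log(X)
        self._l1mx = np.log1p(-X)
        rng = np.random.default_rng(seed)
        Am, Bm, Hm = self._init_means(rng)

        # posterior parameter matrices consistent with the initial means
        A_sh = np.full_like(Am, pr.mu0) + Am
        A_rt = A_sh / Am
        B_sh = np.full_like(Bm, pr.nu0) + Bm
        B_rt = B_sh / Bm
        H_sh = np.full_like(Hm, pr.rho0) + Hm
        H_rt = H_sh / Hm

        neg_lx = -self._lx
        neg_l1mx = -self._l1mx
        trace = [self._surrogate(Am, Bm, Hm)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            a = Am @ Hm
            b = Bm @ Hm
            psi_ab = psi(a + b)
            Psi_a = psi_ab - psi(a)  # > 0
            Psi_b = psi_ab - psi(b)  # > 0

            nA_sh = pr.mu0 + Am * (Psi_a @ Hm.T)
            nA_rt = pr.alpha0 + neg_lx @ Hm.T
            nB_sh = pr.nu0 + Bm * (Psi_b @ Hm.T)
            nB_rt = pr.beta0 + neg_l1mx @ Hm.T
            nH_sh = pr.rho0 + Hm * (Am.T @ Psi_a + Bm.T @ Psi_b)
            nH_rt = pr.zeta0 + Am.T @ neg_lx + Bm.T @ neg_l1mx

            # damped backtracking on the surrogate (step=1 is the plain update)
            accepted = False
            for step in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
                cA_sh = A_sh ** (1 - step) * nA_sh**step
                cA_rt = A_rt ** (1 - step) * nA_rt**step
                cB_sh = B_sh ** (1 - step) * nB_sh**step
                cB_rt = B_rt ** (1 - step) * nB_rt**step
                cH_sh = H_sh ** (1 - step) * nH_sh**step
                cH_rt = H_rt ** (1 - step) * nH_rt**step
                cand = self._surrogate(cA_sh / cA_rt, cB_sh / cB_rt, cH_sh / cH_rt)
                if cand >= trace[-1] - 1e-9:
                    A_sh, A_rt, B_sh, B_rt, H_sh, H_rt = cA_sh, cA_rt, cB_sh, cB_rt, cH_sh, cH_rt
                    Am, Bm, Hm = A_sh / A_rt, B_sh / B_rt, H_sh / H_rt
                    trace.append(cand)
                    accepted = True
                    break
            if not accepted:  # no ascent direction left: stop at current point
                converged = True
                break
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0)
            if rel < tol:
                converged = True
                break

        return BGNMFResults(
            A_shape=A_sh, A_rate=A_rt, B_shape=B_sh, B_rate=B_rt,
            H_shape=H_sh, H_rate=H_rt,
            elbo_trace=np.asarray(trace), K=self.K, iterations_run=it,
            converged=converged, priors=pr,
            row_ids=self.row_ids, col_ids=self.col_ids,
        )


def fit_bgnmf(
    X,
    K: int,
    priors: BGNMFPriors | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> BGNMFResults:
    """Functional front-end: fit BG-NMF with inner dimension ``K``."""
    return BGNMF(X, K, priors=priors).fit(max_iter=max_iter, tol=tol, seed=seed)


def reconstruct_mean(post: BGNMFResults) -> np.ndarray:
    """Posterior-mean bounded reconstruction (see BGNMFResults.reconstruct_mean)."""
    return post.reconstruct_mean()


def pseudo_basis(post: BGNMFResults) -> tuple[np.ndarray, np.ndarray]:
    """Bounded pseudo-basis and excitation matrix (see BGNMFResults.pseudo_basis)."""
    return post.pseudo_basis()
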