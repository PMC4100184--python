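"""Variational mixture-model clusterers with automatic complexity control.

Five back-ends share one fit contract, matched to the geometry of the
reduced features they consume:

* ``GaussianMixtureVB``      - baseline for PCA scores (unbounded reals);
* ``BetaMixture``            - bounded (0,1) features, e.g. BG-NMF pseudo-basis rows;
* ``RecursiveBetaPartition`` - benchmark: recursive 1-vs-2 beta-mixture splits
  accepted by a responsibility-weighted BIC, leaves labelled by their split
  path ("rL", "rLR", ...);
* ``VonMisesFisherMixture``  - unit-norm features (spectral embedding columns);
* ``WatsonMixture``          - axial unit features (x and -x equivalent).

The variational fits place a sparse Dirichlet prior on the mixture weights;
after convergence, components whose weight falls below ``prune`` (default
0.01) are removed and the model is given one refit pass.  The surviving
count is the inferred number of clusters.

The beta mixture uses extended variational inference: gamma posteriors over
the beta shape parameters, with the intractable E[lnGamma] terms of the beta
likelihood lower-bounded to first order at the current posterior means —
exactly the scheme used by the BG-NMF module.  The directional mixtures
update mean directions/axes in closed form and solve the 1-D concentration
equations through the log-space Bessel/Kummer evaluations of
``methclust.distributions``.

Each fit records an ELBO surrogate per iteration (mixture log-likelihood at
posterior means plus log-priors); an iteration that would decrease the
surrogate is rejected and the fit stops there, so the recorded trace is
non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi, logsumexp
from sklearn.cluster import KMeans

from .distributions import (
    log_kummer_1f1,
    vmf_log_normalizer,
    watson_log_normalizer,
)

__all__ = [
    "MixtureResults",
    "GaussianMixtureVB",
    "BetaMixture",
    "RecursiveBetaPartition",
    "VonMisesFisherMixture",
    "WatsonMixture",
    "fit_vbgmm",
    "fit_vbbmm",
    "fit_rpbmm",
    "fit_vbvmm",
    "fit_vbwmm",
]

_SPARSE_DIRICHLET = 1e-3  # weight-prior concentration: sparse, prunes redundancy


@dataclass
class MixtureResults:
    """Family-tagged mixture fit: weights, parameters, responsibilities."""

    family: str
    weights: np.ndarray  # simplex over surviving components
    component_params: dict
    responsibilities: np.ndarray  # N x M_effective, rows sum to 1
    labels: np.ndarray  # 1-based component assignment per observation
    M_effective: int
    elbo_trace: np.ndarray | None = None
    wtdbic_trace: list | None = None  # RPBMM only
    leaf_paths: list | None = None  # RPBMM only: split-path label per component
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"{self.family} mixture fit",
            "=" * 40,
            f"observations      : {self.responsibilities.shape[0]}",
            f"components kept   : {self.M_effective}",
            f"weights           : {np.round(self.weights, 4)}",
        ]
        if self.elbo_trace is not None and len(self.elbo_trace):
            lines.append(f"iterations        : {len(self.elbo_trace) - 1}")
            lines.append(f"final ELBO surr.  : {self.elbo_trace[-1]:.4f}")
        if self.leaf_paths is not None:
            lines.append(f"leaf paths        : {self.leaf_paths}")
        sizes = np.bincount(self.labels - 1, minlength=self.M_effective)
        lines.append(f"cluster sizes     : {sizes.tolist()}")
        return "\n".join(lines)


def _finalize(family, weights, params, resp, seed, elbo=None, **extra) -> MixtureResults:
    resp = resp / resp.sum(axis=1, keepdims=True)
    labels = np.argmax(resp, axis=1) + 1
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return MixtureResults(
        family=family,
        weights=w,
        component_params=params,
        responsibilities=resp,
        labels=labels,
        M_effective=resp.shape[1],
        elbo_trace=None if elbo is None else np.asarray(elbo),
        seed=seed,
        **extra,
    )


# ---------------------------------------------------------------------------
# weighted beta fitting helpers (shared by BetaMixture and RPBMM)


def _beta_suffstats(lx, l1mx, w):
    W = w.sum()
    return W, (w @ lx) / W, (w @ l1mx) / W  # mean ln x, mean ln(1-x) per dim


def _beta_ml_fixed_point(mlx, ml1mx, u0=None, v0=None, n_iter=100):
    """Weighted per-dimension beta maximum likelihood (damped Newton).

    Solves psi(u) - psi(u+v) = mean(ln x) and psi(v) - psi(u+v) =
    mean(ln(1-x)) jointly, vectorized over dimensions.
    """
    from scipy.special import polygamma

    # geometric-mean-based moment init (Minka-style)
    gx, g1mx = np.exp(mlx), np.exp(ml1mx)
    denom = np.maximum(1.0 - gx - g1mx, 1e-6)
    if u0 is None:
        u0 = np.clip(0.5 + gx / (2.0 * denom), 0.05, 1e5)
    if v0 is None:
        v0 = np.clip(0.5 + g1mx / (2.0 * denom), 0.05, 1e5)
    u, v = np.asarray(u0, dtype=float).copy(), np.asarray(v0, dtype=float).copy()
    for _ in range(n_iter):
        puv = polygamma(1, u + v)
        g1 = psi(u) - psi(u + v) - mlx
        g2 = psi(v) - psi(u + v) - ml1mx
        a = polygamma(1, u) - puv
        d = polygamma(1, v) - puv
        det = a * d - puv**2
        det = np.where(np.abs(det) < 1e-14, 1e-14, det)
        du = (d * g1 + puv * g2) / det
        dv = (puv * g1 + a * g2) / det
        # damp so parameters stay positive
        step = np.minimum(1.0, 0.9 * np.minimum(u / np.abs(du + 1e-300), v / np.abs(dv + 1e-300)))
        u = np.clip(u - step * du, 1e-3, 1e6)
        v = np.clip(v - step * dv, 1e-3, 1e6)
        if np.max(np.abs(g1)) + np.max(np.abs(g2)) < 1e-10:
            break
    return u, v


def _beta_loglik_matrix(lx, l1mx, U, V):
    """N x M log-likelihood, independent beta per dimension at means U, V (M x K)."""
    const = np.sum(gammaln(U + V) - gammaln(U) - gammaln(V), axis=1)  # M
    return const[None, :] + lx @ (U - 1.0).T + l1mx @ (V - 1.0).T


def _validate_bounded(Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be N x K")
    if np.any(Y <= 0.0) or np.any(Y >= 1.0):
        raise ValueError("entries at or beyond 0/1; clip to [1e-6, 1-1e-6] first")
    return Y


def _kmeans_resp(Y, M, seed, smoothing=1e-2):
    km = KMeans(n_clusters=min(M, Y.shape[0]), n_init=3, random_state=seed)
    lab = km.fit_predict(Y)
    resp = np.full((Y.shape[0], M), smoothing)
    resp[np.arange(Y.shape[0]), lab] = 1.0
    return resp / resp.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# variational beta mixture


class BetaMixture:
    """Variational Bayesian mixture of independent-dimension beta laws.

    Parameters
    ----------
    Y : array-like (N, K), entries in (0, 1)
    n_components : int
        Initial number of mixture components (pruned during fitting).
    prune : float
        Posterior-weight threshold below which a component is removed.
    """

    def __init__(self, Y, n_components: int = 15, prune: float = 0.01,
                 prior_shape: float = 1.0, prior_rate: float = 0.5):
        self.Y = _validate_bounded(Y)
        self.M_init = int(n_components)
        self.prune = float(prune)
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        if self.M_init < 1:
            raise ValueError("n_components must be >= 1")

    def _surrogate(self, lw, U, V, lx, l1mx):
        ll = logsumexp(lw[None, :] + _beta_loglik_matrix(lx, l1mx, U, V), axis=1).sum()
        lp = np.sum((self.prior_shape - 1.0) * np.log(U) - self.prior_rate * U)
        lp += np.sum((self.prior_shape - 1.0) * np.log(V) - self.prior_rate * V)
        return float(ll + lp)

    def _vb_loop(self, lx, l1mx, resp, max_iter, tol):
        N, K = lx.shape
        M = resp.shape[1]
        a0, b0 = self.prior_shape, self.prior_rate
        U = np.full((M, K), 2.0)
        V = np.full((M, K), 2.0)
        alpha = _SPARSE_DIRICHLET + resp.sum(axis=0)
        trace = []
        for it in range(max_iter):
            Nm = resp.sum(axis=0) + 1e-12
            Slx = resp.T @ lx  # M x K
            Sl1mx = resp.T @ l1mx
            # gamma posterior for each beta shape (extended VI bound)
            cu = U * (psi(U + V) - psi(U))
            cv = V * (psi(U + V) - psi(V))
            # gamma posterior: shape = a0 + c*N_m, rate = b0 - sum_n r_nm ln x_nk
            U_new = (a0 + Nm[:, None] * cu) / (b0 - Slx)
            V_new = (a0 + Nm[:, None] * cv) / (b0 - Sl1mx)
            U_new = np.clip(U_new, 1e-3, 1e6)
            V_new = np.clip(V_new, 1e-3, 1e6)
            alpha_new = _SPARSE_DIRICHLET + Nm
            lw_new = psi(alpha_new) - psi(alpha_new.sum())
            cand = self._surrogate(
                np.log(alpha_new / alpha_new.sum()), U_new, V_new, lx, l1mx
            )
            if trace and cand < trace[-1] - 1e-9:
                break
            U, V, alpha = U_new, V_new, alpha_new
            trace.append(cand)
            # E-step
            logr = lw_new[None, :] + _beta_loglik_matrix(lx, l1mx, U, V)
            logr -= logsumexp(logr, axis=1, keepdims=True)
            resp = np.exp(logr)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
                break
        return resp, U, V, alpha, trace

    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> MixtureResults:
        lx, l1mx = np.log(self.Y), np.log1p(-self.Y)
        resp = _kmeans_resp(self.Y, self.M_init, seed)
        resp, U, V, alpha, trace = self._vb_loop(lx, l1mx, resp, max_iter, tol)
        # prune by posterior weight, then one refit pass
        w = resp.sum(axis=0) / resp.shape[0]
        keep = np.flatnonzero(w >= self.prune)
        if keep.size == 0:
            keep = np.array([int(np.argmax(w))])
        if keep.size < resp.shape[1]:
            resp = resp[:, keep]
            resp /= resp.sum(axis=1, keepdims=True)
            # refit pass after pruning; the recorded trace is the refit's
            # (pruning changes the model, so traces are not comparable)
            resp, U, V, alpha, trace = self._vb_loop(lx, l1mx, resp, max_iter, tol)
        w = resp.sum(axis=0) / resp.shape[0]
        params = {"shape_u": U, "shape_v": V, "dirichlet": alpha,
                  "means": U / (U + V)}
        return _finalize("beta", w, params, resp, seed, elbo=np.asarray(trace))


# ---------------------------------------------------------------------------
# recursive partitioning beta mixture (benchmark)


class RecursiveBetaPartition:
    """Recursive binary beta-mixture partitioning scored by weighted BIC.

    At each node a 1-component and a 2-component independent-beta model are
    fitted by (weighted) EM; the node splits iff the responsibility-weighted
    BIC improves.  Leaves are the final clusters, labelled by their split
    path ("r" root, then "L"/"R").
    """

    def __init__(self, Y, max_depth: int = 8, min_weight: float = 4.0):
        self.Y = _validate_bounded(Y)
        self.max_depth = max_depth
        self.min_weight = min_weight

    def _node_fit1(self, lx, l1mx, w):
        W, mlx, ml1mx = _beta_suffstats(lx, l1mx, w)
        u, v = _beta_ml_fixed_point(mlx, ml1mx)
        ll = float(w @ _beta_loglik_matrix(lx, l1mx, u[None, :], v[None, :])[:, 0])
        k_free = 2 * lx.shape[1]
        bic = -2.0 * ll + k_free * np.log(W)
        return bic, (u, v)

    def _node_fit2(self, lx, l1mx, w, seed):
        N, K = lx.shape
        km = KMeans(n_clusters=2, n_init=3, random_state=seed)
        lab = km.fit(self.Y_node, sample_weight=w + 1e-9).predict(self.Y_node)
        resp = np.full((N, 2), 0.05)
        resp[np.arange(N), lab] = 1.0
        resp /= resp.sum(axis=1, keepdims=True)
        U = np.full((2, K), 2.0)
        V = np.full((2, K), 2.0)
        pi = np.array([0.5, 0.5])
        ll_prev = -np.inf
        for _ in range(200):
            wc = w[:, None] * resp
            Wc = wc.sum(axis=0) + 1e-12
            for c in range(2):
                _, mlx, ml1mx = _beta_suffstats(lx, l1mx, wc[:, c] + 1e-12)
                U[c], V[c] = _beta_ml_fixed_point(mlx, ml1mx, U[c], V[c], n_iter=25)
            pi = Wc / Wc.sum()
            logf = np.log(pi)[None, :] + _beta_loglik_matrix(lx, l1mx, U, V)
            lse = logsumexp(logf, axis=1)
            resp = np.exp(logf - lse[:, None])
            ll = float(w @ lse)
            if abs(ll - ll_prev) < 1e-8 * (abs(ll_prev) + 1.0):
                break
            ll_prev = ll
        W = w.sum()
        k_free = 4 * K + 1
        bic = -2.0 * ll + k_free * np.log(W)
        return bic, resp, (U, V, pi)

    def fit(self, seed: int = 0) -> MixtureResults:
        Y = self.Y
        lx, l1mx = np.log(Y), np.log1p(-Y)
        N = Y.shape[0]
        leaves: list[tuple[str, np.ndarray, tuple]] = []
        bic_trace: list[dict] = []

        def recurse(w, mask, path, depth, node_seed):
            self.Y_node = Y  # EM init clusters on full rows; weights localize
            bic1, par1 = self._node_fit1(lx, l1mx, w)
            do_split = False
            if depth < self.max_depth and w.sum() >= 2 * self.min_weight:
                bic2, resp2, par2 = self._node_fit2(lx, l1mx, w, node_seed)
                bic_trace.append({"path": path, "bic1": bic1, "bic2": bic2})
                wl = w * resp2[:, 0]
                wr = w * resp2[:, 1]
                if bic2 < bic1 and wl.sum() >= self.min_weight and wr.sum() >= self.min_weight:
                    do_split = True
            else:
                bic_trace.append({"path": path, "bic1": bic1, "bic2": None})
            if do_split:
                # deterministic child order: L = heavier child
                order = (0, 1) if wl.sum() >= wr.sum() else (1, 0)
                children = [w * resp2[:, c] for c in order]
                hard = np.argmax(resp2[:, list(order)], axis=1)
                for side, (cw, tag) in enumerate(zip(children, "LR")):
                    cmask = mask & (hard == side)
                    recurse(cw, cmask, path + tag, depth + 1, node_seed * 2 + side + 1)
            else:
                leaves.append((path, mask, par1))

        recurse(np.ones(N), np.ones(N, dtype=bool), "r", 0, seed + 1)
        # empty leaves can arise from soft/hard mismatch; drop them
        leaves = [lf for lf in leaves if lf[1].sum() > 0]
        M = len(leaves)
        resp = np.zeros((N, M))
        for j, (_, mask, _) in enumerate(leaves):
            resp[mask, j] = 1.0
        unassigned = resp.sum(axis=1) == 0
        if unassigned.any():  # defensive: assign to largest leaf
            resp[unassigned, int(np.argmax(resp.sum(axis=0)))] = 1.0
        w = resp.sum(axis=0) / N
        params = {"leaves": {p: {"u": par[0], "v": par[1]} for p, _, par in leaves}}
        return _finalize(
            "beta-recursive", w, params, resp, seed,
            wtdbic_trace=bic_trace, leaf_paths=[p for p, _, _ in leaves],
        )


# ---------------------------------------------------------------------------
# directional mixtures


def _validate_unit_rows(Z):
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("Z must be N x K")
    nrm = np.linalg.norm(Z, axis=1)
    if np.any(np.abs(nrm - 1.0) > 1e-8):
        raise ValueError("rows must be unit l2 norm")
    return Z / nrm[:, None]


def _solve_vmf_concentration(rbar, K, ridge=0.0):
    """Solve A_K(lam) = rbar for lam >= 0 (Banerjee init + Newton)."""
    from scipy.special import ive

    rbar = min(max(rbar - ridge, 0.0), 1.0 - 1e-6)
    if rbar < 1e-9:
        return 0.0
    lam = rbar * (K - rbar**2) / (1.0 - rbar**2)
    for _ in range(25):
        a = ive(K / 2.0, lam) / ive(K / 2.0 - 1.0, lam)
        da = 1.0 - a**2 - (K - 1.0) / lam * a
        step = (a - rbar) / max(da, 1e-12)
        lam_new = min(max(lam - step, lam / 4.0), lam * 4.0 + 1.0)
        if abs(lam_new - lam) < 1e-10 * (1.0 + lam):
            lam = lam_new
            break
        lam = lam_new
    return float(min(max(lam, 0.0), 1e5))


def _solve_watson_concentration(rbar, p):
    """Solve d/dk ln 1F1(1/2, p/2, k) = rbar for k > 0 (bisection).

    g(0) = 1/p and g -> 1 as k -> inf; rbar <= 1/p maps to k ~ 0.
    """
    lo, hi = 1e-6, 2000.0

    def g(k):
        return (1.0 / p) * np.exp(
            log_kummer_1f1(1.5, p / 2.0 + 1.0, k) - log_kummer_1f1(0.5, p / 2.0, k)
        )

    if rbar <= 1.0 / p + 1e-9:
        return 1e-6
    rbar = min(rbar, 1.0 - 1e-6)
    if g(hi) < rbar:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) < rbar:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _DirectionalMixtureBase:
    family = ""

    def __init__(self, Z, n_components: int = 10, prune: float = 0.01,
                 conc_prior_rate: float = 1.0):
        self.Z = _validate_unit_rows(Z)
        self.M_init = int(n_components)
        self.prune = float(prune)
        self.conc_prior_rate = conc_prior_rate  # gamma(1, rate) prior on concentration

    # subclass hooks
    def _init_resp(self, seed):
        raise NotImplementedError

    def _mstep(self, resp):
        raise NotImplementedError

    def _log_component(self, params):
        raise NotImplementedError

    def _surrogate(self, lw, params):
        ll = logsumexp(lw[None, :] + self._log_component(params), axis=1).sum()
        concs = params[1]
        return float(ll - self.conc_prior_rate * np.sum(concs))

    def _vb_loop(self, resp, max_iter, tol):
        trace = []
        params = self._mstep(resp)
        alpha = _SPARSE_DIRICHLET + resp.sum(axis=0)
        for _ in range(max_iter):
            lw = psi(alpha) - psi(alpha.sum())
            logr = lw[None, :] + self._log_component(params)
            logr -= logsumexp(logr, axis=1, keepdims=True)
            resp_new = np.exp(logr)
            params_new = self._mstep(resp_new)
            alpha_new = _SPARSE_DIRICHLET + resp_new.sum(axis=0)
            wbar = alpha_new / alpha_new.sum()
            cand = self._surrogate(np.log(wbar), params_new)
            if trace and cand < trace[-1] - 1e-9:
                break
            resp, params, alpha = resp_new, params_new, alpha_new
            trace.append(cand)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
                break
        return resp, params, alpha, trace

    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> MixtureResults:
        resp = self._init_resp(seed)
        resp, params, alpha, trace = self._vb_loop(resp, max_iter, tol)
        w = resp.sum(axis=0) / resp.shape[0]
        keep = np.flatnonzero(w >= self.prune)
        if keep.size == 0:
            keep = np.array([int(np.argmax(w))])
        if keep.size < resp.shape[1]:
            resp = resp[:, keep] / resp[:, keep].sum(axis=1, keepdims=True)
            resp, params, alpha, trace = self._vb_loop(resp, max_iter, tol)
        w = resp.sum(axis=0) / resp.shape[0]
        mus, concs = params
        pdict = {"directions": mus, "concentrations": concs, "dirichlet": alpha}
        return _finalize(self.family, w, pdict, resp, seed, elbo=np.asarray(trace))


class VonMisesFisherMixture(_DirectionalMixtureBase):
    """Variational Bayesian von Mises-Fisher mixture on the unit hypersphere."""

    family = "vmf"

    def _init_resp(self, seed):
        return _kmeans_resp(self.Z, self.M_init, seed)

    def _mstep(self, resp):
        Z = self.Z
        K = Z.shape[1]
        Nm = resp.sum(axis=0) + 1e-12
        R = resp.T @ Z  # M x K resultants
        Rn = np.linalg.norm(R, axis=1)
        mus = np.where(Rn[:, None] > 1e-12, R / np.maximum(Rn, 1e-12)[:, None],
                       np.eye(K)[0][None, :])
        lams = np.array([
            _solve_vmf_concentration(Rn[m] / Nm[m], K, ridge=self.conc_prior_rate / Nm[m])
            for m in range(resp.shape[1])
        ])
        return mus, lams

    def _log_component(self, params):
        mus, lams = params
        K = self.Z.shape[1]
        cc = np.array([vmf_log_normalizer(K, l) for l in lams])
        return cc[None, :] + (self.Z @ mus.T) * lams[None, :]


class WatsonMixture(_DirectionalMixtureBase):
    """Variational Bayesian Watson mixture for axial data (x ~ -x).

    Component concentrations are restricted to kappa > 0 (clusters around
    axes); the girdle form stays available in the distributions module.
    """

    family = "watson"

    def _init_resp(self, seed):
        # axial k-means: assign by squared projection, axis = top eigenvector
        Z = self.Z
        N, K = Z.shape
        rng = np.random.default_rng(seed)
        M = min(self.M_init, N)
        axes = Z[rng.choice(N, size=M, replace=False)].copy()
        lab = np.zeros(N, dtype=int)
        for _ in range(50):
            proj = (Z @ axes.T) ** 2
            new_lab = np.argmax(proj, axis=1)
            if np.array_equal(new_lab, lab) and _ > 0:
                break
            lab = new_lab
            for m in range(M):
                pts = Z[lab == m]
                if len(pts) == 0:
                    axes[m] = Z[rng.integers(N)]
                    continue
                S = pts.T @ pts
                _, vecs = np.linalg.eigh(S)
                axes[m] = vecs[:, -1]
        resp = np.full((N, self.M_init), 1e-2)
        resp[np.arange(N), lab] = 1.0
        return resp / resp.sum(axis=1, keepdims=True)

    def _mstep(self, resp):
        Z = self.Z
        p = Z.shape[1]
        M = resp.shape[1]
        Nm = resp.sum(axis=0) + 1e-12
        mus = np.empty((M, p))
        kappas = np.empty(M)
        for m in range(M):
            S = (Z * resp[:, m][:, None]).T @ Z / Nm[m]
            evals, vecs = np.linalg.eigh(S)
            mus[m] = vecs[:, -1]
            rbar = float(evals[-1])
            kappas[m] = _solve_watson_concentration(
                max(rbar - self.conc_prior_rate / Nm[m], 0.0), p
            )
        return mus, kappas

    def _log_component(self, params):
        mus, kappas = params
        p = self.Z.shape[1]
        cc = np.array([watson_log_normalizer(p, k) for k in kappas])
        return cc[None, :] + ((self.Z @ mus.T) ** 2) * kappas[None, :]


# ---------------------------------------------------------------------------
# Gaussian baseline (library-backed)


class GaussianMixtureVB:
    """Variational Bayesian Gaussian mixture baseline (sklearn-backed).

    Accepts features as a K x N matrix (columns are samples, the orientation
    PCA produces) and prunes components with posterior weight < ``prune``.
    """

    def __init__(self, Y, n_components: int = 10, prune: float = 0.01):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (K x N, samples as columns)")
        self.X = Y.T  # N x K
        N, K = self.X.shape
        if N <= K:
            raise ValueError(
                f"N={N} samples <= K={K} dimensions: reduce the dimension before clustering"
            )
        self.M_init = int(n_components)
        self.prune = float(prune)

    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> MixtureResults:
        from sklearn.mixture import BayesianGaussianMixture

        bgm = BayesianGaussianMixture(
            n_components=min(self.M_init, self.X.shape[0]),
            weight_concentration_prior_type="dirichlet_distribution",
            weight_concentration_prior=_SPARSE_DIRICHLET,
            mean_precision_prior=10.0,  # pulls starved components onto the data mean
            covariance_type="full",
            reg_covar=1e-6,
            max_iter=max_iter,
            tol=tol,
            n_init=3,
            random_state=seed,
        )
        bgm.fit(self.X)
        resp = bgm.predict_proba(self.X)
        w = resp.sum(axis=0) / resp.shape[0]
        keep = np.flatnonzero(w >= self.prune)
        if keep.size == 0:
            keep = np.array([int(np.argmax(w))])
        resp = resp[:, keep]
        params = {
            "means": bgm.means_[keep],
            "covariances": bgm.covariances_[keep],
        }
        w = resp.sum(axis=0)
        return _finalize(
            "gaussian", w, params, resp, seed,
            elbo=np.asarray([bgm.lower_bound_]),
        )


# ---------------------------------------------------------------------------
# functional front-ends (one per clustering back-end)


def fit_vbgmm(Y, M_init: int = 10, prune: float = 0.01, seed: int = 0) -> MixtureResults:
    """VB Gaussian mixture on a K x N feature matrix (PCA orientation)."""
    return GaussianMixtureVB(Y, M_init, prune).fit(seed=seed)


def fit_vbbmm(Y, M_init: int = 15, prune: float = 0.01, seed: int = 0) -> MixtureResults:
    """VB beta mixture on N x K bounded features (pseudo-basis rows)."""
    return BetaMixture(Y, M_init, prune).fit(seed=seed)


def fit_rpbmm(Y, seed: int = 0) -> MixtureResults:
    """Recursive-partitioning beta mixture (weighted-BIC benchmark)."""
    return RecursiveBetaPartition(Y).fit(seed=seed)


def fit_vbvmm(Z, M_init: int = 10, prune: float = 0.01, seed: int = 0) -> MixtureResults:
    """VB von Mises-Fisher mixture on N x K unit-row features."""
    return VonMisesFisherMixture(Z, M_init, prune).fit(seed=seed)


def fit_vbwmm(Z, M_init: int = 10, prune: float = 0.01, seed: int = 0) -> MixtureResults:
    """VB Watson (axial) mixture on N x K unit-row features."""
    return WatsonMixture(Z, M_init, prune).fit(seed=seed)
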