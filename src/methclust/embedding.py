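"""Feature selection and linear/spectral dimension reduction.

CpG-by-sample beta-value matrices have far more features (CpGs, typically
tens of thousands) than samples (~100).  The preprocessing here follows the
standard methylation workflow: keep the top-variance CpGs, estimate the
number of salient dimensions K from random-matrix theory (eigenvalues of the
sample-sample correlation matrix above the Marchenko-Pastur upper edge), and
reduce either with PCA or with a normalized-graph-Laplacian spectral
embedding whose output columns have unit l2 norm (so they can be clustered
with directional mixture models downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DimensionEstimate",
    "select_top_variance",
    "estimate_dim_rmt",
    "pca_reduce",
    "spectral_embed",
]


@dataclass
class DimensionEstimate:
    """RMT dimension estimate: eigenvalues above the Marchenko-Pastur edge."""

    K: int
    eigenvalues: np.ndarray  # descending
    threshold: float


def select_top_variance(X: pd.DataFrame, n: int):
    """Keep the ``n`` rows (CpGs) with largest sample variance.

    Original row order is preserved among the selected rows; ties are broken
    in favour of earlier rows.  Accepts a DataFrame (ids carried through) or
    a plain array.
    """
    is_df = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(dtype=float) if is_df else np.asarray(X, dtype=float)
    P = arr.shape[0]
    if not 1 <= n <= P:
        raise ValueError(f"n must be in [1, {P}], got {n}")
    if n == P:
        return X
    var = arr.var(axis=1, ddof=1)
    # stable selection: sort by (-variance, row index) and keep original order
    order = np.lexsort((np.arange(P), -var))[:n]
    keep = np.sort(order)
    return X.iloc[keep] if is_df else arr[keep]


def estimate_dim_rmt(X) -> DimensionEstimate:
    """Estimate the number of signal dimensions by random-matrix theory.

    Rows (features) are standardized to zero mean, unit variance; the
    eigenvalues of the T x T sample-sample correlation matrix C = X'X / P are
    compared against the Marchenko-Pastur upper edge (1 + sqrt(T/P))^2.  At
    finite P the top noise eigenvalue fluctuates around the edge on the
    Tracy-Widom scale, so the working threshold is the finite-sample
    (Johnstone) centering plus three Tracy-Widom scale units; this keeps the
    false-positive rate on pure noise well below 5% while leaving any real
    signal component (which sits far above the bulk) untouched.  K is the
    count of eigenvalues above the threshold.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("estimate_dim_rmt needs a matrix with at least 2 rows and 2 columns")
    sd = arr.std(axis=1, ddof=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        import warnings

        warnings.warn(f"dropping {int(degenerate.sum())} constant rows before RMT estimation")
        arr = arr[~degenerate]
        sd = sd[~degenerate]
    P, T = arr.shape
    Z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    C = (Z.T @ Z) / P
    evals = np.linalg.eigvalsh(C)[::-1]
    # finite-sample MP edge (Johnstone centering) + 3 Tracy-Widom scale units
    mu = (np.sqrt(P - 0.5) + np.sqrt(T - 0.5)) ** 2 / P
    sig = (np.sqrt(P - 0.5) + np.sqrt(T - 0.5)) / P * (
        1.0 / np.sqrt(P - 0.5) + 1.0 / np.sqrt(T - 0.5)
    ) ** (1.0 / 3.0)
    edge = float(mu + 3.0 * sig)
    K = int(np.sum(evals > edge))
    return DimensionEstimate(K=K, eigenvalues=evals, threshold=edge)


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def pca_reduce(X, K: int) -> np.ndarray:
    """Project samples (columns) onto the K leading principal axes.

    Rows (features) are mean-centered internally; the returned score matrix
    is K x T.  Eigenvector signs are fixed (largest-magnitude loading
    positive) for backend-independent reproducibility.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    P, T = arr.shape
    if not 1 <= K <= min(P, T):
        raise ValueError(f"K must be in [1, {min(P, T)}], got {K}")
    Xc = arr - arr.mean(axis=1, keepdims=True)
    # eigenvectors of the P x P feature covariance via thin SVD of Xc
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    U = _fix_eigvec_signs(U[:, :K])
    return U.T @ Xc  # K x T scores


def spectral_embed(X, K: int, sigma: float | str = "auto") -> np.ndarray:
    """Normalized spectral embedding of the N column-samples of X.

    Steps: Gaussian affinity A_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)) with
    zero diagonal; M = D^{-1/2} A D^{-1/2}; the K leading eigenvectors of M
    form the rows of Y (K x N); each *column* of Y is scaled to unit l2 norm,
    giving Z.  With ``sigma="auto"`` the bandwidth is set from the data:
    sigma = sqrt(Var(B)) where B is the matrix of squared pairwise distances.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D with samples as columns")
    N = arr.shape[1]
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, N={N}], got {K}")
    pts = arr.T  # N x L
    sq = np.sum(pts**2, axis=1)
    B = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.fill_diagonal(B, 0.0)
    B = np.clip(B, 0.0, None)
    if sigma == "auto":
        sigma_val = float(np.sqrt(B.var()))
        if sigma_val <= 0:
            raise ValueError("degenerate data: all pairwise distances identical")
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    A = np.exp(-B / (2.0 * sigma_val**2))
    np.fill_diagonal(A, 0.0)
    d = A.sum(axis=1)
    if np.any(d <= 0):
        bad = int(np.argmin(d))
        raise ValueError(f"sample {bad} is isolated (zero affinity row sum); increase sigma")
    Dm12 = 1.0 / np.sqrt(d)
    M = A * Dm12[:, None] * Dm12[None, :]
    evals, evecs = np.linalg.eigh(M)
    top = np.argsort(evals)[::-1][:K]
    Y = _fix_eigvec_signs(evecs[:, top]).T  # K x N
    norms = np.linalg.norm(Y, axis=0)
    if np.any(norms <= 0):
        raise ValueError("zero embedding column; cannot normalize")
    return Y / norms[None, :]
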