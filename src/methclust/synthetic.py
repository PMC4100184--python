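"""Seeded generators for methylation-like and directional test data.

The grouped-methylation generator emulates the structure of a typical
Illumina 27k breast-tissue cohort: a CpG-by-sample matrix of beta-values in
(0,1) with one normal group and several heterogeneous cancer subgroups, most
CpGs sharing a common beta law across groups, and a fraction of
differentially methylated (DM) CpGs whose group means are shifted.  The
default profile mirrors a 136-sample cohort (23 normals, 113 cancers split
into three subgroups).

Two more generators produce exact draws from the BG-NMF generative model
(gamma bases and excitations, beta observations) and from directional
(vMF / Watson) mixtures on the unit hypersphere.

Every generator is a pure function of its parameter record: the same record
(including the seed) reproduces the data bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bgnmf import BGNMFPriors, EPS
from .distributions import VmfParams, WatsonParams, sample_vmf, sample_watson

__all__ = [
    "SyntheticTruth",
    "gen_group_methylation",
    "gen_bgnmf_matrix",
    "gen_directional_mixture",
    "DEFAULT_GROUP_SIZES",
]

#: default cohort profile: 23 normals + 113 cancers in three subgroups
DEFAULT_GROUP_SIZES = (23, 40, 40, 33)


@dataclass
class SyntheticTruth:
    """Generated data plus the ground truth that produced it."""

    X: pd.DataFrame | np.ndarray
    group_labels: np.ndarray
    dm_rows: np.ndarray
    generator_params: dict
    true_mean_matrix: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def gen_group_methylation(
    P: int = 1000,
    T: int = 136,
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES,
    dm_fraction: float = 0.2,
    delta: float = 0.3,
    concentration: float = 60.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Grouped beta-value matrix with planted differential methylation.

    Non-DM CpGs share one beta law across all groups.  Each DM CpG gets a
    baseline mean drawn so that +/-delta stays inside (0,1); group 0 (the
    "normal" group) keeps the baseline, and every other group shifts the
    mean by +delta or -delta with a group-and-CpG-specific sign, so cancer
    subgroups differ from the normals and from each other.  Entries are
    Beta(mean*concentration, (1-mean)*concentration) draws clipped to
    [1e-6, 1-1e-6].
    """
    group_sizes = tuple(int(g) for g in group_sizes)
    if sum(group_sizes) != T:
        raise ValueError(f"group sizes {group_sizes} must sum to T={T}")
    if not 0.0 <= dm_fraction < 1.0:
        raise ValueError("dm_fraction must be in [0, 1)")
    margin = 0.05
    if delta < 0 or delta + 2 * margin >= 1.0:
        raise ValueError(f"delta={delta} leaves no room for means inside (0,1)")
    params = dict(
        P=P, T=T, group_sizes=group_sizes, dm_fraction=dm_fraction,
        delta=delta, concentration=concentration, seed=seed,
    )
    rng = np.random.default_rng(seed)
    G = len(group_sizes)
    labels = np.repeat(np.arange(G), group_sizes)

    n_dm = int(round(dm_fraction * P))
    dm_rows = np.sort(rng.choice(P, size=n_dm, replace=False))
    is_dm = np.zeros(P, dtype=bool)
    is_dm[dm_rows] = True

    base_mean = rng.uniform(margin, 1.0 - margin, size=P)
    # DM baselines drawn so that +/-delta stays in (margin, 1-margin)
    base_mean[is_dm] = rng.uniform(margin + delta, 1.0 - margin - delta, size=n_dm)

    mean_pg = np.tile(base_mean[:, None], (1, G))
    signs = rng.choice([-1.0, 1.0], size=(n_dm, G))
    signs[:, 0] = 0.0  # normal group keeps baseline
    mean_pg[is_dm] += signs * delta

    mean_pt = mean_pg[:, labels]  # P x T expected value of every entry
    a = mean_pt * concentration
    b = (1.0 - mean_pt) * concentration
    X = np.clip(rng.beta(a, b), EPS, 1.0 - EPS)
    df = pd.DataFrame(
        X,
        index=[f"cg{i:06d}" for i in range(P)],
        columns=[f"S{j:03d}" for j in range(T)],
    )
    return SyntheticTruth(
        X=df, group_labels=labels, dm_rows=dm_rows,
        generator_params=params, true_mean_matrix=mean_pt,
        extras={"group_means": mean_pg, "is_dm": is_dm},
    )


def gen_bgnmf_matrix(
    P: int = 200,
    T: int = 60,
    K: int = 3,
    priors: BGNMFPriors | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Exact draw from the BG-NMF generative model.

    A (P x K), B (P x K) and H (K x T) are drawn from their gamma priors;
    each X_pt is a Beta(sum_k A_pk H_kt, sum_k B_pk H_kt) draw.  The true
    mean matrix AH / (AH + BH) is recorded for recovery checks.
    """
    pr = priors or BGNMFPriors(mu0=2.0, alpha0=1.0, nu0=2.0, beta0=1.0, rho0=0.8, zeta0=1.0)
    params = dict(P=P, T=T, K=K, priors=vars(pr).copy(), seed=seed)
    rng = np.random.default_rng(seed)
    A = rng.gamma(pr.mu0, 1.0 / pr.alpha0, size=(P, K))
    B = rng.gamma(pr.nu0, 1.0 / pr.beta0, size=(P, K))
    H = rng.gamma(pr.rho0, 1.0 / pr.zeta0, size=(K, T))
    a = A @ H
    b = B @ H
    X = np.clip(rng.beta(a, b), EPS, 1.0 - EPS)
    return SyntheticTruth(
        X=X, group_labels=np.zeros(T, dtype=int), dm_rows=np.array([], dtype=int),
        generator_params=params, true_mean_matrix=a / (a + b),
        extras={"A": A, "B": B, "H": H},
    )


def _separated_axes(M: int, K: int, rng: np.random.Generator, min_angle_deg: float = 60.0) -> np.ndarray:
    """M well-separated unit axes in R^K: a randomly rotated orthonormal set."""
    if M > K:
        raise ValueError(
            f"cannot place M={M} axes with >= {min_angle_deg} deg pairwise separation in K={K} dims"
        )
    Q, _ = np.linalg.qr(rng.standard_normal((K, K)))
    return Q[:, :M].T  # orthogonal -> 90 deg pairwise


def gen_directional_mixture(
    family: str = "vmf",
    M: int = 3,
    K: int = 3,
    kappas=(400.0, 400.0, 400.0),
    weights=None,
    n: int = 300,
    seed: int = 0,
) -> SyntheticTruth:
    """Labelled sample from a mixture of vMF or Watson components.

    Component axes are drawn as a randomly rotated orthonormal set (pairwise
    90 degrees, satisfying the >= 60 degree separation contract); sample
    counts per component are multinomial in the weights.
    """
    if family not in ("vmf", "watson"):
        raise ValueError("family must be 'vmf' or 'watson'")
    kappas = np.asarray(kappas, dtype=float)
    if kappas.shape[0] != M:
        raise ValueError("need one concentration per component")
    weights = np.full(M, 1.0 / M) if weights is None else np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-10:
        raise ValueError("weights must sum to 1")
    params = dict(family=family, M=M, K=K, kappas=kappas.tolist(),
                  weights=weights.tolist(), n=n, seed=seed)
    rng = np.random.default_rng(seed)
    axes = _separated_axes(M, K, rng)
    counts = rng.multinomial(n, weights)
    chunks, labels = [], []
    for m in range(M):
        if counts[m] == 0:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if family == "vmf":
            chunks.append(sample_vmf(VmfParams(axes[m], kappas[m]), counts[m], sub_seed))
        else:
            chunks.append(sample_watson(WatsonParams(axes[m], kappas[m]), counts[m], sub_seed))
        labels += [m] * counts[m]
    return SyntheticTruth(
        X=np.vstack(chunks), group_labels=np.array(labels), dm_rows=np.array([], dtype=int),
        generator_params=params, true_mean_matrix=None,
        extras={"axes": axes, "counts": counts},
    )
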