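"""End-to-end reduce -> cluster -> evaluate pipelines and their scoring.

Five method combinations are supported, each pairing a dimension-reduction
step with the mixture family matched to the geometry of its output:

======================  =====================================
reduction -> clusterer   feature geometry
======================  =====================================
pca    + vbgmm           unbounded real scores (baseline)
bgnmf  + rpbmm           bounded (0,1) pseudo-basis rows
bgnmf  + vbbmm           bounded (0,1) pseudo-basis rows
sc     + vbvmm           unit-norm spectral features
sc     + vbwmm           unit-norm features, axial reading
======================  =====================================

Scoring maps each cluster to its majority truth class; a sample is
misclustered iff its cluster's majority class differs from its own.  For a
binary normal/cancer truth the two misclustering directions are reported
separately (cancer->normal, normal->cancer), with class1 taken as the
larger class (cancer in a typical cohort).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bgnmf import BGNMF
from .embedding import select_top_variance, estimate_dim_rmt, pca_reduce, spectral_embed
from .mixtures import fit_vbgmm, fit_vbbmm, fit_rpbmm, fit_vbvmm, fit_vbwmm, MixtureResults

logger = logging.getLogger("methclust")

__all__ = ["ClusterReport", "PipelineConfig", "evaluate_clustering", "run_pipeline", "COMPATIBLE"]

#: the supported reduction -> clusterer pairings
COMPATIBLE = {
    "pca": ("vbgmm",),
    "bgnmf": ("vbbmm", "rpbmm"),
    "sc": ("vbvmm", "vbwmm"),
}


@dataclass
class ClusterReport:
    """Clustering evaluation against known classes.

    ``error_rate`` is a percentage: 100 x misclustered / N.  The directional
    counts follow the convention of a binary cohort where class1 is the
    majority class (cancer) and class2 the minority (normal); they are None
    when the truth has more than two classes.
    """

    method: str
    n_clusters: int
    error_rate: float
    miscl_class1_to_class2: int | None
    miscl_class2_to_class1: int | None
    confusion: dict
    K_used: int | None
    seed: int | None
    labels: np.ndarray = field(repr=False)
    cluster_names: list = field(repr=False)
    class1: str | None = None
    class2: str | None = None

    def cluster_names_per_sample(self):
        return [self.cluster_names[l - 1] for l in self.labels]

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_clusters": int(self.n_clusters),
            "error_rate": float(self.error_rate),
            "miscl_class1_to_class2": self.miscl_class1_to_class2,
            "miscl_class2_to_class1": self.miscl_class2_to_class1,
            "class1": self.class1,
            "class2": self.class2,
            "confusion": self.confusion,
            "K_used": self.K_used,
            "seed": self.seed,
            "assignments": [int(l) for l in self.labels],
            "cluster_names": list(self.cluster_names),
        }
        return d

    def summary(self) -> str:
        lines = [
            f"method               : {self.method}",
            f"clusters             : {self.n_clusters}",
            f"error rate           : {self.error_rate:.2f}%",
        ]
        if self.miscl_class1_to_class2 is not None:
            lines.append(f"{self.class1}->{self.class2}       : {self.miscl_class1_to_class2}")
            lines.append(f"{self.class2}->{self.class1}       : {self.miscl_class2_to_class1}")
        return "\n".join(lines)


def evaluate_clustering(labels, truth, method: str = "", K_used=None, seed=None,
                        cluster_names=None) -> ClusterReport:
    """Score a clustering against known classes by majority-class mapping.

    Each cluster is assigned the truth class holding the majority of its
    members (ties broken toward the larger class overall); every sample
    whose own class differs from its cluster's majority class counts as
    misclustered.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError(f"length mismatch: {labels.shape[0]} labels vs {truth.shape[0]} truths")
    classes, class_counts = np.unique(truth, return_counts=True)
    if classes.size < 2:
        raise ValueError("truth must contain at least 2 classes")
    class_order = classes[np.argsort(-class_counts, kind="stable")]  # larger first
    clusters = np.unique(labels)
    if cluster_names is None:
        cluster_names = [str(c) for c in clusters]
    name_of = dict(zip(clusters, cluster_names))

    N = labels.shape[0]
    confusion: dict = {}
    majority: dict = {}
    for c in clusters:
        mask = labels == c
        row = {str(k): int(np.sum(truth[mask] == k)) for k in classes}
        confusion[name_of[c]] = row
        # majority with ties toward the larger class
        best = max(class_order, key=lambda k: (row[str(k)], -list(class_order).index(k)))
        majority[c] = best
    mapped = np.array([majority[c] for c in labels])
    wrong = mapped != truth
    error_rate = 100.0 * wrong.sum() / N

    c12 = c21 = None
    class1 = class2 = None
    if classes.size == 2:
        class1, class2 = class_order[0], class_order[1]
        c12 = int(np.sum(wrong & (truth == class1)))  # class1 samples in class2-majority clusters
        c21 = int(np.sum(wrong & (truth == class2)))
        class1, class2 = str(class1), str(class2)

    # relabel clusters 1..M in first-appearance order for the report
    order = {c: i + 1 for i, c in enumerate(clusters)}
    return ClusterReport(
        method=method, n_clusters=int(clusters.size), error_rate=float(error_rate),
        miscl_class1_to_class2=c12, miscl_class2_to_class1=c21,
        confusion=confusion, K_used=K_used, seed=seed,
        labels=np.array([order[c] for c in labels]),
        cluster_names=list(cluster_names), class1=class1, class2=class2,
    )


@dataclass
class PipelineConfig:
    """Configuration of one reduce->cluster->evaluate run."""

    reduction: str = "bgnmf"  # pca | bgnmf | sc
    clusterer: str = "vbbmm"  # vbgmm | vbbmm | rpbmm | vbvmm | vbwmm
    K: int | str = "rmt"  # embedding dimension, or "rmt" to estimate
    n_top_cpgs: int = 1000
    M_init: int = 15
    prune: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.reduction not in COMPATIBLE:
            raise ValueError(f"unknown reduction {self.reduction!r}; choose from {sorted(COMPATIBLE)}")
        allowed = COMPATIBLE[self.reduction]
        if self.clusterer not in allowed:
            raise ValueError(
                f"clusterer {self.clusterer!r} is incompatible with reduction "
                f"{self.reduction!r}: bounded-support clusterers (vbbmm, rpbmm) need bgnmf, "
                f"directional clusterers (vbvmm, vbwmm) need sc, and vbgmm pairs with pca"
            )


def run_pipeline(X: pd.DataFrame, config: PipelineConfig, truth=None, outdir=None
                 ) -> tuple[ClusterReport | None, dict]:
    """Execute select-top-variance -> reduce -> cluster (-> evaluate).

    ``X`` is CpG x sample.  BG-NMF is applied to the transpose (samples as
    rows) so the pseudo-basis rows index samples; spectral embedding treats
    the column-samples as the points.  Returns the ClusterReport (None when
    no truth is given) and an artifact dict with the fit, features and
    resolved configuration; with ``outdir`` set, the report JSON, the
    assignment TSV and the resolved config are also written there.
    """
    config.validate()
    seed = int(config.seed)
    sample_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    n_top = min(int(config.n_top_cpgs), X.shape[0])
    Xs = select_top_variance(X, n_top)
    arr = Xs.to_numpy(dtype=float) if isinstance(Xs, pd.DataFrame) else np.asarray(Xs, float)
    logger.info("selected %d top-variance CpGs of %d (T=%d samples)", n_top, X.shape[0], X.shape[1])

    if config.K == "rmt":
        est = estimate_dim_rmt(arr)
        K = max(est.K, 2)
        logger.info("RMT estimated K=%d (threshold %.3f)", est.K, est.threshold)
    else:
        K = int(config.K)

    if config.reduction == "pca":
        feats = pca_reduce(arr, K)  # K x T
        logger.info("PCA scores %s", feats.shape)
    elif config.reduction == "bgnmf":
        fit = BGNMF(arr.T, K).fit(seed=seed)
        W, _ = fit.pseudo_basis()  # T x K bounded rows (samples)
        feats = np.clip(W, 1e-6, 1 - 1e-6)
        logger.info("BG-NMF pseudo-basis %s after %d iterations", W.shape, fit.iterations_run)
    else:  # sc
        feats = spectral_embed(arr, K, sigma="auto")  # K x T, unit columns
        logger.info("spectral embedding %s", feats.shape)

    if config.clusterer == "vbgmm":
        mix = fit_vbgmm(feats, config.M_init, config.prune, seed)
    elif config.clusterer == "vbbmm":
        mix = fit_vbbmm(feats, config.M_init, config.prune, seed)
    elif config.clusterer == "rpbmm":
        mix = fit_rpbmm(feats, seed)
    elif config.clusterer == "vbvmm":
        mix = fit_vbvmm(feats.T, config.M_init, config.prune, seed)
    else:  # vbwmm
        mix = fit_vbwmm(feats.T, config.M_init, config.prune, seed)
    logger.info("%s found %d clusters", config.clusterer, mix.M_effective)

    method = f"{config.reduction}+{config.clusterer}"
    cluster_names = mix.leaf_paths if mix.leaf_paths is not None else [
        str(i + 1) for i in range(mix.M_effective)
    ]
    report = None
    if truth is not None:
        report = evaluate_clustering(
            mix.labels, truth, method=method, K_used=K, seed=seed,
            cluster_names=[cluster_names[c - 1] for c in np.unique(mix.labels)],
        )
    artifacts = {
        "mixture": mix,
        "features": feats,
        "K": K,
        "config": {**asdict(config), "K_resolved": K, "method": method},
        "sample_ids": sample_ids,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_report

        with open(outdir / "config.resolved.yaml", "w") as fh:
            for k, v in artifacts["config"].items():
                fh.write(f"{k}: {v}\n")
        if report is not None:
            write_report(report, outdir / "report.json",
                         assignments_path=outdir / "assignments.tsv",
                         sample_ids=sample_ids)
        else:
            with open(outdir / "assignments.tsv", "w") as fh:
                fh.write("sample_id\tcluster\n")
                ids = sample_ids or [f"S{i:03d}" for i in range(len(mix.labels))]
                for sid, lab in zip(ids, mix.labels):
                    fh.write(f"{sid}\t{cluster_names[lab - 1]}\n")
    return report, artifacts
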