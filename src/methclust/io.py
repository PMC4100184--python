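"""Reading and writing beta-value matrices, labels and cluster reports.

File conventions: a beta matrix is delimited text (TSV or CSV by extension)
with a header row of sample identifiers and a first column of CpG
identifiers; a label file is two columns (sample_id, class).  Values are
validated to [0,1]; exact 0/1 entries are clipped to [1e-6, 1-1e-6] with a
logged count so downstream beta likelihoods stay finite.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bgnmf import EPS

logger = logging.getLogger("methclust")

__all__ = ["read_beta_matrix", "read_labels", "write_report", "write_beta_matrix"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(path) -> pd.DataFrame:
    """Read and validate a CpG-by-sample beta-value matrix.

    Raises a ValueError naming the offending cell for values outside [0,1]
    or missing cells, and for duplicate CpG identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate CpG id {dup!r} in {path}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"missing value at CpG {df.index[r]!r}, sample {df.columns[c]!r}")
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0.0) | (vals > 1.0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"beta-value {vals[r, c]} outside [0,1] at CpG {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    n_clip = int(np.sum((vals <= 0.0) | (vals >= 1.0)))
    if n_clip:
        logger.info("clipped %d exact 0/1 beta-values to [%g, %g]", n_clip, EPS, 1 - EPS)
    df = pd.DataFrame(np.clip(vals, EPS, 1.0 - EPS), index=df.index, columns=df.columns)
    return df


def write_beta_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, class) label file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, names=["sample_id", "label"],
                     skiprows=1 if _has_header(path) else 0)
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"].to_numpy())


def _has_header(path: Path) -> bool:
    first = path.read_text().splitlines()[0].lower()
    return "sample" in first and "label" in first or "class" in first


def write_report(report, path, assignments_path=None, sample_ids=None) -> None:
    """Serialize a ClusterReport as JSON (and cluster assignments as TSV).

    The confusion table is keyed by cluster label (RPBMM path labels such as
    "rLLR" are preserved).
    """
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if assignments_path is not None:
        if sample_ids is None:
            sample_ids = [f"S{i:03d}" for i in range(len(report.labels))]
        with open(assignments_path, "w") as fh:
            fh.write("sample_id\tcluster\n")
            for sid, lab in zip(sample_ids, report.cluster_names_per_sample()):
                fh.write(f"{sid}\t{lab}\n")
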