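"""Workflow QC: sample PCA, set overlaps, and identification tallies."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .quantify import ProteinQuantMatrix, as_frame

__all__ = ["PCAResult", "VennCounts", "pca_qc", "venn_counts", "id_counts"]


@dataclass
class PCAResult:
    """Sample-level PCA of the log2 matrix (samples as observations).

    Centered, no unit-variance scaling (preserves intensity-magnitude
    structure).  ``ellipses`` holds 95% confidence-ellipse parameters per
    sample group (plotting metadata from a 2-D Gaussian fit of the group's
    PC1/PC2 coordinates; no inferential claim).
    """

    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    ellipses: dict[str, dict] = field(default_factory=dict)


@dataclass(frozen=True)
class VennCounts:
    only_a: int
    only_b: int
    shared: int
    union: int
    pct_shared_of_a: float | None  # None (flagged) when |A| = 0


def pca_qc(
    matrix: ProteinQuantMatrix, sample_groups: Mapping[str, Sequence[str]] | None = None
) -> PCAResult:
    """PCA of samples on the (complete, imputed) log2 protein matrix."""
    X = matrix.values.to_numpy().T  # samples x proteins
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before PCA")
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("need >= 2 samples for PCA")
    n_comp = min(n_samples, X.shape[1])
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0.0):
        coords = np.zeros((n_samples, n_comp))
        evr = np.zeros(n_comp)
    else:
        pca = PCA(n_components=n_comp, svd_solver="full")
        coords = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=matrix.values.columns, columns=columns)

    centroids: dict[str, np.ndarray] = {}
    ellipses: dict[str, dict] = {}
    if sample_groups:
        scale = float(np.sqrt(chi2.ppf(0.95, df=2)))
        for group, samples in sample_groups.items():
            pts = coordinates.loc[list(samples)].to_numpy()
            centroids[group] = pts.mean(axis=0)
            if pts.shape[0] >= 3 and pts.shape[1] >= 2:
                cov = np.cov(pts[:, :2].T)
                eigval, eigvec = np.linalg.eigh(cov)
                order = np.argsort(eigval)[::-1]
                eigval, eigvec = eigval[order], eigvec[:, order]
                ellipses[group] = {
                    "center": centroids[group][:2],
                    "width": 2 * scale * float(np.sqrt(max(eigval[0], 0.0))),
                    "height": 2 * scale * float(np.sqrt(max(eigval[1], 0.0))),
                    "angle_deg": float(np.degrees(np.arctan2(eigvec[1, 0], eigvec[0, 0]))),
                }
    return PCAResult(coordinates, evr, centroids, ellipses)


def venn_counts(set_a: set, set_b: set) -> VennCounts:
    """Exact two-set overlap counts; the percentage is shared / |A| * 100."""
    shared = set_a & set_b
    pct = 100.0 * len(shared) / len(set_a) if set_a else None
    return VennCounts(
        only_a=len(set_a - set_b),
        only_b=len(set_b - set_a),
        shared=len(shared),
        union=len(set_a | set_b),
        pct_shared_of_a=pct,
    )


def id_counts(records) -> pd.DataFrame:
    """Per-sample counts of distinct protein groups, peptides and precursors.

    Only rows with an observed intensity count.  Peptides are distinct
    modified sequences; precursors are distinct (modified sequence, charge)
    pairs.  Counts are invariant to row order.
    """
    frame = as_frame(records).dropna(subset=["intensity"])
    rows = []
    for sample in sorted(frame["sample_id"].unique()):
        sub = frame[frame["sample_id"] == sample]
        rows.append(
            {
                "sample_id": sample,
                "protein_groups": sub["protein_group"].nunique(),
                "peptides": sub["modified_sequence"].nunique(),
                "precursors": len(sub[["modified_sequence", "charge"]].drop_duplicates()),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "protein_groups", "peptides", "precursors"])
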