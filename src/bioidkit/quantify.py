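"""Precursor-to-protein quantification.

Turns long-format precursor records into a normalized, filtered, imputed
protein x sample log2-intensity matrix and computes replicate coefficients
of variation (CVs).  The summarization is a transparent stand-in for search
engine label-free quantification: global median normalization, a lower-
quantile precursor filter, top-3 mean protein roll-up, single-hit exclusion,
and left-censored global imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_annotations import PrecursorRecord, records_to_frame

__all__ = [
    "ProteinQuantMatrix",
    "as_frame",
    "normalize_global_median",
    "filter_precursors_percentile",
    "summarize_to_protein",
    "impute_global",
    "compute_cv",
]

PRECURSOR_KEY = ["protein_group", "modified_sequence", "charge"]


def as_frame(records) -> pd.DataFrame:
    """Coerce a record list or long-format DataFrame to the frame dialect."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return records_to_frame(records)


@dataclass
class ProteinQuantMatrix:
    """Proteins x samples log2-intensity matrix with precursor support counts.

    ``values``: DataFrame indexed by protein accession, columns = sample ids,
    entries = log2 intensity (NaN = missing).  ``n_precursors`` counts the
    distinct precursors supporting each retained protein (always >= 2 after
    the single-hit filter); ``excluded_single_hit`` lists the proteins that
    were removed because a single precursor supported them.
    """

    values: pd.DataFrame
    n_precursors: dict[str, int] = field(default_factory=dict)
    excluded_single_hit: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            self.values.copy(), dict(self.n_precursors), list(self.excluded_single_hit)
        )

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "n_precursors", [self.n_precursors[p] for p in out.index])
        out.to_csv(path, sep="\t", index_label="protein")


def normalize_global_median(records) -> pd.DataFrame:
    """Global median normalization on the log2 scale.

    Each sample's intensities are multiplied by a constant factor so that
    its median log2 intensity equals the grand mean of the pre-normalization
    per-sample medians.  A sample with no observed intensity is an error.
    """
    frame = as_frame(records)
    medians: dict[str, float] = {}
    for sample, sub in frame.groupby("sample_id"):
        observed = sub["intensity"].dropna()
        if observed.empty:
            raise ValueError(f"sample {sample!r} has no observed intensities")
        medians[sample] = float(np.median(np.log2(observed.to_numpy())))
    target = float(np.mean(list(medians.values())))
    shift = frame["sample_id"].map(lambda s: target - medians[s])
    frame["intensity"] = frame["intensity"] * np.exp2(shift)
    return frame


def _cross_sample_medians(frame: pd.DataFrame) -> pd.Series:
    """Median observed log2 intensity per precursor across samples."""
    obs = frame.dropna(subset=["intensity"]).copy()
    obs["log2"] = np.log2(obs["intensity"])
    return obs.groupby(PRECURSOR_KEY, sort=True)["log2"].median()


def filter_precursors_percentile(records, fraction: float) -> pd.DataFrame:
    """Drop the weakest precursors by cross-sample median intensity.

    The lowest ``floor(fraction * n)`` precursors (global ranking of their
    cross-sample median intensities) are removed; ``fraction=0`` is the
    identity, ``fraction=1`` empties the table.  Ties are broken by the
    precursor key for determinism.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    frame = as_frame(records)
    if fraction == 0.0 or frame.empty:
        return frame
    medians = _cross_sample_medians(frame)
    n = len(medians)
    k = int(np.floor(fraction * n + 1e-12))
    if k == 0:
        return frame
    order = medians.sort_values(kind="mergesort")  # stable: ties by key order
    dropped = set(order.index[:k])
    keys = list(zip(frame["protein_group"], frame["modified_sequence"], frame["charge"]))
    keep = [key not in dropped for key in keys]
    return frame.loc[keep].reset_index(drop=True)


def summarize_to_protein(records) -> ProteinQuantMatrix:
    """Roll precursors up to a protein-level log2 matrix (top-3 mean).

    Per (protein, sample) the value is the mean of the log2 intensities of
    the protein's three strongest precursors (by cross-sample median; fewer
    if the protein has fewer).  Proteins supported by exactly one precursor
    overall are excluded and reported separately.
    """
    frame = as_frame(records)
    samples = sorted(frame["sample_id"].unique())
    if frame.empty:
        return ProteinQuantMatrix(pd.DataFrame(index=pd.Index([], name="protein")))

    medians = _cross_sample_medians(frame)
    n_precursors = (
        frame[PRECURSOR_KEY].drop_duplicates().groupby("protein_group").size().to_dict()
    )
    excluded = sorted(p for p, n in n_precursors.items() if n == 1)
    retained = [p for p in sorted(n_precursors) if n_precursors[p] > 1]

    # top-3 precursors per protein by cross-sample median; stable sort keeps
    # the key order on ties (medians is already key-sorted)
    med_df = medians.reset_index(name="median")
    med_df = med_df.sort_values(
        ["protein_group", "median"], ascending=[True, False], kind="mergesort"
    )
    top = med_df.groupby("protein_group", sort=False).head(3)[PRECURSOR_KEY]

    obs = frame.dropna(subset=["intensity"]).copy()
    obs["log2"] = np.log2(obs["intensity"])
    obs = obs.merge(top, on=PRECURSOR_KEY)
    obs = obs[obs["protein_group"].isin(retained)]
    agg = obs.groupby(["protein_group", "sample_id"])["log2"].mean()

    values = pd.DataFrame(np.nan, index=pd.Index(retained, name="protein"), columns=samples)
    if not agg.empty:
        wide = agg.unstack("sample_id")
        values.loc[wide.index, wide.columns] = wide
    counts = {p: n_precursors[p] for p in retained}
    return ProteinQuantMatrix(values, counts, excluded)


def impute_global(
    matrix: ProteinQuantMatrix,
    seed: int,
    percentile: float = 1.0,
    sd: float = 0.3,
    min_observed: int = 20,
) -> ProteinQuantMatrix:
    """Left-censored global imputation.

    Missing log2 values are drawn from a Gaussian centered at the global
    ``percentile``-th percentile of observed log2 values with standard
    deviation ``sd``, mimicking intensities censored at the detection limit.
    Observed values are never touched; the draw order is fixed (row-major),
    so a seed fully determines the result.
    """
    out = matrix.copy()
    arr = out.values.to_numpy(copy=True)
    observed = arr[~np.isnan(arr)]
    if observed.size < min_observed:
        raise ValueError(
            f"need >= {min_observed} observed values to estimate the imputation "
            f"distribution, got {observed.size}"
        )
    loc = float(np.percentile(observed, percentile))
    rng = np.random.default_rng(seed)
    mask = np.isnan(arr)
    arr[mask] = rng.normal(loc, sd, size=int(mask.sum()))
    out.values = pd.DataFrame(arr, index=out.values.index, columns=out.values.columns)
    return out


def compute_cv(matrix: ProteinQuantMatrix, sample_group: Sequence[str]) -> dict[str, float]:
    """Coefficient of variation per protein over a replicate group.

    CV = sd / mean on the linear intensity scale (sd with ddof=1).  Proteins
    with fewer than two observed values in the group are omitted (CV
    undefined).
    """
    group = [s for s in sample_group]
    missing = [s for s in group if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    sub = matrix.values[group]
    cvs: dict[str, float] = {}
    for protein, row in sub.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size < 2:
            continue
        linear = np.exp2(vals)
        cvs[protein] = float(np.std(linear, ddof=1) / np.mean(linear))
    return cvs
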