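"""Biotinylation-site analysis of the acidic second elution.

The acidic second elution releases the biotinylated peptides themselves, so
each ``Biotin_K``-carrying precursor pins a direct biotinylation site to a
1-based lysine position on the parent protein.  This module extracts and
quantifies those sites, counts them per replicate group, and compares
site-level to protein-level fold changes (direct-interaction evidence vs
coenrichment).  Site-level differential testing reuses the protein engine
unchanged: one engine, two levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialResult, compare_distributions
from .io_annotations import parse_modified_peptide, strip_modifications
from .quantify import ProteinQuantMatrix, as_frame

__all__ = [
    "BiotinSite",
    "SiteCounts",
    "ConcordanceResult",
    "extract_sites",
    "site_matrix",
    "count_sites",
    "site_protein_concordance",
]

SITE_SEP = "@"  # matrix row id = f"{protein}{SITE_SEP}{position}"


@dataclass
class BiotinSite:
    """A biotinylated lysine: protein accession + 1-based position.

    ``intensities`` maps sample id -> linear intensity aggregated over all
    precursors covering the site (max by default, robust to charge-state
    duplication).
    """

    protein: str
    position: int
    best_peptide: str
    intensities: dict[str, float]


@dataclass
class SiteCounts:
    per_sample: pd.Series  # sites observed per sample
    group_means: dict[str, float]
    statistic: float | None  # one-way ANOVA across groups; None if refused
    p_value: float | None
    refused: bool = False


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # protein, position, site_fc, protein_fc
    pearson_r: float | None
    p_value: float | None
    refused: bool = False


def extract_sites(
    records,
    peptide_starts: Mapping[tuple[str, str], int],
    aggregate: str = "max",
) -> tuple[list[BiotinSite], int]:
    """Extract biotinylation sites from second-elution precursor records.

    ``peptide_starts`` maps ``(protein_group, bare_peptide_sequence)`` to the
    1-based protein position of the peptide's first residue.  Records whose
    peptide has no mapping are skipped and counted (second return value).
    One site is emitted per distinct (protein, lysine position); its
    per-sample intensity is the max (or, with ``aggregate="sum"``, the sum)
    over covering precursors, and ``best_peptide`` is the covering peptide
    with the highest median intensity.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError(f"aggregate must be 'max' or 'sum', got {aggregate!r}")
    frame = as_frame(records).dropna(subset=["intensity"])
    sites: dict[tuple[str, int], dict[str, float]] = {}
    peptide_for: dict[tuple[str, int], dict[str, list[float]]] = {}
    n_skipped = 0
    for row in frame.itertuples(index=False):
        if "Biotin_K" not in row.modified_sequence:
            continue
        bare = strip_modifications(row.modified_sequence)
        key = (row.protein_group, bare)
        if key not in peptide_starts:
            n_skipped += 1
            continue
        tokens = parse_modified_peptide(row.modified_sequence, peptide_starts[key])
        for residue, position, mod in tokens:
            if mod != "Biotin_K":
                continue
            site = (row.protein_group, position)
            per_sample = sites.setdefault(site, {})
            if aggregate == "max":
                per_sample[row.sample_id] = max(
                    per_sample.get(row.sample_id, -np.inf), float(row.intensity)
                )
            else:
                per_sample[row.sample_id] = per_sample.get(row.sample_id, 0.0) + float(
                    row.intensity
                )
            peptide_for.setdefault(site, {}).setdefault(row.modified_sequence, []).append(
                float(row.intensity)
            )
    out = []
    for protein, position in sorted(sites):
        cover = peptide_for[(protein, position)]
        best = max(sorted(cover), key=lambda pep: float(np.median(cover[pep])))
        out.append(BiotinSite(protein, position, best, dict(sites[(protein, position)])))
    return out, n_skipped


def site_matrix(sites: Sequence[BiotinSite], samples: Sequence[str]) -> ProteinQuantMatrix:
    """Sites x samples log2 matrix, rows keyed ``protein@position``.

    Shaped as a :class:`ProteinQuantMatrix` so the protein differential
    engine applies to sites without modification.
    """
    index = [f"{s.protein}{SITE_SEP}{s.position}" for s in sites]
    values = pd.DataFrame(np.nan, index=pd.Index(index, name="protein"), columns=list(samples))
    for site, row_id in zip(sites, index):
        for sample, intensity in site.intensities.items():
            if sample in values.columns:
                values.at[row_id, sample] = np.log2(intensity)
    counts = {row_id: 2 for row_id in index}  # sites pass support filtering by construction
    return ProteinQuantMatrix(values, counts, [])


def split_site_id(row_id: str) -> tuple[str, int]:
    protein, position = row_id.rsplit(SITE_SEP, 1)
    return protein, int(position)


def count_sites(
    sites: Sequence[BiotinSite], sample_groups: Mapping[str, Sequence[str]]
) -> SiteCounts:
    """Per-replicate biotin-site counts with a one-way ANOVA group comparison.

    A site counts as observed in a sample if it has an intensity there.  The
    ANOVA is refused (with a flag) when any group has fewer than two samples.
    """
    all_samples = [s for group in sample_groups.values() for s in group]
    counts = pd.Series(0, index=pd.Index(all_samples, name="sample_id"), dtype=int)
    for site in sites:
        for sample in site.intensities:
            if sample in counts.index:
                counts[sample] += 1
    group_values = {g: counts[list(ss)].to_numpy(dtype=float) for g, ss in sample_groups.items()}
    group_means = {g: float(np.mean(v)) if v.size else float("nan") for g, v in group_values.items()}
    if any(v.size < 2 for v in group_values.values()) or len(group_values) < 2:
        return SiteCounts(counts, group_means, None, None, refused=True)
    statistic, p = compare_distributions(*group_values.values(), method="anova")
    return SiteCounts(counts, group_means, statistic, p, refused=False)


def site_protein_concordance(
    site_differentials: DifferentialResult | pd.DataFrame,
    protein_differentials: DifferentialResult | pd.DataFrame,
) -> ConcordanceResult:
    """Site-level vs parent-protein fold-change agreement.

    Joins each biotinylation site's avg log2 ratio (second elution) with its
    parent protein's (first elution); only sites whose parent protein was
    quantified in both elutions enter.  Pearson r over the joined pairs;
    refused (r = None) with fewer than 3 pairs.
    """
    site_tab = site_differentials.table if isinstance(site_differentials, DifferentialResult) else site_differentials
    prot_tab = (
        protein_differentials.table
        if isinstance(protein_differentials, DifferentialResult)
        else protein_differentials
    )
    prot_fc = dict(zip(prot_tab["protein"], prot_tab["avg_log2_ratio"]))
    rows = []
    for row in site_tab.itertuples(index=False):
        protein, position = split_site_id(row.protein)
        if protein not in prot_fc:
            continue
        rows.append(
            {
                "protein": protein,
                "position": position,
                "site_fc": float(row.avg_log2_ratio),
                "protein_fc": float(prot_fc[protein]),
            }
        )
    table = pd.DataFrame(rows, columns=["protein", "position", "site_fc", "protein_fc"])
    if len(table) < 3:
        return ConcordanceResult(table, None, None, refused=True)
    r, p = stats.pearsonr(table["site_fc"], table["protein_fc"])
    return ConcordanceResult(table, float(r), float(p), refused=False)
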