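"""Per-protein differential enrichment and distribution-comparison tests.

The bait-vs-control contrast is a two-sided Welch unequal-variance t-test on
log2 intensities, with Benjamini-Hochberg adjustment across all tested
proteins (reported as the Q-value).  The same engine is reused unchanged for
biotinylation-site-level contrasts.  Group-level distribution comparisons
(replicate CVs, fold-change shifts, site counts) use the Wilcoxon rank-sum
test or one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import ProteinQuantMatrix

__all__ = [
    "DifferentialResult",
    "test_enrichment",
    "bh_adjust",
    "compare_distributions",
]

DIFFERENTIAL_COLUMNS = ["protein", "avg_log2_ratio", "p_value", "q_value", "n_bait", "n_control"]


@dataclass
class DifferentialResult:
    """Candidate table for one contrast plus the proteins that could not be tested."""

    table: pd.DataFrame  # columns: DIFFERENTIAL_COLUMNS
    skipped: list[str]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        bad = p[np.isnan(p) | (p < 0) | (p > 1)]
        raise ValueError(f"p-values must lie in [0, 1]; offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def _welch_p(bait: np.ndarray, control: np.ndarray) -> float:
    vb, vc = np.var(bait, ddof=1), np.var(control, ddof=1)
    if vb == 0.0 and vc == 0.0:
        # degenerate: no within-group variability; identical means carry no
        # evidence, different means are infinitely strong
        return 1.0 if np.mean(bait) == np.mean(control) else 0.0
    return float(stats.ttest_ind(bait, control, equal_var=False).pvalue)


def test_enrichment(
    matrix: ProteinQuantMatrix,
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
) -> DifferentialResult:
    """Welch t-test per protein for a bait-vs-control contrast.

    ``avg_log2_ratio`` = mean(bait) - mean(control) on the log2 scale.
    Proteins with fewer than two observed values on either side are skipped
    and reported.  Q-values are BH-adjusted over all tested proteins.
    """
    for name, group in (("bait", bait_samples), ("control", control_samples)):
        absent = [s for s in group if s not in matrix.values.columns]
        if absent:
            raise ValueError(f"{name} samples not in matrix: {absent}")
        if len(group) < 2:
            raise ValueError(f"need >= 2 {name} samples, got {len(group)}")

    rows = []
    skipped: list[str] = []
    bait_block = matrix.values[list(bait_samples)].to_numpy()
    ctrl_block = matrix.values[list(control_samples)].to_numpy()
    for i, protein in enumerate(matrix.values.index):
        bait = bait_block[i][~np.isnan(bait_block[i])]
        control = ctrl_block[i][~np.isnan(ctrl_block[i])]
        if bait.size < 2 or control.size < 2:
            skipped.append(protein)
            continue
        rows.append(
            {
                "protein": protein,
                "avg_log2_ratio": float(np.mean(bait) - np.mean(control)),
                "p_value": _welch_p(bait, control),
                "n_bait": int(bait.size),
                "n_control": int(control.size),
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in DIFFERENTIAL_COLUMNS if c != "q_value"])
    if not table.empty:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["q_value"] = pd.Series(dtype=float)
    return DifferentialResult(table[DIFFERENTIAL_COLUMNS], skipped)


def compare_distributions(
    *groups: Sequence[float], method: str = "wilcoxon"
) -> tuple[float, float]:
    """Compare value distributions between groups.

    ``wilcoxon``: two-sided Wilcoxon rank-sum (Mann-Whitney U) on exactly two
    groups; the null distribution is enumerated exactly when both groups have
    n <= 8 and there are no ties, otherwise the normal approximation with tie
    correction is used.  ``anova``: standard one-way ANOVA across >= 2 groups.

    Returns ``(statistic, p_value)``.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if method == "wilcoxon":
        if len(groups) != 2:
            raise ValueError(f"wilcoxon requires exactly 2 groups, got {len(groups)}")
        x = np.asarray(groups[0], dtype=float)
        y = np.asarray(groups[1], dtype=float)
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        how = "exact" if (tie_free and x.size <= 8 and y.size <= 8) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=how)
        return float(res.statistic), float(res.pvalue)
    if method == "anova":
        if len(groups) < 2:
            raise ValueError("anova requires >= 2 groups")
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if np.ptp(np.concatenate(arrays)) == 0.0:
            # no variance anywhere: zero between-group spread, no evidence
            return 0.0, 1.0
        res = stats.f_oneway(*arrays)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
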