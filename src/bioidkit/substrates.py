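"""Proteasome-substrate calling from MG132 vs vehicle contrasts.

Trapping substrates at the proteasome with the inhibitor MG132 makes them
proximity-labeled; a protein is a *potential substrate* when it is enriched
(bait vs control) under MG132 (fold change log2 > 1.5 and Q < 0.05 by
default) but not under vehicle.  Candidates that are also significantly
upregulated in the whole-cell proteome under MG132 are demoted, since their
apparent enrichment can be explained by abundance alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import DifferentialResult

__all__ = [
    "SUBSTRATE_COLUMNS",
    "call_substrates",
    "exclude_proteome_regulated",
    "overlap_known",
    "candidate_set",
]

logger = logging.getLogger(__name__)

SUBSTRATE_COLUMNS = [
    "protein",
    "fc_mg132",
    "q_mg132",
    "fc_vehicle",
    "q_vehicle",
    "missing_mg132",
    "missing_vehicle",
    "proteome_upregulated",
    "is_candidate",
    "known_ubiquitylated",
]


def _as_table(diff: DifferentialResult | pd.DataFrame) -> pd.DataFrame:
    return diff.table if isinstance(diff, DifferentialResult) else diff


def _enriched(fc: pd.Series, q: pd.Series, t_fc: float, t_q: float) -> pd.Series:
    # NaN (protein untested in this contrast) counts as not enriched
    return (fc > t_fc) & (q < t_q) & fc.notna() & q.notna()


def call_substrates(
    mg132: DifferentialResult | pd.DataFrame,
    vehicle: DifferentialResult | pd.DataFrame,
    t_fc: float = 1.5,
    t_q: float = 0.05,
) -> pd.DataFrame:
    """Candidate substrate calls from the MG132 and vehicle contrasts.

    The two contrasts are outer-joined on protein; a protein missing from one
    contrast is treated as not enriched there and flagged.  A candidate is
    enriched under MG132 and NOT enriched under vehicle (the vehicle
    condition uses the negation of the same thresholds).
    """
    mg = _as_table(mg132)[["protein", "avg_log2_ratio", "q_value"]].rename(
        columns={"avg_log2_ratio": "fc_mg132", "q_value": "q_mg132"}
    )
    veh = _as_table(vehicle)[["protein", "avg_log2_ratio", "q_value"]].rename(
        columns={"avg_log2_ratio": "fc_vehicle", "q_value": "q_vehicle"}
    )
    calls = mg.merge(veh, on="protein", how="outer", sort=True)
    calls["missing_mg132"] = calls["fc_mg132"].isna()
    calls["missing_vehicle"] = calls["fc_vehicle"].isna()
    enriched_mg = _enriched(calls["fc_mg132"], calls["q_mg132"], t_fc, t_q)
    enriched_veh = _enriched(calls["fc_vehicle"], calls["q_vehicle"], t_fc, t_q)
    calls["proteome_upregulated"] = False
    calls["is_candidate"] = enriched_mg & ~enriched_veh
    calls["known_ubiquitylated"] = False
    return calls[SUBSTRATE_COLUMNS].reset_index(drop=True)


def exclude_proteome_regulated(
    calls: pd.DataFrame,
    proteome: DifferentialResult | pd.DataFrame | None,
    t_fc: float = 1.5,
    t_q: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Demote candidates that MG132 upregulates in the whole-cell proteome.

    ``proteome`` is the whole-proteome MG132-vs-vehicle contrast; proteins
    significantly upregulated there (same thresholds by default) cannot be
    distinguished from abundance artifacts and lose candidate status.  If the
    contrast is unavailable the step is skipped with a warning.  Returns the
    updated calls and a report with the demoted fraction.
    """
    calls = calls.copy()
    n_before = int(calls["is_candidate"].sum())
    if proteome is None:
        logger.warning("whole-proteome contrast unavailable; confounder exclusion skipped")
        return calls, {"skipped": True, "n_candidates_before": n_before, "n_demoted": 0,
                       "demoted_fraction": 0.0, "demoted": []}
    tab = _as_table(proteome)
    upregulated = set(
        tab.loc[_enriched(tab["avg_log2_ratio"], tab["q_value"], t_fc, t_q), "protein"]
    )
    in_up = calls["protein"].isin(upregulated)
    calls.loc[in_up, "proteome_upregulated"] = True
    demoted_mask = in_up & calls["is_candidate"]
    calls.loc[demoted_mask, "is_candidate"] = False
    demoted = sorted(calls.loc[demoted_mask, "protein"])
    report = {
        "skipped": False,
        "n_candidates_before": n_before,
        "n_demoted": len(demoted),
        "demoted_fraction": (len(demoted) / n_before) if n_before else 0.0,
        "demoted": demoted,
    }
    return calls, report


def candidate_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.loc[calls["is_candidate"], "protein"])


def overlap_known(
    calls_by_construct: Mapping[str, pd.DataFrame], known_ubiquitylated: set[str]
) -> dict:
    """Overlap of candidate substrates with known ubiquitylation responders.

    Per construct: candidate count, overlap with the known set and its
    fraction; plus pairwise shared/unique candidate sets between constructs.
    Also marks ``known_ubiquitylated`` in-place on each calls table.
    """
    summary: dict = {"constructs": {}, "pairwise": {}}
    candidates: dict[str, set[str]] = {}
    for name, calls in calls_by_construct.items():
        calls["known_ubiquitylated"] = calls["protein"].isin(known_ubiquitylated)
        cand = candidate_set(calls)
        candidates[name] = cand
        overlap = cand & known_ubiquitylated
        summary["constructs"][name] = {
            "n_candidates": len(cand),
            "n_known": len(overlap),
            "fraction_known": (len(overlap) / len(cand)) if cand else 0.0,
        }
    for a, b in combinations(sorted(candidates), 2):
        shared = candidates[a] & candidates[b]
        summary["pairwise"][f"{a}|{b}"] = {
            "shared": len(shared),
            f"unique_{a}": len(candidates[a] - shared),
            f"unique_{b}": len(candidates[b] - shared),
        }
    return summary
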