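"""Config-driven orchestration of the full analysis.

One call (or ``bioidkit run``) executes: generate (synthetic mode) ->
ingest -> quantify -> differential -> classify -> biotin_sites ->
substrates -> qc, serializing every stage's outputs into a run directory
together with a manifest (config hash, seed, stage record counts, output
file hashes).  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import biotin_sites as sites_mod
from . import classifier as clf
from . import qc as qc_mod
from . import substrates as sub_mod
from .differential import DifferentialResult, compare_distributions, test_enrichment
from .io_annotations import (
    load_annotation_sets,
    read_precursor_report,
    records_to_frame,
)
from .quantify import (
    ProteinQuantMatrix,
    compute_cv,
    filter_precursors_percentile,
    impute_global,
    normalize_global_median,
    summarize_to_protein,
)
from .synthetic_data import GeneratorConfig, generate_experiment, generate_substrate_scenario

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_runs"]

logger = logging.getLogger(__name__)

STAGES = (
    "generate",
    "ingest",
    "quantify",
    "differential",
    "classify",
    "biotin_sites",
    "substrates",
    "qc",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML losslessly."""

    out_dir: str = "bioidkit_run"
    synthetic: bool = True
    # real-data inputs (ignored in synthetic mode)
    report_path: str | None = None
    samples_path: str | None = None
    annotation_dir: str | None = None
    # thresholds (defaults mirror the study's printed values)
    t_fc: float = 1.5
    t_q: float = 0.05
    alpha: float = 0.05
    precursor_filter_fraction: float = 0.2
    score_weights: tuple[float, float] = (1.0, 1.0)
    top_ns: tuple[int, ...] = (25, 50, 100, 250)
    seed: int = 0
    # stage toggles (required stages cannot be disabled)
    run_biotin_sites: bool = True
    run_substrates: bool = True
    run_qc: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.t_q <= 1 and 0 < self.alpha <= 1):
            raise ValueError("thresholds out of range")
        if not 0 <= self.precursor_filter_fraction <= 1:
            raise ValueError("precursor_filter_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_weights"] = list(self.score_weights)
        d["top_ns"] = list(self.top_ns)
        d["generator"]["tp_log2_effect_range"] = list(
            self.generator.tp_log2_effect_range
        )
        d["generator"]["precursors_per_protein"] = list(self.generator.precursors_per_protein)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = dict(data.pop("generator", {}))
        for key in ("tp_log2_effect_range", "precursors_per_protein"):
            if key in gen:
                gen[key] = tuple(gen[key])
        for key in ("score_weights", "top_ns"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(generator=GeneratorConfig(**gen), **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def quantify_records(records, filter_fraction: float, seed: int) -> ProteinQuantMatrix:
    """Standard quantification chain: normalize -> filter -> roll up -> impute."""
    frame = normalize_global_median(records)
    frame = filter_precursors_percentile(frame, filter_fraction)
    matrix = summarize_to_protein(frame)
    return impute_global(matrix, seed=seed)


def score_experiment(
    experiment,
    filter_fraction: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
    weights: tuple[float, float] = (1.0, 1.0),
):
    """Quantify + test + classify one (synthetic or ingested) experiment.

    Convenience wrapper over the standard chain, using the experiment's
    annotation sets with the lid exclusion applied.  Returns
    ``(ranked_table, classifier_report, differential_result)``.
    """
    frame = records_to_frame(experiment.records)
    first = frame[~frame["modified_sequence"].str.contains("Biotin_K", regex=False)]
    matrix = quantify_records(first, filter_fraction, seed=seed)
    diff = test_enrichment(matrix, experiment.bait_samples, experiment.control_samples)
    tp_set = (
        experiment.annotation_sets["proteasome_associates"]
        - experiment.annotation_sets.get("lid_members", set())
    )
    tn_set = experiment.annotation_sets["mito_true_negatives"]
    from .classifier import classify_interactors

    ranked, report = classify_interactors(diff.table, tp_set, tn_set, alpha=alpha, weights=weights)
    return ranked, report, diff


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory.

    On stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage, and a :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }
    stage = "setup"
    t_stage = time.perf_counter()

    def begin(name: str) -> None:
        nonlocal stage, t_stage
        stage = name
        t_stage = time.perf_counter()
        logger.info("stage %s: start", name)

    def done(**counts) -> None:
        manifest["stages"].append({"name": stage, **counts})
        logger.info("stage %s: done in %.2fs %s", stage, time.perf_counter() - t_stage, counts)

    try:
        # -- generate ------------------------------------------------------
        begin("generate")
        if config.synthetic:
            gen = replace(config.generator, seed=config.seed)
            experiment = generate_experiment(gen)
            data_dir = out / "data"
            experiment.write(data_dir)
            scenario = None
            if config.run_substrates:
                scenario = generate_substrate_scenario(replace(gen, seed=config.seed + 1))
            done(n_records=len(experiment.records), n_samples=len(experiment.samples))
            report_path = data_dir / "report.tsv"
            samples_path = data_dir / "samples.tsv"
            annotation_dir = data_dir / "annotation_sets"
            peptide_starts = experiment.peptide_starts
            truth = experiment.truth
        else:
            for name, path in (
                ("report_path", config.report_path),
                ("samples_path", config.samples_path),
                ("annotation_dir", config.annotation_dir),
            ):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {path}")
            report_path = Path(config.report_path)
            samples_path = Path(config.samples_path)
            annotation_dir = Path(config.annotation_dir)
            scenario = None
            peptide_starts = {}
            truth = None
            done()

        # -- ingest --------------------------------------------------------
        begin("ingest")
        records, annotations = read_precursor_report(report_path, samples_path)
        annotation_sets = {
            name: s.accessions for name, s in load_annotation_sets(annotation_dir).items()
        }
        bait_samples = [a.sample_id for a in annotations if a.bait == "bait"]
        control_samples = [a.sample_id for a in annotations if a.bait == "control"]
        done(n_records=len(records), n_bait=len(bait_samples), n_control=len(control_samples))

        # -- quantify ------------------------------------------------------
        begin("quantify")
        frame = records_to_frame(records)
        first_elution = frame[~frame["modified_sequence"].str.contains("Biotin_K", regex=False)]
        matrix = quantify_records(
            first_elution, config.precursor_filter_fraction, seed=config.seed + 11
        )
        matrix.write(out / "protein_matrix.tsv")
        (out / "excluded_single_hit.txt").write_text(
            "".join(f"{p}\n" for p in matrix.excluded_single_hit), encoding="utf-8"
        )
        cv_rows = []
        for group, group_samples in (("bait", bait_samples), ("control", control_samples)):
            for protein, cv in compute_cv(matrix, group_samples).items():
                cv_rows.append({"protein": protein, "group": group, "cv": cv})
        cv_table = pd.DataFrame(cv_rows, columns=["protein", "group", "cv"])
        cv_table.to_csv(out / "cvs.tsv", sep="\t", index=False)
        done(n_proteins=len(matrix.proteins), n_single_hit=len(matrix.excluded_single_hit))

        # -- differential --------------------------------------------------
        begin("differential")
        diff = test_enrichment(matrix, bait_samples, control_samples)
        diff.write(out / "candidates.tsv")
        done(n_tested=len(diff.table), n_skipped=len(diff.skipped))

        # -- classify ------------------------------------------------------
        begin("classify")
        tp_set = set(annotation_sets.get("proteasome_associates", set()))
        tn_set = set(annotation_sets.get("mito_true_negatives", set()))
        ranked, report = clf.classify_interactors(
            diff.table, tp_set, tn_set, alpha=config.alpha, weights=config.score_weights
        )
        ranked.to_csv(out / "ranked_interactors.tsv", sep="\t", index=False)
        known_union = (
            tp_set | set(annotation_sets.get("PIPs", set())) | set(annotation_sets.get("UPS", set()))
        )
        enriched = set(ranked.loc[ranked["above_cutoff"], "protein"])
        classifier_summary = report.to_dict()
        classifier_summary["interactor_fraction_pct"] = (
            clf.interactor_fraction(enriched, known_union) if enriched else None
        )
        topn_sets = {
            name: set(annotation_sets[name])
            for name in ("proteasome_associates", "PIPs", "UPS")
            if name in annotation_sets
        }
        ranks = pd.Series(
            ranked["rank"].to_numpy(), index=ranked["protein"].to_numpy(), name="rank"
        )
        topn = clf.topn_recovery(ranks, topn_sets, list(config.top_ns))
        topn.to_csv(out / "topn_recovery.tsv", sep="\t", index=False)
        _write_json(classifier_summary, out / "classifier_report.json")
        done(n_enriched=report.n_enriched, f1=report.f1)

        # -- biotin_sites --------------------------------------------------
        site_summary: dict = {"enabled": bool(config.run_biotin_sites)}
        if config.run_biotin_sites:
            begin("biotin_sites")
            second_elution = frame[frame["modified_sequence"].str.contains("Biotin_K", regex=False)]
            sites, n_skipped = sites_mod.extract_sites(second_elution, peptide_starts)
            smatrix = sites_mod.site_matrix(sites, bait_samples + control_samples)
            smatrix = (
                impute_global(smatrix, seed=config.seed + 13)
                if smatrix.values.notna().sum().sum() >= 20
                else smatrix
            )
            site_rows = [
                {
                    "protein": s.protein,
                    "position": s.position,
                    "best_peptide": s.best_peptide,
                    **{k: s.intensities.get(k, "") for k in bait_samples + control_samples},
                }
                for s in sites
            ]
            pd.DataFrame(site_rows).to_csv(out / "biotin_sites.tsv", sep="\t", index=False)
            site_summary.update({"n_sites": len(sites), "n_unmapped_records": n_skipped})
            if len(sites) >= 3 and not smatrix.values.isna().any().any():
                site_diff = test_enrichment(smatrix, bait_samples, control_samples)
                site_diff.write(out / "site_candidates.tsv")
                concordance = sites_mod.site_protein_concordance(site_diff, diff)
                concordance.table.to_csv(out / "site_concordance.tsv", sep="\t", index=False)
                site_summary["concordance_r"] = concordance.pearson_r
                counts = sites_mod.count_sites(
                    sites, {"bait": bait_samples, "control": control_samples}
                )
                site_summary["site_counts_per_sample"] = counts.per_sample.to_dict()
            _write_json(site_summary, out / "biotin_sites_report.json")
            done(**{k: v for k, v in site_summary.items() if isinstance(v, (int, float))})

        # -- substrates ----------------------------------------------------
        if config.run_substrates and scenario is not None:
            begin("substrates")
            contrasts = {}
            for name, exp in (("mg132", scenario.mg132), ("vehicle", scenario.vehicle)):
                m = quantify_records(
                    records_to_frame(exp.records),
                    config.precursor_filter_fraction,
                    seed=config.seed + 17,
                )
                contrasts[name] = test_enrichment(m, exp.bait_samples, exp.control_samples)
            wp_matrix = quantify_records(
                records_to_frame(scenario.proteome_records),
                config.precursor_filter_fraction,
                seed=config.seed + 19,
            )
            mg_arm = [s.sample_id for s in scenario.proteome_samples if s.treatment == "MG132"]
            veh_arm = [s.sample_id for s in scenario.proteome_samples if s.treatment == "vehicle"]
            proteome_diff = test_enrichment(wp_matrix, mg_arm, veh_arm)
            calls = sub_mod.call_substrates(
                contrasts["mg132"], contrasts["vehicle"], config.t_fc, config.t_q
            )
            calls, demotion = sub_mod.exclude_proteome_regulated(
                calls, proteome_diff, config.t_fc, config.t_q
            )
            overlap = sub_mod.overlap_known(
                {"main": calls}, set(annotation_sets.get("known_ubiquitylated", set()))
            )
            calls.to_csv(out / "substrate_calls.tsv", sep="\t", index=False)
            _write_json(
                {"demotion": {k: v for k, v in demotion.items() if k != "demoted"},
                 "overlap": overlap},
                out / "substrate_summary.json",
            )
            done(n_candidates=int(calls["is_candidate"].sum()), n_demoted=demotion["n_demoted"])
        elif config.run_substrates:
            begin("substrates")
            done(skipped=1)

        # -- qc ------------------------------------------------------------
        if config.run_qc:
            begin("qc")
            pca = qc_mod.pca_qc(matrix, {"bait": bait_samples, "control": control_samples})
            ids = qc_mod.id_counts(frame)
            ids.to_csv(out / "id_counts.tsv", sep="\t", index=False)
            first_proteins = set(first_elution.dropna(subset=["intensity"])["protein_group"])
            second_proteins = set(
                frame[frame["modified_sequence"].str.contains("Biotin_K", regex=False)]
                .dropna(subset=["intensity"])["protein_group"]
            )
            venn = qc_mod.venn_counts(first_proteins, second_proteins)
            qc_report = {
                "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
                "pca_centroids": {g: [float(x) for x in c] for g, c in pca.centroids.items()},
                "venn_first_vs_second_elution": {
                    "only_first": venn.only_a,
                    "only_second": venn.only_b,
                    "shared": venn.shared,
                    "union": venn.union,
                    "pct_shared_of_first": venn.pct_shared_of_a,
                },
                "cv_median": {
                    group: float(cv_table.loc[cv_table["group"] == group, "cv"].median())
                    for group in ("bait", "control")
                    if (cv_table["group"] == group).any()
                },
            }
            _write_json(qc_report, out / "qc_report.json")
            done(n_components=len(pca.explained_variance_ratio))

    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    _write_json(manifest, out / "manifest.json")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out


def compare_runs(run_dirs: Sequence[str | Path], axis: str = "workflow") -> dict:
    """Side-by-side comparison of >= 2 completed runs along an experimental axis.

    Reports per-run F1, identification counts, CV medians and topN recovery,
    pairwise deltas, and Wilcoxon comparisons of the per-protein CV
    distributions (computed on the protein intersection when the universes
    differ, which is reported).
    """
    if axis not in ("workflow", "input", "gradient"):
        raise ValueError(f"unknown comparison axis {axis!r}")
    if len(run_dirs) < 2:
        raise ValueError("need >= 2 run directories")
    runs = {}
    for position, run_dir in enumerate(run_dirs):
        run_dir = Path(run_dir)
        name = f"run{position}:{run_dir.name}"
        report = json.loads((run_dir / "classifier_report.json").read_text(encoding="utf-8"))
        ids = pd.read_csv(run_dir / "id_counts.tsv", sep="\t")
        cvs = pd.read_csv(run_dir / "cvs.tsv", sep="\t")
        topn = pd.read_csv(run_dir / "topn_recovery.tsv", sep="\t")
        runs[name] = {"report": report, "ids": ids, "cvs": cvs, "topn": topn}

    comparison: dict = {"axis": axis, "runs": {}, "pairwise": {}}
    for name, data in runs.items():
        comparison["runs"][name] = {
            "f1": data["report"]["f1"],
            "n_enriched": data["report"]["n_enriched"],
            "mean_protein_groups": float(data["ids"]["protein_groups"].mean()),
            "cv_median": {
                group: float(sub["cv"].median())
                for group, sub in data["cvs"].groupby("group")
            },
            "topn": {
                f"{row.set}@{row.top_n}": int(row.count_)
                for row in data["topn"]
                .rename(columns={"count": "count_"})
                .itertuples(index=False)
            },
        }
    names = list(runs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair: dict = {"delta_f1": runs[b]["report"]["f1"] - runs[a]["report"]["f1"]}
            for group in ("bait", "control"):
                cv_a = runs[a]["cvs"].query("group == @group").set_index("protein")["cv"]
                cv_b = runs[b]["cvs"].query("group == @group").set_index("protein")["cv"]
                common = cv_a.index.intersection(cv_b.index)
                pair[f"cv_{group}_n_common"] = int(len(common))
                if len(common) >= 2:
                    _, p = compare_distributions(
                        cv_a.loc[common].to_numpy(), cv_b.loc[common].to_numpy(),
                        method="wilcoxon",
                    )
                    pair[f"cv_{group}_wilcoxon_p"] = float(p)
            comparison["pairwise"][f"{a}|{b}"] = pair
    return comparison
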