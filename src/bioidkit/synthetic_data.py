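"""Seeded synthetic BioID experiments with known ground truth.

Emulates the statistical structure of a bait-vs-control proximity-labeling
experiment measured by DIA label-free quantification, so that every
downstream stage (quantification, differential testing, classification,
site analysis, substrate calling) can be exercised against planted truth:

* two groups (bait-ligase fusion vs ligase-only control) with ``n_replicates``
  independent replicates each;
* a true-positive set of specifically enriched proteins with log2 effects
  drawn from ``tp_log2_effect_range``;
* an equally-abundant, naturally biotinylated true-negative set (zero
  effect) plus a few "lid" members listed with the positives but not
  directly biotinylated (exercising the lid exclusion);
* bystander background proteins whose abundance scales with
  ``background_binding`` — unspecific carry-over also adds a linear-scale
  floor to the control side of enriched proteins, attenuating large
  apparent fold changes the way unspecific bead binding does;
* log-normal intensity noise with group-specific CVs (control higher),
  per-precursor response factors, and missing-not-at-random censoring of
  the lowest intensities;
* biotinylated-lysine peptides (``Biotin_K``) on a configurable fraction of
  the true positives.

All randomness flows from a single seeded generator; identical
configurations produce byte-identical serialized outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .io_annotations import (
    PrecursorRecord,
    SampleAnnotation,
    write_annotation_set,
    write_precursor_report,
    write_sample_annotation,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticExperiment",
    "SubstrateScenario",
    "generate_experiment",
    "generate_substrate_scenario",
]

#: Fraction of a protein's cellular abundance that unspecifically carries
#: over onto the beads (scaled by ``background_binding``).
CARRYOVER_FRACTION = 0.02

#: Extra per-precursor-per-sample measurement noise (log2 sd) on top of the
#: shared protein-level replicate noise.
PRECURSOR_NOISE_SD = 0.1

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for termini


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic BioID generator.

    Defaults mirror a four-replicate bait-vs-control design with strong
    planted enrichment (log2 effects 2-6), moderate control-side noise
    (CV 25% vs 15% for bait) and mild intensity-dependent missingness.
    """

    n_replicates: int = 4
    n_tp: int = 60
    n_tn: int = 60
    n_background: int = 600
    n_lid: int = 5
    tp_log2_effect_range: tuple[float, float] = (2.0, 6.0)
    background_binding: float = 0.25
    cv_bait: float = 0.15
    cv_control: float = 0.25
    missing_rate: float = 0.05
    biotin_site_fraction: float = 0.5
    precursors_per_protein: tuple[int, int] = (2, 6)
    n_substrates: int = 40
    confounder_fraction: float = 0.1
    workflow: str = "automated"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_replicates": self.n_replicates,
            "n_tp": self.n_tp,
            "n_tn": self.n_tn,
            "n_background": self.n_background,
            "n_lid": self.n_lid,
            "n_substrates": self.n_substrates,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name, value in (
            ("missing_rate", self.missing_rate),
            ("biotin_site_fraction", self.biotin_site_fraction),
            ("confounder_fraction", self.confounder_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.cv_bait <= 0 or self.cv_control <= 0:
            raise ValueError("cv values must be > 0")
        if self.background_binding < 0:
            raise ValueError("background_binding must be >= 0")
        lo, hi = self.tp_log2_effect_range
        if lo > hi:
            raise ValueError(f"tp_log2_effect_range must be ordered, got ({lo}, {hi})")
        plo, phi = self.precursors_per_protein
        if plo < 1 or plo > phi:
            raise ValueError(f"invalid precursors_per_protein range ({plo}, {phi})")


@dataclass
class GroundTruth:
    """Latent truth of a simulated experiment."""

    tp_accessions: set[str] = field(default_factory=set)
    tn_accessions: set[str] = field(default_factory=set)
    substrate_accessions: set[str] = field(default_factory=set)
    confounder_accessions: set[str] = field(default_factory=set)
    true_log2_effects: dict[str, float] = field(default_factory=dict)
    site_positions: dict[str, list[int]] = field(default_factory=dict)

    def validate(self) -> None:
        sets = [self.tp_accessions, self.tn_accessions, self.substrate_accessions]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError(f"ground-truth sets overlap: {sorted(a & b)[:5]}")
        for acc, positions in self.site_positions.items():
            if any(p < 1 for p in positions):
                raise ValueError(f"site position < 1 for {acc}")


@dataclass
class SyntheticExperiment:
    records: list[PrecursorRecord]
    samples: list[SampleAnnotation]
    annotation_sets: dict[str, set[str]]
    truth: GroundTruth
    peptide_starts: dict[tuple[str, str], int]
    untrainable: bool = False  # no TP and no TN: classifier cannot be fit

    @property
    def bait_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.bait == "bait"]

    @property
    def control_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.bait == "control"]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_precursor_report(self.records, directory / "report.tsv")
        write_sample_annotation(self.samples, directory / "samples.tsv")
        sets_dir = directory / "annotation_sets"
        sets_dir.mkdir(exist_ok=True)
        for name, accessions in self.annotation_sets.items():
            write_annotation_set(accessions, sets_dir / f"{name}.txt")
        with open(directory / "ground_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("key\tvalue\n")
            for name in ("tp", "tn", "substrate", "confounder"):
                accs = getattr(self.truth, f"{name}_accessions")
                for acc in sorted(accs):
                    fh.write(f"{name}\t{acc}\n")
            for acc in sorted(self.truth.true_log2_effects):
                fh.write(f"effect:{acc}\t{self.truth.true_log2_effects[acc]!r}\n")
            for acc in sorted(self.truth.site_positions):
                positions = ",".join(str(p) for p in self.truth.site_positions[acc])
                fh.write(f"sites:{acc}\t{positions}\n")
        with open(directory / "peptide_starts.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein_group\tpeptide\tprotein_start\n")
            for (protein, bare) in sorted(self.peptide_starts):
                fh.write(f"{protein}\t{bare}\t{self.peptide_starts[(protein, bare)]}\n")


@dataclass
class SubstrateScenario:
    mg132: SyntheticExperiment
    vehicle: SyntheticExperiment
    proteome_records: list[PrecursorRecord]
    proteome_samples: list[SampleAnnotation]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# internal protein/peptide synthesis
# ---------------------------------------------------------------------------


@dataclass
class _Precursor:
    bare: str
    modified_sequence: str
    charge: int
    protein_start: int
    site_position: int | None = None  # set for Biotin_K precursors


@dataclass
class _Protein:
    accession: str
    cls: str  # TP / TN / BG / LID / SUB / CNF
    base: float  # log2 cellular abundance
    effect: float  # specific bait-vs-control log2 enrichment
    proteome_effect: float = 0.0  # MG132-vs-vehicle whole-proteome shift
    precursors: list[_Precursor] = field(default_factory=list)


def _log2_sd(cv: float) -> float:
    """Log2-scale sd of a log-normal with the given linear-scale CV."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2)


def _random_peptide(rng: np.random.Generator, used: set[str], biotin_k: bool) -> tuple[str, int]:
    """Unique bare peptide; for biotin peptides returns the internal K index."""
    while True:
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length - 1))
        terminal = "K" if rng.random() < 0.5 else "R"
        k_index = -1
        if biotin_k:
            k_index = int(rng.integers(0, length - 1))
            body = body[:k_index] + "K" + body[k_index + 1 :]
            terminal = "R"  # missed-cleavage-free C-terminus
        peptide = body + terminal
        if peptide not in used:
            used.add(peptide)
            return peptide, k_index


def _build_proteins(config: GeneratorConfig, rng: np.random.Generator) -> list[_Protein]:
    lo, hi = config.tp_log2_effect_range
    proteins: list[_Protein] = []

    def effect() -> float:
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    for cls, count in (
        ("TP", config.n_tp),
        ("TN", config.n_tn),
        ("LID", config.n_lid),
        ("BG", config.n_background),
        ("SUB", config.n_substrates),
        ("CNF", int(round(config.confounder_fraction * config.n_substrates))),
    ):
        for i in range(count):
            base = float(rng.normal(25.0, 1.5))
            proteins.append(
                _Protein(
                    accession=f"{cls}{i:04d}",
                    cls=cls,
                    base=base,
                    effect=effect() if cls in ("TP", "SUB", "CNF") else 0.0,
                    proteome_effect=float(rng.uniform(2.0, 4.0)) if cls == "CNF" else 0.0,
                )
            )
    used: set[str] = set()
    plo, phi = config.precursors_per_protein
    first_of_class: set[str] = set()
    for protein in proteins:
        if protein.cls not in first_of_class:
            # force one single-precursor protein per class to exercise the
            # single-hit filter downstream
            first_of_class.add(protein.cls)
            k = 1
        else:
            k = int(rng.integers(plo, phi + 1))
        for _ in range(k):
            bare, _ = _random_peptide(rng, used, biotin_k=False)
            protein.precursors.append(
                _Precursor(
                    bare=bare,
                    modified_sequence=f"_{bare}_",
                    charge=int(rng.integers(2, 4)),
                    protein_start=int(rng.integers(1, 400)),
                )
            )
    return proteins


def _attach_biotin_sites(
    proteins: list[_Protein], config: GeneratorConfig, rng: np.random.Generator
) -> None:
    tp = [p for p in proteins if p.cls == "TP"]
    n_with_sites = int(round(config.biotin_site_fraction * len(tp)))
    used = {prec.bare for p in proteins for prec in p.precursors}
    # take from the end: keeps the forced single-precursor TP protein single
    for protein in tp[len(tp) - n_with_sites :]:
        for _ in range(int(rng.integers(1, 4))):
            bare, k_index = _random_peptide(rng, used, biotin_k=True)
            start = int(rng.integers(1, 400))
            modseq = "_" + bare[: k_index + 1] + "[Biotin_K]" + bare[k_index + 1 :] + "_"
            protein.precursors.append(
                _Precursor(
                    bare=bare,
                    modified_sequence=modseq,
                    charge=int(rng.integers(2, 4)),
                    protein_start=start,
                    site_position=start + k_index,
                )
            )


def _group_mean(protein: _Protein, group: str, config: GeneratorConfig, enriched: set[str]) -> float | None:
    """Expected log2 intensity of a protein in a sample group; None = absent.

    ``enriched`` names the classes specifically enriched on the bait side in
    this report.  The control side of enriched proteins receives the
    unspecific carry-over floor ``background_binding * CARRYOVER_FRACTION *
    abundance``; bystanders are pure carry-over and vanish at
    ``background_binding = 0``.
    """
    b = config.background_binding
    floor = b * CARRYOVER_FRACTION * (2.0 ** protein.base)
    if protein.cls in enriched:
        if group == "bait":
            return protein.base
        return math.log2(2.0 ** (protein.base - protein.effect) + floor)
    if protein.cls == "BG":
        if b == 0.0:
            return None
        return protein.base + math.log2(b)
    # TN / LID (and unenriched SUB/CNF): specific, equal signal in both groups
    return protein.base


def _synthesize_report(
    proteins: list[_Protein],
    samples: list[SampleAnnotation],
    mean_fn: Callable[[_Protein, str], float | None],
    sd_by_group: dict[str, float],
    missing_rate: float,
    rng: np.random.Generator,
) -> list[PrecursorRecord]:
    """Draw, censor and assemble the long-format report (fixed row order)."""
    rows: list[tuple[str, str, str, int, float]] = []
    log2_values: list[float] = []
    for protein in proteins:
        for sample in samples:
            group = sample.bait
            mean = mean_fn(protein, group)
            if mean is None:
                continue
            shared = rng.normal(0.0, sd_by_group[group])
            for prec in protein.precursors:
                value = mean + shared + rng.normal(0.0, PRECURSOR_NOISE_SD)
                rows.append(
                    (sample.sample_id, protein.accession, prec.modified_sequence, prec.charge, value)
                )
                log2_values.append(value)
    if missing_rate > 0.0 and log2_values:
        threshold = float(np.quantile(np.asarray(log2_values), missing_rate))
    else:
        threshold = -math.inf
    return [
        PrecursorRecord(sid, acc, modseq, charge, 2.0 ** value)
        for sid, acc, modseq, charge, value in rows
        if value >= threshold
    ]


def _annotation_sets(
    proteins: list[_Protein], config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, set[str]]:
    by_class: dict[str, list[str]] = {}
    for protein in proteins:
        by_class.setdefault(protein.cls, []).append(protein.accession)
    tp = by_class.get("TP", [])
    tn = by_class.get("TN", [])
    lid = by_class.get("LID", [])
    bg = by_class.get("BG", [])
    sub = by_class.get("SUB", [])

    def sample(pool: list[str], k: int) -> set[str]:
        k = min(k, len(pool))
        if k == 0:
            return set()
        return {str(a) for a in rng.choice(np.array(pool), size=k, replace=False)}

    sets = {
        "proteasome_associates": set(tp) | set(lid),
        "lid_members": set(lid),
        "mito_true_negatives": set(tn),
        "PIPs": sample(tp, max(1, len(tp) // 4)) | sample(bg, len(bg) // 50),
        "UPS": sample(tp, max(1, len(tp) // 3)) | sample(bg, len(bg) // 30),
        "known_ubiquitylated": sample(sub, int(round(0.6 * len(sub)))) | sample(bg, len(bg) // 20),
    }
    return sets


def _truth(proteins: list[_Protein]) -> GroundTruth:
    truth = GroundTruth()
    for protein in proteins:
        if protein.cls == "TP":
            truth.tp_accessions.add(protein.accession)
        elif protein.cls == "TN":
            truth.tn_accessions.add(protein.accession)
        elif protein.cls == "SUB":
            truth.substrate_accessions.add(protein.accession)
        elif protein.cls == "CNF":
            truth.confounder_accessions.add(protein.accession)
        if protein.effect != 0.0:
            truth.true_log2_effects[protein.accession] = protein.effect
        sites = sorted(
            prec.site_position for prec in protein.precursors if prec.site_position is not None
        )
        if sites:
            truth.site_positions[protein.accession] = sites
    truth.validate()
    return truth


def _samples(config: GeneratorConfig, prefix: str, treatment: str) -> list[SampleAnnotation]:
    out = []
    for group in ("bait", "control"):
        for r in range(1, config.n_replicates + 1):
            out.append(
                SampleAnnotation(
                    sample_id=f"{prefix}{group}_{r}",
                    bait=group,
                    treatment=treatment,
                    workflow=config.workflow,
                    replicate=r,
                )
            )
    return out


def generate_experiment(config: GeneratorConfig) -> SyntheticExperiment:
    """Generate one bait-vs-control BioID experiment (substrate classes absent).

    Returns the long-format precursor report, sample annotation, curated
    annotation sets, peptide start coordinates and the planted ground truth.
    A configuration with neither TP nor TN proteins is generated anyway but
    flagged ``untrainable`` (the downstream classifier cannot be fit).
    """
    config.validate()
    config = replace(config, n_substrates=0, confounder_fraction=0.0)
    rng = np.random.default_rng(config.seed)
    proteins = _build_proteins(config, rng)
    _attach_biotin_sites(proteins, config, rng)
    annotation_sets = _annotation_sets(proteins, config, rng)
    samples = _samples(config, "", "none")
    sd = {"bait": _log2_sd(config.cv_bait), "control": _log2_sd(config.cv_control)}
    records = _synthesize_report(
        proteins,
        samples,
        lambda p, g: _group_mean(p, g, config, enriched={"TP"}),
        sd,
        config.missing_rate,
        rng,
    )
    starts = {
        (p.accession, prec.bare): prec.protein_start for p in proteins for prec in p.precursors
    }
    return SyntheticExperiment(
        records=records,
        samples=samples,
        annotation_sets=annotation_sets,
        truth=_truth(proteins),
        peptide_starts=starts,
        untrainable=(config.n_tp == 0 and config.n_tn == 0),
    )


def generate_substrate_scenario(config: GeneratorConfig) -> SubstrateScenario:
    """Generate the inhibitor-trapping scenario: MG132 + vehicle + proteome.

    Substrate proteins are enriched (bait vs control) only under MG132;
    confounders look identical in the BioID contrast but are additionally
    upregulated by MG132 in the whole-cell proteome.  Stable interactors
    (the TP class) are enriched under both treatments, so the vehicle
    exclusion removes them from the substrate calls.
    """
    config.validate()
    if config.n_substrates <= 0:
        raise ValueError("substrate scenario requires n_substrates > 0")
    rng = np.random.default_rng(config.seed)
    proteins = _build_proteins(config, rng)
    _attach_biotin_sites(proteins, config, rng)
    annotation_sets = _annotation_sets(proteins, config, rng)
    truth = _truth(proteins)
    starts = {
        (p.accession, prec.bare): prec.protein_start for p in proteins for prec in p.precursors
    }
    sd = {"bait": _log2_sd(config.cv_bait), "control": _log2_sd(config.cv_control)}

    mg_samples = _samples(config, "mg_", "MG132")
    mg_records = _synthesize_report(
        proteins,
        mg_samples,
        lambda p, g: _group_mean(p, g, config, enriched={"TP", "SUB", "CNF"}),
        sd,
        config.missing_rate,
        rng,
    )
    veh_samples = _samples(config, "veh_", "vehicle")
    veh_records = _synthesize_report(
        proteins,
        veh_samples,
        lambda p, g: _group_mean(p, g, config, enriched={"TP"}),
        sd,
        config.missing_rate,
        rng,
    )

    # whole-cell proteome: MG132 vs vehicle, everything at cellular abundance,
    # only confounders shifted
    wp_samples = []
    for treatment in ("MG132", "vehicle"):
        for r in range(1, config.n_replicates + 1):
            wp_samples.append(
                SampleAnnotation(
                    sample_id=f"wp_{treatment.lower()}_{r}",
                    bait="bait" if treatment == "MG132" else "control",
                    treatment=treatment,
                    workflow=config.workflow,
                    replicate=r,
                )
            )
    sd_wp = {"bait": _log2_sd(config.cv_bait), "control": _log2_sd(config.cv_bait)}

    def proteome_mean(protein: _Protein, group: str) -> float:
        if protein.cls == "CNF" and group == "bait":  # bait column = MG132 arm
            return protein.base + protein.proteome_effect
        return protein.base

    wp_records = _synthesize_report(
        proteins, wp_samples, proteome_mean, sd_wp, config.missing_rate, rng
    )

    def experiment(records, samples):
        return SyntheticExperiment(
            records=records,
            samples=samples,
            annotation_sets=annotation_sets,
            truth=truth,
            peptide_starts=starts,
            untrainable=(config.n_tp == 0 and config.n_tn == 0),
        )

    return SubstrateScenario(
        mg132=experiment(mg_records, mg_samples),
        vehicle=experiment(veh_records, veh_samples),
        proteome_records=wp_records,
        proteome_samples=wp_samples,
        truth=truth,
    )
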