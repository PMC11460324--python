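"""Tabular dialects and curated annotation sets consumed by the pipeline.

The quantification reports are long-format tab-separated tables in the
dialect exported by DIA search engines: one row per quantified precursor
per sample, with a modified-peptide string carrying bracketed modification
names (``_SK[Biotin_K]LER_``).  Annotation gene sets are one-accession-per-
line text files; ``#`` starts a comment.

Coordinates are 1-based and inclusive on the protein sequence, matching
the UniProt site-reporting convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PrecursorRecord",
    "SampleAnnotation",
    "AnnotationSet",
    "ANNOTATION_SET_NAMES",
    "read_precursor_report",
    "write_precursor_report",
    "read_sample_annotation",
    "write_sample_annotation",
    "parse_modified_peptide",
    "strip_modifications",
    "load_annotation_sets",
    "write_annotation_set",
    "records_to_frame",
    "frame_to_records",
    "representative_accession",
]

REPORT_COLUMNS = ("sample_id", "protein_group", "modified_sequence", "charge", "intensity")
ANNOTATION_COLUMNS = (
    "sample_id",
    "bait",
    "treatment",
    "workflow",
    "replicate",
    "input_cells",
    "gradient_min",
)

#: Recognised curated gene-set names.  ``proteasome_associates`` and
#: ``mito_true_negatives`` provide the TP/TN labels for the classifier;
#: ``lid_members`` are 19S lid subunits excluded from the positive set
#: (freeze-induced disassembly prevents their direct biotinylation).
ANNOTATION_SET_NAMES = (
    "proteasome_associates",
    "lid_members",
    "PIPs",
    "UPS",
    "mito_true_negatives",
    "known_ubiquitylated",
)


@dataclass(frozen=True)
class PrecursorRecord:
    """One quantified precursor in one sample."""

    sample_id: str
    protein_group: str
    modified_sequence: str
    charge: int
    intensity: float | None  # linear scale; None = missing

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.intensity is not None and not self.intensity > 0:
            raise ValueError(
                f"intensity must be positive when present, got {self.intensity!r} "
                f"for {self.protein_group}/{self.modified_sequence}"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    """Experimental-design annotation of a single MS run."""

    sample_id: str
    bait: str  # "bait" or "control"
    treatment: str = "none"  # "MG132", "vehicle" or "none"
    workflow: str = "none"  # "manual", "automated" or "none"
    replicate: int = 1
    input_cells: int | None = None
    gradient_min: float | None = None

    def __post_init__(self) -> None:
        if self.bait not in ("bait", "control"):
            raise ValueError(f"bait must be 'bait' or 'control', got {self.bait!r}")
        if self.treatment not in ("MG132", "vehicle", "none"):
            raise ValueError(f"invalid treatment {self.treatment!r}")
        if self.workflow not in ("manual", "automated", "none"):
            raise ValueError(f"invalid workflow {self.workflow!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class AnnotationSet:
    name: str
    accessions: set[str] = field(default_factory=set)


def representative_accession(protein_group: str) -> str:
    """Leading accession (before ';') representing a protein group."""
    return protein_group.split(";")[0].strip()


# ---------------------------------------------------------------------------
# modified-peptide grammar
# ---------------------------------------------------------------------------

def parse_modified_peptide(
    modified_sequence: str, protein_start: int = 1
) -> list[tuple[str, int, str | None]]:
    """Parse a bracketed modified-peptide string into per-residue tokens.

    Parameters
    ----------
    modified_sequence
        Peptide in the ``_PEPK[Biotin_K]R_`` dialect: optional flanking
        underscores, residues ``A``–``Z``, each optionally followed by a
        bracketed modification name.
    protein_start
        1-based protein position of the first residue.

    Returns
    -------
    list of ``(residue, protein_position, modification-or-None)``.

    Raises
    ------
    ValueError
        On bracket imbalance, characters outside the grammar, or a
        ``Biotin_K`` modification attached to a non-lysine residue
        (which signals a malformed report).
    """
    if protein_start < 1:
        raise ValueError(f"protein_start must be >= 1, got {protein_start}")
    seq = modified_sequence
    if seq.startswith("_"):
        seq = seq[1:]
    if seq.endswith("_"):
        seq = seq[:-1]
    tokens: list[tuple[str, int, str | None]] = []
    i = 0
    while i < len(seq):
        residue = seq[i]
        if not ("A" <= residue <= "Z"):
            raise ValueError(
                f"unexpected character {residue!r} at offset {i} in {modified_sequence!r}"
            )
        i += 1
        mod: str | None = None
        if i < len(seq) and seq[i] == "[":
            end = seq.find("]", i)
            if end == -1:
                raise ValueError(f"unbalanced '[' in {modified_sequence!r}")
            mod = seq[i + 1 : end]
            i = end + 1
        elif i < len(seq) and seq[i] == "]":
            raise ValueError(f"unbalanced ']' in {modified_sequence!r}")
        if mod == "Biotin_K" and residue != "K":
            raise ValueError(
                f"Biotin_K on non-lysine residue {residue!r} in {modified_sequence!r}"
            )
        tokens.append((residue, protein_start + len(tokens), mod))
    return tokens


def strip_modifications(modified_sequence: str) -> str:
    """Bare residue sequence of a modified peptide (no brackets/underscores)."""
    return "".join(res for res, _, _ in parse_modified_peptide(modified_sequence))


# ---------------------------------------------------------------------------
# report / annotation IO
# ---------------------------------------------------------------------------

def _parse_intensity(value, context: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        out = float(text)
    except ValueError:
        raise ValueError(f"unparseable intensity {value!r} ({context})") from None
    return out


def _resolve_columns(header: Sequence[str], required: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in header}
    mapping = {}
    for col in required:
        if col.lower() not in lower:
            raise ValueError(f"missing required column {col!r} in header {list(header)}")
        mapping[col] = lower[col.lower()]
    return mapping


def read_sample_annotation(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, ("sample_id", "bait", "replicate"))
    annotations = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[cols["sample_id"]])
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r} in annotation")
        seen.add(sid)

        def opt(name, cast, default=None):
            lower = {c.lower(): c for c in df.columns}
            if name not in lower:
                return default
            val = row[lower[name]]
            if pd.isna(val) or str(val).strip() == "":
                return default
            return cast(val)

        annotations.append(
            SampleAnnotation(
                sample_id=sid,
                bait=str(row[cols["bait"]]),
                treatment=opt("treatment", str, "none"),
                workflow=opt("workflow", str, "none"),
                replicate=int(float(row[cols["replicate"]])),
                input_cells=opt("input_cells", lambda v: int(float(v))),
                gradient_min=opt("gradient_min", float),
            )
        )
    return annotations


def write_sample_annotation(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "sample_id": ann.sample_id,
                "bait": ann.bait,
                "treatment": ann.treatment,
                "workflow": ann.workflow,
                "replicate": ann.replicate,
                "input_cells": "" if ann.input_cells is None else ann.input_cells,
                "gradient_min": "" if ann.gradient_min is None else ann.gradient_min,
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_precursor_report(
    path: str | Path, annotation_path: str | Path
) -> tuple[list[PrecursorRecord], list[SampleAnnotation]]:
    """Read a long-format precursor report together with its sample annotation.

    Every sample in the report must be described in the annotation table;
    duplicate ``(sample, protein, modified_sequence, charge)`` rows are an
    error (the first offender is named).
    """
    annotations = read_sample_annotation(annotation_path)
    known_samples = {a.sample_id for a in annotations}

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, REPORT_COLUMNS)
    records: list[PrecursorRecord] = []
    seen: set[tuple[str, str, str, int]] = set()
    for idx, row in df.iterrows():
        sid = str(row[cols["sample_id"]])
        if sid not in known_samples:
            raise ValueError(f"sample {sid!r} in report but absent from annotation")
        charge = int(float(row[cols["charge"]]))
        key = (sid, str(row[cols["protein_group"]]), str(row[cols["modified_sequence"]]), charge)
        if key in seen:
            raise ValueError(f"duplicate precursor row (first offender: row {idx}, key {key})")
        seen.add(key)
        records.append(
            PrecursorRecord(
                sample_id=sid,
                protein_group=str(row[cols["protein_group"]]),
                modified_sequence=str(row[cols["modified_sequence"]]),
                charge=charge,
                intensity=_parse_intensity(row[cols["intensity"]], f"row {idx}"),
            )
        )
    return records, annotations


def write_precursor_report(records: Iterable[PrecursorRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "protein_group": r.protein_group,
            "modified_sequence": r.modified_sequence,
            "charge": r.charge,
            "intensity": "" if r.intensity is None else repr(r.intensity),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[PrecursorRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of precursor records (intensity NaN = missing)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "protein_group": [r.protein_group for r in records],
            "modified_sequence": [r.modified_sequence for r in records],
            "charge": [r.charge for r in records],
            "intensity": [math.nan if r.intensity is None else r.intensity for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[PrecursorRecord]:
    return [
        PrecursorRecord(
            sample_id=str(row.sample_id),
            protein_group=str(row.protein_group),
            modified_sequence=str(row.modified_sequence),
            charge=int(row.charge),
            intensity=None if pd.isna(row.intensity) else float(row.intensity),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# annotation gene sets
# ---------------------------------------------------------------------------

def _read_accession_file(path: Path) -> set[str]:
    accessions: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            accessions.add(line)
    return accessions


def write_annotation_set(accessions: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\n" for a in sorted(accessions)), encoding="utf-8")


def load_annotation_sets(
    directory: str | Path, require_classifier_sets: bool = True
) -> dict[str, AnnotationSet]:
    """Load curated gene sets from ``<directory>/<name>.txt`` files.

    Applies the 19S-lid exclusion: the returned ``proteasome_associates``
    set has ``lid_members`` removed (the pre-exclusion set is preserved
    under ``proteasome_associates_all``).  The classifier's TP and TN
    labels must be disjoint; any overlap between the post-exclusion
    positive set and ``mito_true_negatives`` is an error.
    """
    directory = Path(directory)
    sets: dict[str, AnnotationSet] = {}
    for name in ANNOTATION_SET_NAMES:
        path = directory / f"{name}.txt"
        if path.exists():
            sets[name] = AnnotationSet(name, _read_accession_file(path))

    if require_classifier_sets:
        for needed in ("proteasome_associates", "mito_true_negatives"):
            if needed not in sets:
                raise ValueError(f"required annotation set {needed!r} not found in {directory}")

    lid = sets.get("lid_members", AnnotationSet("lid_members", set())).accessions
    if "proteasome_associates" in sets:
        full = sets["proteasome_associates"].accessions
        if not lid <= full:
            raise ValueError(
                f"lid_members not a subset of proteasome_associates: {sorted(lid - full)}"
            )
        sets["proteasome_associates_all"] = AnnotationSet("proteasome_associates_all", set(full))
        sets["proteasome_associates"] = AnnotationSet("proteasome_associates", full - lid)

    if "proteasome_associates" in sets and "mito_true_negatives" in sets:
        overlap = sets["proteasome_associates"].accessions & sets["mito_true_negatives"].accessions
        if overlap:
            raise ValueError(
                f"TP/TN label sets must be disjoint; overlap: {sorted(overlap)[:5]}"
            )
    return sets
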