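"""Domain types, TSV readers/writers, and dataset validation.

All tables are exchanged as UTF-8 tab-separated files with a single header
row, ``.`` decimal separator, no quoting, and ``#`` comment lines.  The
in-memory containers are thin wrappers around :class:`pandas.DataFrame`
so every downstream stage can rely on validated, labelled matrices.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ValidationError",
    "CATEGORIES",
    "GROUPS",
    "EXPERIMENTS",
    "FRACTIONS",
    "STAGES",
    "SpectralCountTable",
    "Dataset",
    "read_tsv",
    "write_tsv",
    "load_design",
    "load_meta",
    "load_counts",
    "load_annotations",
    "load_dataset",
    "write_table",
    "load_table",
    "lengths_from_fasta",
]


class ValidationError(ValueError):
    """A malformed input table; the message names the offending field."""


# The 13 curated functional categories plus the catch-all "other":
# protein synthesis, energy metabolism, lipid metabolism, cell cycle /
# division / growth / fate, protein degradation, apoptosis, oncogene,
# endosome/lysosome, immune function, redox/detox, lectins, zona pellucida
# proteins and vitellogenins.
CATEGORIES = (
    "PS", "EM", "LM", "CC", "PD", "AP", "OG", "EL", "IF", "RD",
    "lectins", "ZPs", "Vtgs", "other",
)
GROUPS = ("good", "poor")
EXPERIMENTS = ("pooled", "multiple")
FRACTIONS = ("whole", "HMW", "LMW")
STAGES = ("raw", "apportioned", "total_normalized", "nsc")

DESIGN_COLUMNS = ("sample_id", "group", "experiment", "fraction", "replicate")
META_COLUMNS = ("protein_id", "length_aa", "unique_peptide_count", "category")
ANNOTATION_COLUMNS = ("protein_id", "term_id", "term_name")


@dataclass
class SpectralCountTable:
    """Proteins x samples matrix of spectral counts at a named stage.

    ``values`` is indexed by protein_id with one column per sample_id.
    ``stage`` records how far through the normalization pipeline the
    matrix has travelled: raw integer counts, shared-peptide apportioned,
    total-scaled, or fully length-normalized (N-SC).
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein_id {dup!r} in count table")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r} in count table")
        if (self.values.values < 0).any():
            raise ValidationError("negative entries in count table")
        if self.stage == "raw":
            vals = self.values.values
            if not (vals == vals.round()).all():
                raise ValidationError("raw counts must be integers")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "SpectralCountTable":
        return SpectralCountTable(self.values[list(sample_ids)].copy(), self.stage)


@dataclass
class Dataset:
    """Validated bundle of design, metadata, counts and annotations.

    ``peptides`` is a long-format frame (peptide_id, protein_ids,
    one column per sample) when peptide-level input was supplied;
    ``counts`` is then absent until apportionment.
    """

    design: pd.DataFrame
    meta: pd.DataFrame
    counts: SpectralCountTable | None = None
    peptides: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    @property
    def peptide_level(self) -> bool:
        return self.peptides is not None

    def samples_for(self, **query: str) -> list[str]:
        """Sample ids matching equality constraints on design columns."""
        mask = pd.Series(True, index=self.design.index)
        for col, val in query.items():
            mask &= self.design[col] == val
        return self.design.loc[mask, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# TSV dialect

def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike,
              comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what} table missing column(s) {missing}")


def _require_unique(series: pd.Series, what: str) -> None:
    dup = series[series.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what} {dup.iloc[0]!r}")


# ---------------------------------------------------------------------------
# Loaders

def load_design(path: str | os.PathLike) -> pd.DataFrame:
    design = read_tsv(path)
    _require_columns(design, DESIGN_COLUMNS, "design")
    design["sample_id"] = design["sample_id"].astype(str)
    _require_unique(design["sample_id"], "sample_id")
    for col, allowed in (("group", GROUPS), ("experiment", EXPERIMENTS),
                         ("fraction", FRACTIONS)):
        bad = set(design[col]) - set(allowed)
        if bad:
            raise ValidationError(f"design column {col!r} has unknown value(s) {sorted(bad)}")
    if (design["replicate"].astype(int) < 1).any():
        raise ValidationError("design column 'replicate' must be a positive integer")
    return design.reset_index(drop=True)


def load_meta(path: str | os.PathLike) -> pd.DataFrame:
    meta = read_tsv(path)
    _require_columns(meta, META_COLUMNS, "meta")
    meta["protein_id"] = meta["protein_id"].astype(str)
    _require_unique(meta["protein_id"], "protein_id")
    if (meta["length_aa"].astype(int) < 6).any():
        bad = meta.loc[meta["length_aa"].astype(int) < 6, "protein_id"].iloc[0]
        raise ValidationError(f"protein {bad!r} has length_aa < 6")
    if (meta["unique_peptide_count"].astype(int) < 0).any():
        raise ValidationError("unique_peptide_count must be nonnegative")
    bad_cat = set(meta["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ValidationError(f"unknown functional category label(s) {sorted(bad_cat)}")
    return meta.set_index("protein_id", drop=False)


def load_counts(path: str | os.PathLike, design: pd.DataFrame,
                meta: pd.DataFrame) -> tuple[SpectralCountTable | None, pd.DataFrame | None]:
    """Load a count TSV; returns (protein table, peptide frame).

    The first column decides the level: ``protein_id`` gives a protein
    matrix directly, ``peptide_id`` (with a ``protein_ids`` column of
    comma-joined ids) flags peptide-level input that must be apportioned.
    """
    frame = read_tsv(path)
    samples = design["sample_id"].tolist()
    if "peptide_id" in frame.columns:
        _require_columns(frame, ("peptide_id", "protein_ids", *samples), "peptide counts")
        _require_unique(frame["peptide_id"], "peptide_id")
        known = set(meta["protein_id"])
        for pids in frame["protein_ids"]:
            for pid in str(pids).split(","):
                if pid not in known:
                    raise ValidationError(f"peptide table references unknown protein {pid!r}")
        return None, frame.reset_index(drop=True)
    _require_columns(frame, ("protein_id", *samples), "counts")
    frame["protein_id"] = frame["protein_id"].astype(str)
    _require_unique(frame["protein_id"], "protein_id")
    extra = set(frame["protein_id"]) - set(meta["protein_id"])
    if extra:
        raise ValidationError(f"count table references unknown protein {sorted(extra)[0]!r}")
    matrix = frame.set_index("protein_id")[samples].astype(float)
    return SpectralCountTable(matrix, stage="raw"), None


def load_annotations(path: str | os.PathLike, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    ann = read_tsv(path)
    _require_columns(ann, ANNOTATION_COLUMNS, "annotations")
    ann["protein_id"] = ann["protein_id"].astype(str)
    if meta is not None:
        extra = set(ann["protein_id"]) - set(meta["protein_id"])
        if extra:
            raise ValidationError(
                f"annotation table references unknown protein {sorted(extra)[0]!r}")
    return ann.reset_index(drop=True)


def load_dataset(count_path: str | os.PathLike, meta_path: str | os.PathLike,
                 design_path: str | os.PathLike,
                 annotation_path: str | os.PathLike | None = None) -> Dataset:
    """Read and cross-validate a full dataset bundle from TSV files."""
    design = load_design(design_path)
    meta = load_meta(meta_path)
    counts, peptides = load_counts(count_path, design, meta)
    annotations = None
    if annotation_path is not None:
        annotations = load_annotations(annotation_path, meta)
    return Dataset(design=design, meta=meta, counts=counts,
                   peptides=peptides, annotations=annotations)


# ---------------------------------------------------------------------------
# Table round-trip

def write_table(table: SpectralCountTable, path: str | os.PathLike) -> None:
    """Write a count matrix as TSV; a comment line records the stage."""
    frame = table.values.reset_index()
    frame.columns = ["protein_id", *table.values.columns]
    write_tsv(frame, path, comments=[f"stage={table.stage}"])


def load_table(path: str | os.PathLike) -> SpectralCountTable:
    stage = "raw"
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
        if head.startswith("#") and "stage=" in head:
            stage = head.split("stage=", 1)[1].strip()
    frame = read_tsv(path)
    matrix = frame.set_index("protein_id").astype(float)
    return SpectralCountTable(matrix, stage=stage)


def lengths_from_fasta(path: str | os.PathLike) -> dict[str, int]:
    """Protein lengths (residues) from a FASTA file; trailing '*' excluded."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ValidationError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq)
        lengths[record.id] = len(seq.rstrip("*"))
    return lengths
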