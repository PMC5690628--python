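"""Three-step spectral-count normalization producing N-SC values.

Raw MS/MS spectral counts are converted to normalized spectral counts
(N-SC) in three sequential steps:

a) shared peptides are apportioned among the protein groups carrying
   them, in proportion to each group's number of unique peptides;
b) each sample's column is scaled so all samples share the same total
   spectral count (the reference total is the mean of sample totals);
c) each protein's row is divided by its length in amino-acid residues.

Steps are deliberately not commutative; the pipeline fixes the a->b->c
order.  Total scaling is computed within each (experiment, fraction)
stratum of the design so separately run gel fractions are never scaled
against one another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import Dataset, SpectralCountTable, ValidationError

__all__ = [
    "NormalizationReport",
    "apportion_shared_peptides",
    "normalize_totals",
    "normalize_length",
    "nsc_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Bookkeeping for the total-scaling step.

    ``raw_totals`` and ``scale_factors`` are per-sample; after scaling,
    every column total equals ``reference_total`` within its stratum.
    ``length_divisors`` holds the per-protein residue counts applied in
    the length step (empty until that step runs).
    """

    raw_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    scale_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    reference_total: dict[str, float] = field(default_factory=dict)
    length_divisors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def apportion_shared_peptides(peptides: pd.DataFrame, meta: pd.DataFrame,
                              sample_ids: list[str] | None = None) -> SpectralCountTable:
    """Distribute peptide spectral counts onto proteins.

    A peptide observed with count c and shared by protein groups
    {1..m} contributes c * U_i / sum_j U_j to protein i, where U_i is
    protein i's unique-peptide count.  If every sharing protein has
    U = 0 the count is split equally (logged).  Per-sample totals are
    conserved exactly.
    """
    if sample_ids is None:
        sample_ids = [c for c in peptides.columns if c not in ("peptide_id", "protein_ids")]
    proteins = list(meta["protein_id"])
    index = pd.Index(proteins, name="protein_id")
    pos = {p: i for i, p in enumerate(proteins)}
    upc = meta["unique_peptide_count"].astype(float)

    counts = peptides[sample_ids].to_numpy(float)
    acc = np.zeros((len(proteins), len(sample_ids)))
    for row_i, pids_str in enumerate(peptides["protein_ids"].astype(str)):
        pids = pids_str.split(",")
        weights = np.array([upc.get(p, 0.0) for p in pids])
        if weights.sum() == 0:
            log.warning("peptide %s shared only among zero-unique-peptide proteins %s; "
                        "splitting equally", peptides.iloc[row_i, 0], pids)
            weights = np.ones(len(pids))
        weights = weights / weights.sum()
        for pid, w in zip(pids, weights):
            acc[pos[pid]] += counts[row_i] * w
    values = pd.DataFrame(acc, index=index, columns=sample_ids)
    return SpectralCountTable(values, stage="apportioned")


def _strata(design: pd.DataFrame | None, sample_ids: pd.Index) -> list[list[str]]:
    """Sample-id groups within which totals are equalized."""
    if design is None:
        return [list(sample_ids)]
    sub = design[design["sample_id"].isin(sample_ids)]
    groups = []
    for _, block in sub.groupby(["experiment", "fraction"], sort=False):
        groups.append(block["sample_id"].tolist())
    return groups


def normalize_totals(table: SpectralCountTable, design: pd.DataFrame | None = None
                     ) -> tuple[SpectralCountTable, NormalizationReport]:
    """Scale each sample so totals are equal within each stratum.

    The reference is the arithmetic mean of the stratum's sample totals,
    which keeps the stratum grand total invariant.  Any strictly
    positive reference would give proportionally identical fold changes
    downstream.
    """
    values = table.values.copy().astype(float)
    report = NormalizationReport()
    raw_totals = values.sum(axis=0)
    zero = raw_totals[raw_totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total spectral count")
    factors = pd.Series(1.0, index=values.columns)
    reference: dict[str, float] = {}
    for samples in _strata(design, values.columns):
        ref = raw_totals[samples].mean()
        for s in samples:
            factors[s] = ref / raw_totals[s]
            reference[s] = ref
    values = values * factors
    report.raw_totals = raw_totals
    report.scale_factors = factors
    report.reference_total = reference
    return SpectralCountTable(values, stage="total_normalized"), report


def normalize_length(table: SpectralCountTable, meta: pd.DataFrame,
                     nsaf: bool = False) -> SpectralCountTable:
    """Divide each protein's row by its length in residues.

    With ``nsaf=True`` each column is additionally re-scaled to sum to 1
    (the NSAF convention); the default is plain division by size.
    """
    missing = table.values.index.difference(meta.index)
    if len(missing):
        raise ValidationError(f"no length_aa for protein {missing[0]!r}")
    lengths = meta.loc[table.values.index, "length_aa"].astype(float)
    values = table.values.div(lengths, axis=0)
    if nsaf:
        values = values / values.sum(axis=0)
    return SpectralCountTable(values, stage="nsc")


def nsc_pipeline(dataset: Dataset, nsaf: bool = False
                 ) -> tuple[SpectralCountTable, NormalizationReport]:
    """Run apportionment (if peptide-level), total scaling, then length scaling."""
    if dataset.peptide_level:
        table = apportion_shared_peptides(
            dataset.peptides, dataset.meta, dataset.design["sample_id"].tolist())
        # keep only proteins with any evidence
        table = SpectralCountTable(
            table.values[table.values.sum(axis=1) > 0], stage="apportioned")
    else:
        if dataset.counts is None:
            raise ValidationError("dataset has neither protein counts nor peptides")
        table = dataset.counts
    table, report = normalize_totals(table, dataset.design)
    table = normalize_length(table, dataset.meta, nsaf=nsaf)
    report.length_divisors = dataset.meta.loc[table.values.index, "length_aa"].astype(float)
    return table, report
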