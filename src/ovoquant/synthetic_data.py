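"""Seeded generator of synthetic egg-proteome datasets with ground truth.

The generator emulates the structure of a two-group (good vs poor egg
quality) spectral-counting experiment: 4 replicate spawns per group,
log-normal baseline protein abundances, negative-binomially
overdispersed integer counts (Poisson in the zero-dispersion limit),
a planted fraction of proteins with known fold changes, group-unique
proteins implemented as structural zeros, peptide records with a share
of two-way shared peptides, protein-length variation, planted enriched
annotation terms, and spawn-survival records with the bimodal quality
structure (good spawns above 90%, poor below 30% survival at 24 hps).
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CATEGORIES, Dataset, SpectralCountTable, ValidationError
from .phenotype import SpawnSurvivalRecord

__all__ = [
    "SimulationConfig",
    "simulate_counts_dataset",
    "simulate_survival_records",
    "evaluate_against_truth",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Defaults mirror the replicated study layout: 1000 proteins, 4 vs 4
    samples, log-normal baselines around e^3 ~ 20 spectra, mild
    negative-binomial overdispersion (phi = 0.1, variance m + phi m^2),
    20% of proteins with planted 2-8x fold changes, and a handful of
    group-unique proteins.
    """

    n_proteins: int = 1000
    n_replicates_per_group: int = 4
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1            # phi >= 0; 0 -> Poisson
    frac_de: float = 0.2
    fold_range: tuple[float, float] = (2.0, 8.0)
    n_unique_good: int = 20
    n_unique_poor: int = 30
    shared_peptide_frac: float = 0.1
    peptides_per_protein: tuple[int, int] = (2, 12)
    length_aa_range: tuple[int, int] = (100, 2000)
    category_probs: tuple[float, ...] = tuple([0.05] * 13 + [0.35])
    n_terms: int = 30
    planted_terms: tuple[tuple[str, float, float], ...] = (
        ("T_planted", 0.05, 10.0),
    )
    term_reference_frac: float = 0.08
    survival_good_mean: float = 98.0
    survival_good_sd: float = 2.0
    survival_poor_mean: float = 8.0
    survival_poor_sd: float = 6.0
    experiment: str = "multiple"
    fraction: str = "whole"
    seed: int = 0

    def validate(self) -> None:
        if self.n_unique_good + self.n_unique_poor > self.n_proteins:
            raise ValidationError("more unique proteins requested than proteins")
        if not 0 <= self.frac_de <= 1 or not 0 <= self.shared_peptide_frac <= 1:
            raise ValidationError("fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValidationError("category_probs must sum to 1")
        if len(self.category_probs) != len(CATEGORIES):
            raise ValidationError(
                f"category_probs must have {len(CATEGORIES)} entries")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 phi: float) -> np.ndarray:
    """Negative-binomial counts with variance m + phi m^2 (Poisson at phi=0)."""
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts_dataset(config: SimulationConfig
                            ) -> tuple[Dataset, pd.DataFrame]:
    """Generate a complete dataset bundle plus its truth table.

    Returns (dataset, truth) where truth is a frame indexed by
    protein_id with columns status in {null, de_good, de_poor,
    unique_good, unique_poor}, true_fold, and baseline mean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    nrep = config.n_replicates_per_group
    protein_ids = [f"P{i:04d}" for i in range(n)]

    # assign statuses
    status = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    k = 0
    for s, count in (("unique_good", config.n_unique_good),
                     ("unique_poor", config.n_unique_poor)):
        status[order[k:k + count]] = s
        k += count
    n_de = int(round(config.frac_de * n))
    n_de = min(n_de, n - k)
    de_idx = order[k:k + n_de]
    de_dir = rng.random(n_de) < 0.5
    status[de_idx] = np.where(de_dir, "de_good", "de_poor")

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    lo, hi = config.fold_range
    true_fold = np.ones(n)
    true_fold[de_idx] = rng.uniform(lo, hi, n_de)

    mean_good = baseline.copy()
    mean_poor = baseline.copy()
    mean_good[status == "de_good"] *= true_fold[status == "de_good"]
    mean_poor[status == "de_poor"] *= true_fold[status == "de_poor"]
    mean_poor[status == "unique_good"] = 0.0
    mean_good[status == "unique_poor"] = 0.0

    good_samples = [f"good_{i + 1}" for i in range(nrep)]
    poor_samples = [f"poor_{i + 1}" for i in range(nrep)]
    counts = np.column_stack(
        [_draw_counts(rng, mean_good, config.dispersion) for _ in good_samples]
        + [_draw_counts(rng, mean_poor, config.dispersion) for _ in poor_samples]
    ).astype(float)
    values = pd.DataFrame(counts, index=pd.Index(protein_ids, name="protein_id"),
                          columns=good_samples + poor_samples)

    design = pd.DataFrame({
        "sample_id": good_samples + poor_samples,
        "group": ["good"] * nrep + ["poor"] * nrep,
        "experiment": config.experiment,
        "fraction": config.fraction,
        "replicate": list(range(1, nrep + 1)) * 2,
    })

    # peptides: split each protein's counts multinomially over its peptides;
    # a share of peptides is two-way shared with a random partner protein
    plo, phi_ = config.peptides_per_protein
    n_pep = rng.integers(plo, phi_ + 1, n)
    pep_rows = []
    shared_of: list[list[int]] = [[] for _ in range(n)]
    pep_id = 0
    for i in range(n):
        share_mask = rng.random(n_pep[i]) < config.shared_peptide_frac
        weights = rng.dirichlet(np.ones(n_pep[i]))
        split = np.vstack([rng.multinomial(int(c), weights)
                           for c in values.iloc[i].astype(int)]).T  # pep x sample
        for j in range(n_pep[i]):
            partners = [protein_ids[i]]
            if share_mask[j] and n > 1:
                other = int(rng.integers(0, n - 1))
                other = other if other < i else other + 1
                partners.append(protein_ids[other])
                shared_of[i].append(j)
            pep_rows.append({
                "peptide_id": f"pep{pep_id:06d}",
                "protein_ids": ",".join(partners),
                **{s: int(c) for s, c in zip(values.columns, split[j])},
            })
            pep_id += 1
    peptides = pd.DataFrame(pep_rows)
    unique_pep_count = np.array([n_pep[i] - len(shared_of[i]) for i in range(n)])

    lengths = rng.integers(config.length_aa_range[0],
                           config.length_aa_range[1] + 1, n)
    categories = rng.choice(CATEGORIES, size=n, p=np.asarray(config.category_probs))
    meta = pd.DataFrame({
        "protein_id": protein_ids,
        "length_aa": lengths,
        "unique_peptide_count": unique_pep_count,
        "category": categories,
    }).set_index("protein_id", drop=False)

    # annotations: background terms at a fixed reference frequency; planted
    # terms over-sample differentially regulated proteins
    is_de = np.isin(status, ["de_good", "de_poor", "unique_good", "unique_poor"])
    ann_rows = []
    planted_ids = {t[0] for t in config.planted_terms}
    for t in range(config.n_terms):
        term = f"T{t:03d}"
        if term in planted_ids:
            continue
        members = rng.random(n) < config.term_reference_frac
        for pid in np.array(protein_ids)[members]:
            ann_rows.append({"protein_id": pid, "term_id": term,
                             "term_name": f"background term {t}"})
    for term_id, ref_frac, enr in config.planted_terms:
        p_member = np.where(is_de, np.minimum(1.0, ref_frac * enr), ref_frac)
        members = rng.random(n) < p_member
        for pid in np.array(protein_ids)[members]:
            ann_rows.append({"protein_id": pid, "term_id": term_id,
                             "term_name": f"planted term {term_id}"})
    annotations = pd.DataFrame(ann_rows, columns=["protein_id", "term_id", "term_name"])

    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "status": status,
        "true_fold": true_fold,
        "baseline": baseline,
    }).set_index("protein_id", drop=False)
    term_truth = pd.DataFrame({
        "term_id": sorted({r["term_id"] for r in ann_rows}),
    })
    term_truth["enriched"] = term_truth["term_id"].isin(planted_ids)
    truth.attrs["terms"] = term_truth

    dataset = Dataset(design=design, meta=meta,
                      counts=SpectralCountTable(values, stage="raw"),
                      peptides=peptides, annotations=annotations)
    return dataset, truth


def simulate_survival_records(config: SimulationConfig,
                              seed: int | None = None) -> list[SpawnSurvivalRecord]:
    """Spawn-survival records with bimodal 24-hps quality structure.

    Good spawns draw 24-hps survival above 90%, poor below 30%; survival
    is non-increasing over 8/24/48/72 hps and constant after 24 hps.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    nrep = config.n_replicates_per_group
    for label, mean, sd, lo, hi in (
            ("good", config.survival_good_mean, config.survival_good_sd, 90.001, 100.0),
            ("poor", config.survival_poor_mean, config.survival_poor_sd, 0.0, 29.999)):
        for i in range(nrep):
            s24 = float(np.clip(rng.normal(mean, sd), lo, hi))
            s8 = float(np.clip(s24 + rng.uniform(0, 0.5) * (100 - s24), s24, 100))
            records.append(SpawnSurvivalRecord(
                female_id=f"{label}_{i + 1}",
                eggs_total=int(rng.integers(100, 500)),
                eggs_incubated=60,
                pct_intact_2_3hps=100.0,
                pct_survival={8: s8, 24: s24, 48: s24, 72: s24},
                pct_abnormal={8: 0.0, 24: 0.0, 48: 0.0, 72: 0.0},
                experiment=config.experiment,
            ))
    return records


def evaluate_against_truth(records, truth: pd.DataFrame) -> dict:
    """Confusion-matrix rates of recovered regulation against the truth.

    A planted protein (de_* or unique_*) counts as recovered when its
    tier is up/highly-up/unique in the planted direction.  Returns
    sensitivity, specificity and FDR (0 when nothing is called).
    """
    by_id = {r.protein_id: r for r in records}
    unknown = set(by_id) - set(truth.index)
    if unknown:
        raise ValidationError(f"record for unknown protein {sorted(unknown)[0]!r}")
    tp = fp = fn = tn = 0
    for pid, row in truth.iterrows():
        rec = by_id.get(pid)
        called = rec is not None and rec.up_regulated
        direction = rec.direction if called else None
        if row["status"] == "null":
            fp += called
            tn += not called
        else:
            want = "good" if row["status"].endswith("good") else "poor"
            if called and direction == want:
                tp += 1
            else:
                fn += 1
    called_total = tp + fp
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "fdr": fp / called_total if called_total else 0.0,
    }
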