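import numpy as np
import pandas as pd
import pytest

from ovoquant.core_data import Dataset, SpectralCountTable


@pytest.fixture
def tiny_design() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": ["g1", "g2", "p1", "p2"],
        "group": ["good", "good", "poor", "poor"],
        "experiment": "multiple",
        "fraction": "whole",
        "replicate": [1, 2, 1, 2],
    })


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    meta = pd.DataFrame({
        "protein_id": ["P1", "P2", "P3"],
        "length_aa": [100, 200, 50],
        "unique_peptide_count": [3, 1, 2],
        "category": ["PS", "EM", "other"],
    })
    return meta.set_index("protein_id", drop=False)


@pytest.fixture
def tiny_counts(tiny_design, tiny_meta) -> SpectralCountTable:
    values = pd.DataFrame(
        [[10.0, 12.0, 2.0, 4.0],
         [20.0, 18.0, 20.0, 22.0],
         [0.0, 0.0, 5.0, 7.0]],
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
        columns=["g1", "g2", "p1", "p2"])
    return SpectralCountTable(values, stage="raw")


@pytest.fixture
def tiny_dataset(tiny_design, tiny_meta, tiny_counts) -> Dataset:
    return Dataset(design=tiny_design, meta=tiny_meta, counts=tiny_counts)


def write_bundle(tmp_path, design, meta, counts):
    """Write a dataset bundle as TSV files; returns the three paths."""
    dp = tmp_path / "design.tsv"
    mp = tmp_path / "meta.tsv"
    cp = tmp_path / "counts.tsv"
    design.to_csv(dp, sep="\t", index=False)
    meta.reset_index(drop=True).to_csv(mp, sep="\t", index=False)
    frame = counts.values.reset_index()
    frame.to_csv(cp, sep="\t", index=False)
    return cp, mp, dp
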