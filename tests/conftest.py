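"""Shared fixtures: tiny in-memory datasets and delimited-text files."""

import numpy as np
import pandas as pd
import pytest

from roikst.core_data import (MarkerAnnotation, MarkerMatrix, SampleTable)
from roikst.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default-scale simulated dataset, fixed seed."""
    return simulate_dataset(SimulationConfig(), seed=20)


@pytest.fixture(scope="session")
def small_dataset():
    """A cheaper dataset for repeated fits."""
    return simulate_dataset(SimulationConfig(n=60), seed=21)


@pytest.fixture(scope="session")
def annotation():
    """Hand-laid annotation on two chromosomes."""
    rows = [
        ("cgA", "1", 96_999, "methylation"),
        ("cgB", "1", 97_000, "methylation"),
        ("cgC", "1", 100_000, "methylation"),
        ("cgD", "1", 103_000, "methylation"),
        ("cgE", "1", 103_001, "methylation"),
        ("cgF", "2", 100_000, "methylation"),
        ("snp1", "1", 100_500, "genotype"),
        ("snp2", "1", 99_000, "genotype"),
    ]
    return MarkerAnnotation(table=pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos", "kind"]))


@pytest.fixture()
def toy_table():
    rng = np.random.default_rng(3)
    n = 12
    ids = tuple(f"S{i}" for i in range(n))
    return SampleTable(
        sample_ids=ids,
        response=rng.normal(size=n),
        covariates=pd.DataFrame({"pre_lntg": rng.normal(4.9, 0.5, n),
                                 "age": rng.uniform(30, 70, n)}),
    )


@pytest.fixture()
def toy_markers(toy_table):
    rng = np.random.default_rng(4)
    return MarkerMatrix(
        sample_ids=toy_table.sample_ids,
        marker_ids=("cgX", "cgY", "cgZ"),
        values=rng.beta(2, 2, size=(toy_table.n, 3)),
        marker_kind="methylation",
    )


@pytest.fixture()
def pheno_file(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "sample_id\tpost_lntg\tpre_lntg\tage\n"
        "A\t5.1\t4.8\t50\n"
        "B\t4.9\t4.7\t41\n"
        "C\t5.3\t5.0\t63\n"
        "D\t4.6\t4.4\t\n"        # missing age
        "E\t5.0\t4.9\t55\n"
    )
    return path
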