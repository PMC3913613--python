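import numpy as np
import pandas as pd
import pytest

from oralclust import CountTable, SimulationDesign, simulate_dataset


@pytest.fixture
def toy_shared(tmp_path):
    path = tmp_path / "toy.shared"
    path.write_text(
        "label\tGroup\tnumOtus\tOtu001\tOtu002\tOtu003\n"
        "0.03\ts1\t3\t5\t0\t1\n"
        "0.03\ts2\t3\t2\t2\t2\n")
    return str(path)


@pytest.fixture
def toy_constaxonomy(tmp_path):
    path = tmp_path / "toy.cons.taxonomy"
    path.write_text(
        "OTU\tSize\tTaxonomy\n"
        "Otu001\t10\tBacteria(100);Firmicutes(100);Bacilli(100);"
        "Lactobacillales(100);Streptococcaceae(100);Streptococcus(95);\n"
        "Otu002\t4\tBacteria(100);Firmicutes(100);Bacilli(100);"
        "Lactobacillales(100);Streptococcaceae(100);Streptococcus(90);"
        "Streptococcus_sanguinis(80);\n"
        "Otu003\t3\tBacteria(100);Bacteroidetes(100);Bacteroidia(100);"
        "Bacteroidales(100);Prevotellaceae(100);Prevotella(99);"
        "Prevotella_intermedia(97);\n")
    return str(path)


@pytest.fixture
def toy_metadata(tmp_path):
    path = tmp_path / "toy.metadata.tsv"
    path.write_text(
        "sample\tsubject\tday\n"
        "s1\tp35\t1\n"
        "s2\tp35\t3\n")
    return str(path)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 1], [2, 2, 2], [3, 3, 4], [1, 8, 1]],
        index=["aD1", "aD3", "bD1", "bD3"],
        columns=["Otu001", "Otu002", "Otu003"])
    md = pd.DataFrame({"subject": ["a", "a", "b", "b"], "day": [1, 3, 1, 3]},
                      index=counts.index)
    return CountTable(counts, md)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at the study's default design."""
    design = SimulationDesign(seed=7)
    table, tax, truth = simulate_dataset(design)
    return design, table, tax, truth
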