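import numpy as np
import pytest

import tgcn
from tgcn.synthetic import PlantedContact, PlantedDesign, StratumSpec


@pytest.fixture(scope="session")
def reference_table():
    return tgcn.load_reference_table(tgcn.bundled_reference_path())


@pytest.fixture(scope="session")
def small_design():
    """4 genes, 3 age groups, one planted contact; tiny but non-trivial."""
    return PlantedDesign(
        genes=("GA", "GB", "GC", "GD"),
        strata={
            "20-29": StratumSpec(n=25, tissues=("Cortex", "Amygdala")),
            "40-49": StratumSpec(n=25, tissues=("Cortex",)),
            "70-79": StratumSpec(n=25, tissues=("Hippocampus",)),
        },
        planted=(PlantedContact("GA", "GB", "40-49", 0.95),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    ds, truth = tgcn.generate(small_design)
    return ds, truth


@pytest.fixture()
def dataset_on_disk(tmp_path, small_design):
    ds, truth = tgcn.generate(small_design, out_dir=tmp_path)
    return {
        "expression": tmp_path / "expression.gct",
        "annotations": tmp_path / "annotations.tsv",
        "truth": tmp_path / "truth.csv",
        "dataset": ds,
    }


def random_network(rng: np.random.Generator, alpha: float = 0.05):
    """A random but valid temporal network, for serialization properties."""
    n_genes = int(rng.integers(2, 7))
    genes = tuple(f"G{chr(65 + i)}" for i in range(n_genes))
    labels = list(tgcn.AGE_GROUP_LABELS[: int(rng.integers(1, 7))])
    snapshots = []
    for label in labels:
        edges = []
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < 0.4:
                    p = float(rng.random() * alpha * 0.999)
                    r = float(rng.uniform(-1, 1))
                    edges.append(tgcn.Edge(genes[i], genes[j], p=p, r=r))
        snapshots.append(tgcn.Snapshot(tgcn.AgeGroup(label), genes, edges))
    return tgcn.make_temporal_network(genes, snapshots, alpha)
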