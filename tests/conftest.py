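import numpy as np
import pandas as pd
import pytest

from splicedegree import IsoformAbundanceMatrix
from splicedegree import simulate as sim


@pytest.fixture(scope="session")
def small_scene() -> sim.SimulatedScene:
    """A 300-gene scene in the 3+5+3 study design with type structure."""
    config = sim.SimulationConfig(n_genes=300, seed=11)
    return sim.simulate_scene(config)


@pytest.fixture(scope="session")
def small_matrix(small_scene) -> IsoformAbundanceMatrix:
    return IsoformAbundanceMatrix(small_scene.tpm, small_scene.catalog.tx2gene)


@pytest.fixture()
def tiny_matrix() -> IsoformAbundanceMatrix:
    """Two genes, two samples, hand-set TPM values."""
    tpm = pd.DataFrame(
        {
            "s1": [12.0, 0.5, 0.2, 20.0],
            "s2": [0.0, 0.0, 0.0, 1_000_000.0],
        },
        index=pd.Index(["gA.t1", "gA.t2", "gA.t3", "gB.t1"], name="transcript_id"),
    )
    tx2gene = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gA", "gB"],
            "biotype": ["protein_coding"] * 4,
        },
        index=tpm.index,
    )
    return IsoformAbundanceMatrix(tpm, tx2gene)


def random_tpm_matrix(rng: np.random.Generator, n_genes: int, n_samples: int):
    """Random abundance matrix with a spread of magnitudes and zeros."""
    n_iso = rng.integers(1, 6, size=n_genes)
    genes = np.repeat([f"g{i}" for i in range(n_genes)], n_iso)
    tx = pd.Index([f"{g}.t{j}" for j, g in enumerate(genes)], name="transcript_id")
    tpm = rng.lognormal(1.0, 2.5, size=(tx.size, n_samples))
    tpm[rng.random(tpm.shape) < 0.3] = 0.0
    frame = pd.DataFrame(tpm, index=tx,
                         columns=[f"s{k}" for k in range(n_samples)])
    tx2gene = pd.DataFrame({"gene_id": genes, "biotype": "protein_coding"},
                           index=tx)
    return IsoformAbundanceMatrix(frame, tx2gene)


@pytest.fixture()
def study_metadata() -> pd.DataFrame:
    """11 samples in the 3 liver + 5 HepG2 + 3 Huh7 design."""
    rows = (
        [("s0", "liver"), ("s1", "liver"), ("s2", "liver")]
        + [(f"s{i}", "HepG2") for i in range(3, 8)]
        + [(f"s{i}", "Huh7") for i in range(8, 11)]
    )
    return pd.DataFrame(rows, columns=["sample_id", "type"])
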