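import numpy as np
import pandas as pd
import pytest

from ragsynergy import de, simdata
from ragsynergy.data_io import CountMatrix


def make_count_matrix(counts: np.ndarray, genotypes, treatments, timepoints=None, genes=None):
    """Assemble a CountMatrix from an array and parallel metadata lists."""
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(1, n_genes + 1)]
    timepoints = timepoints or [6] * n_samples
    names = [f"s{i}" for i in range(1, n_samples + 1)]
    samples = pd.DataFrame(
        {
            "genotype": genotypes,
            "treatment": treatments,
            "timepoint": timepoints,
            "replicate": range(1, n_samples + 1),
        },
        index=pd.Index(names, name="sample"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=names),
        samples=samples,
    )


@pytest.fixture(scope="session")
def default_design():
    return simdata.DesignSpec(seed=0)


@pytest.fixture(scope="session")
def small_experiment():
    """2000-gene experiment with planted classes, fixed phi, seed 0."""
    props = {
        "null": 0.84, "shared_all": 0.04, "r1_only": 0.03, "r2_only": 0.03,
        "additive": 0.03, "synergistic": 0.03,
    }
    cfg = simdata.EffectClassConfig(
        n_genes=2000, proportions=props, dispersion_shape=None
    )
    design = simdata.DesignSpec(seed=0)
    truth, matrix = simdata.simulate(cfg, design)
    return truth, matrix


@pytest.fixture(scope="session")
def small_contrasts_6h(small_experiment):
    """Per-genotype aphid-vs-mock contrasts at 6 h on the small experiment."""
    truth, matrix = small_experiment
    filtered, norm, disp = de.timepoint_workflow(matrix, 6)
    contrasts = {
        g: de.aphid_vs_mock(filtered, norm, disp, g, 6)
        for g in ["S", "R1", "R2", "R12"]
    }
    return truth, contrasts


@pytest.fixture()
def toy_gff3(tmp_path):
    path = tmp_path / "genes.gff3"
    lines = [
        "##gff-version 3",
        "Gm07\tphytozome\tgene\t5600000\t5601000\t.\t+\t.\tID=GeneA",
        "Gm07\tphytozome\tgene\t5769789\t5800000\t.\t-\t.\tID=GeneB",
        "Gm07\tphytozome\tgene\t5100000\t5531331\t.\t+\t.\tID=GeneC",
        "Gm07\tphytozome\tgene\t6000000\t6001000\t.\t+\t.\tID=GeneD",
        "Gm13\tphytozome\tgene\t5600000\t5601000\t.\t+\t.\tID=GeneE",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
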