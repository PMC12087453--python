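import numpy as np
import pandas as pd
import pytest

from methylseed.simulate import SimulationConfig, generate_cohort, simulate_all


@pytest.fixture(scope="session")
def small_cohort():
    """Default study conditions at reduced probe count, shared across tests."""
    cfg = SimulationConfig(n_cpg=2000, n_gene=200, seed=7)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effect, no confounders, one batch: pure noise."""
    cfg = SimulationConfig(
        n_cpg=2000,
        n_gene=200,
        delta_beta=0.0,
        confounder_spec=[],
        batch_spec=(1, 0.0, 1.0),
        seed=13,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_annotation():
    """Hand-enumerable 12-probe annotation over 5 genes."""
    rows = {
        "cg01": ("1", 100, "G1", "TSS200", "Island"),
        "cg02": ("1", 200, "G1", "TSS1500", "N_Shore"),
        "cg03": ("1", 300, "G1", "Body", "OpenSea"),
        "cg04": ("1", 400, "G2", "TSS200", "Island"),
        "cg05": ("2", 100, "G2", "Body", "OpenSea"),
        "cg06": ("2", 150, "G3", "TSS1500", "S_Shore"),
        "cg07": ("2", 250, "G3", "3'UTR", "OpenSea"),
        "cg08": ("3", 50, "G4", "TSS200", "Island"),
        "cg09": ("3", 90, "G4", "TSS200", "Island"),
        "cg10": ("3", 500, "G5", "5'UTR", "N_Shelf"),
        "cg11": ("3", 700, "G5", "TSS1500", "S_Shelf"),
        "cg12": ("4", 10, "", "intergenic", "OpenSea"),
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "pos", "gene", "region", "island"]
    ).rename_axis("probe_id")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
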