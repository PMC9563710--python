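import numpy as np
import pandas as pd
import pytest

from hetmir import DEThresholds, SimParams, PlantedMode, simulate_counts
from hetmir.pipeline import de_status_table, run_de_stage

NON_CONSERVED = (
    "additive", "hp_dominant", "lp_dominant", "over_dominant", "under_dominant"
)


def tiny_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hand-built 3-miRNA, 4-sample count matrix with known CPMs."""
    counts = pd.DataFrame(
        {
            "P1_1": [100, 900, 0],
            "P1_2": [200, 800, 0],
            "P2_1": [300, 700, 0],
            "P2_2": [400, 500, 100],
        },
        index=pd.Index(["mir-a", "mir-b", "mir-c"], name="mirna_id"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["P1_1", "P1_2", "P2_1", "P2_2"],
            "genotype": ["P1", "P1", "P2", "P2"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return counts, samples


@pytest.fixture
def tiny():
    return tiny_counts()


@pytest.fixture(scope="session")
def recovery_run():
    """Synthetic study at the reference design (4 replicates, 1M-read
    libraries, dispersion 0.1, 200 miRNAs, 30 planted per non-conserved
    category at effect 8), classified end to end."""
    planted = [
        PlantedMode(f"sim-{mode}-{i + 1:02d}", mode, "both", 8.0)
        for mode in NON_CONSERVED
        for i in range(30)
    ]
    params = SimParams(
        n_replicates=4, library_size=1_000_000, dispersion=0.1,
        n_mirnas=200, seed=20240817,
    )
    counts, samples, truth = simulate_counts(params, planted)
    tables, dropped = run_de_stage(counts, samples, DEThresholds())
    status = de_status_table(tables)
    return {
        "counts": counts, "samples": samples, "truth": truth,
        "tables": tables, "status": status, "dropped": dropped,
    }


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
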