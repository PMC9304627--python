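import numpy as np
import pandas as pd
import pytest

from microconet.cohort import CohortSpec, PlantedModule, generate_cohort
from microconet.io import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """4 samples x 5 taxa with hand-chosen counts."""
    return CountTable(
        pd.DataFrame(
            [
                [9, 5, 100, 3, 0],
                [0, 5, 80, 4, 1],
                [0, 0, 120, 6, 2],
                [0, 0, 90, 2, 3],
            ],
            index=["s1", "s2", "s3", "s4"],
            columns=["t1", "t2", "t3", "t4", "t5"],
        )
    )


@pytest.fixture
def meta_paired():
    """Validated metadata: 3 controls + 3 ERA subjects with two timepoints."""
    rows = []
    for i in range(3):
        rows.append((f"c{i}", "CTRL", "T0", f"C{i}", 1.0 + i))
    for i in range(3):
        rows.append((f"e{i}t0", "ERA", "T0", f"E{i}", 4.0 + i))
        rows.append((f"e{i}t1", "ERA", "T1", f"E{i}", 2.0 + i))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "timepoint", "subject_id", "ESR"])
    return df.set_index("sample_id")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-spec synthetic cohort, shared across tests."""
    return generate_cohort(CohortSpec(), seed=20240901)


@pytest.fixture(scope="session")
def module_cohort():
    """40 control samples, one 6-species module at latent rho 0.85."""
    names = [f"OTU_{i:04d}" for i in range(60)]
    spec = CohortSpec(
        n_ctrl=40,
        n_era=2,
        n_taxa=60,
        modules=[PlantedModule(names[:6], rho=0.85)],
        variables=[],
        diversity_deficit=0.0,
    )
    return generate_cohort(spec, seed=777)


def random_count_table(rng, n_samples=6, n_taxa=8, sparse=False):
    lam = rng.uniform(0.2, 30, size=n_taxa)
    counts = rng.poisson(lam, size=(n_samples, n_taxa))
    if sparse:
        counts[rng.random(counts.shape) < 0.5] = 0
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
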