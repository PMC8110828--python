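import numpy as np
import pandas as pd
import pytest

from relicdna.io_tables import AsvCountTable, SampleMetadata
from relicdna.synthetic import GeneratorConfig, generate_dataset


def toy_metadata(n_logs: int = 3) -> SampleMetadata:
    rows = []
    for stage in ("I", "III", "V"):
        for dna in ("intra", "extra", "total"):
            for r in range(n_logs):
                rows.append(
                    {
                        "sample_id": f"{stage}_{dna}_L{r + 1}",
                        "log_id": f"L{r + 1}",
                        "stage": stage,
                        "dna_type": dna,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def random_table(meta: SampleMetadata, n_asvs: int, rng) -> AsvCountTable:
    counts = rng.poisson(1.0, size=(n_asvs, len(meta.sample_ids)))
    counts[0, :] += 1  # keep every sample's total positive
    return AsvCountTable(
        pd.DataFrame(
            counts,
            index=pd.Index([f"ASV{i:03d}" for i in range(n_asvs)], name="asv_id"),
            columns=meta.sample_ids,
        )
    )


@pytest.fixture(scope="session")
def meta27() -> SampleMetadata:
    return toy_metadata()


@pytest.fixture(scope="session")
def small_dataset():
    """One small end-to-end synthetic dataset shared across tests."""
    cfg = GeneratorConfig(n_asvs=120, seed=7)
    return generate_dataset(cfg)
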