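import numpy as np
import pandas as pd
import pytest

from gravlfq import PipelineConfig, SimConfig, generate_dataset
from gravlfq.pipeline import run_all


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_proteins=120)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full pipeline at the default study scale (1500 proteins)."""
    out = tmp_path_factory.mktemp("pipeline1500")
    cfg = PipelineConfig(seed=1, sim=SimConfig(seed=1, n_proteins=1500),
                         out_dir=str(out))
    return run_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def toy_quant_matrix(values: dict, min_peptides: int = 2):
    """Build a QuantMatrix from {protein: {(cond, sample, frac): abundance}}."""
    from gravlfq.quantification import QuantMatrix

    df = pd.DataFrame(values).T
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["condition", "sample", "fraction"])
    df.index.name = "protein_accession"
    counts = df.notna().astype(float) * 2
    counts[df.isna()] = np.nan
    return QuantMatrix(abundance=df, peptide_count=counts,
                       min_peptides=min_peptides)
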