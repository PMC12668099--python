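import numpy as np
import pandas as pd
import pytest

from cimtomics.synthetic import CohortSpec, simulate_cohort
from cimtomics.types import MethylationMatrix


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        n_per_stratum={"Chinese": 160, "Malay": 70, "Indian": 70},
        n_cpgs=60, n_genes=10, n_snps_per_region=20, n_regions=1,
        effect_table=[
            ("cg000002", "phenotype", 0.15),
            ("snp01_010", "cg000002", 0.5),
            ("cg000002", "gene0002", 0.4),
            ("snp01_010", "gene0002", 0.3),
        ],
        noise_sd=0.1, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202409)


def make_matrix(values: np.ndarray, sample_ids=None, cpg_ids=None,
                chrom="chr1", spacing=10_000) -> MethylationMatrix:
    """Small helper to wrap a raw array as a MethylationMatrix."""
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    cpg_ids = cpg_ids or [f"cg{j:03d}" for j in range(m)]
    pos = pd.DataFrame({"chrom": chrom,
                        "pos": 1_000_000 + spacing * np.arange(m)},
                       index=pd.Index(cpg_ids))
    vals = pd.DataFrame(values, index=sample_ids, columns=cpg_ids)
    return MethylationMatrix(vals, pos)
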