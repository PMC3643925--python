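import numpy as np
import pytest

from snpset import (
    ScenarioSpec,
    build_haplotype_model,
    simulate_case_control,
)


@pytest.fixture(scope="session")
def small_model():
    """10 exchangeable SNPs, MAF 0.2, pairwise R^2 0.5."""
    return build_haplotype_model([0.2] * 10, 0.5)


@pytest.fixture(scope="session")
def fixed_dataset():
    """Seeded 200 x 10 case-control dataset with a mild planted effect.

    Used by the exact oracle-equivalence tests (KPCA/PCA duality, SIR
    closed form, SPCA degenerate grid), which need one fixed dataset.
    """
    spec = ScenarioSpec(
        scenario_id="oracle",
        n_snps=10,
        mafs=(0.2,) * 10,
        r2=0.5,
        causal_indices=(0,),
        grrs=(1.4,),
        n_cases=100,
        n_controls=100,
    )
    ds = simulate_case_control(spec, np.random.default_rng(20130503))
    return ds


@pytest.fixture(scope="session")
def null_dataset():
    """Seeded null dataset (no causal SNP), 300 individuals, 8 SNPs."""
    spec = ScenarioSpec(
        scenario_id="null",
        n_snps=8,
        mafs=(0.3,) * 8,
        r2=0.2,
        n_cases=150,
        n_controls=150,
    )
    return simulate_case_control(spec, np.random.default_rng(42))
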