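import numpy as np
import pandas as pd
import pytest

from triagen import synthio


@pytest.fixture(scope="session")
def small_arch() -> synthio.GenArchitecture:
    return synthio.GenArchitecture(
        n_variants=100,
        n_blocks=5,
        block_r=0.6,
        risk_haplotype=synthio.RiskHaplotype(variants=(0, 1)),
    )


@pytest.fixture(scope="session")
def small_bundle(small_arch) -> synthio.CohortBundle:
    parch = synthio.default_protein_architecture(small_arch, n_proteins=12, seed=5)
    return synthio.simulate_cohort(small_arch, parch, 2000, 0.08, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def summary_frame(ids, betas, ses, chrom="1", pos_start=10_000, spacing=10_000):
    """Build a minimal summary-statistics frame for meta/MR/coloc tests."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    from scipy.stats import norm

    z = betas / ses
    return pd.DataFrame(
        {
            "id": list(ids),
            "chrom": chrom,
            "pos": pos_start + spacing * np.arange(len(betas)),
            "ea": "A",
            "oa": "G",
            "eaf": 0.3,
            "beta": betas,
            "se": ses,
            "z": z,
            "p": 2 * norm.sf(np.abs(z)),
        }
    )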