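import numpy as np
import pandas as pd
import pytest

from pescore import simulate
from pescore.io import GenotypeMatrix


@pytest.fixture(scope="session")
def mini_study():
    """A small single-cohort study with one planted pathway, shared across tests."""
    return simulate.simulate_study(simulate.preset("mini", seed=11))


def make_genotypes(n=50, m=20, seed=0, missing_rate=0.0, maf=(0.1, 0.5)):
    """Small random hard-call genotype matrix for unit tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, size=m)
    dosages = rng.binomial(1, p, size=(n, m)) + rng.binomial(1, p, size=(n, m))
    dosages = dosages.astype(float)
    if missing_rate:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan
    pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]
    chosen = [pairs[i] for i in rng.integers(len(pairs), size=m)]
    variants = pd.DataFrame({
        "snp_id": [f"snp{j:03d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "counted_allele": [c[0] for c in chosen],
        "other_allele": [c[1] for c in chosen],
        "impute_score": rng.uniform(0.85, 1.0, size=m),
    })
    return GenotypeMatrix(samples=[f"s{i:03d}" for i in range(n)],
                          variants=variants, dosages=dosages)
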