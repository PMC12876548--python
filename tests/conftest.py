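import numpy as np
import pytest

from nmdar_stoich import synthetic
from nmdar_stoich.containers import SubunitCopyNumbers

# Printed relative subunit copy numbers used throughout: wild-type
# GluN1:GluN2A:GluN2B = 1.00 : 0.79 : 1.02, heterozygous mutant
# 0.91 : 0.95 : 0.63 (both normalized to wild-type GluN1).
WT_CN = (1.00, 0.79, 1.02)
HET_CN = (0.91, 0.95, 0.63)

GENE_MAP = {"Grin1": "GluN1", "Grin2a": "GluN2A", "Grin2b": "GluN2B"}

# Synthetic allele pair: 4-nt insertion after position 10, with at least
# five informative positions downstream under the neighbor-exclusion rule.
WT_ALLELE = "GATTGCTGCCCTAAGCTATACTAGGCAGCTGCAGCGTCTGGTTTTACTCAGTGTGATCTT"
MUT_ALLELE = WT_ALLELE[:10] + "TTTT" + WT_ALLELE[10:]


@pytest.fixture
def wt_subunits() -> SubunitCopyNumbers:
    return SubunitCopyNumbers("WT", *WT_CN)


@pytest.fixture
def het_subunits() -> SubunitCopyNumbers:
    return SubunitCopyNumbers("HET", *HET_CN)


@pytest.fixture
def noiseless_config() -> synthetic.ProteomeSimConfig:
    return synthetic.ProteomeSimConfig(
        noise_cv=0.0, missing_rate=0.0, n_background_proteins=50, seed=11
    )


@pytest.fixture
def noiseless_proteome(noiseless_config):
    return synthetic.generate_proteome(noiseless_config)


def group_columns(config: synthetic.ProteomeSimConfig) -> tuple[list[str], list[str]]:
    g1, g2 = config.group_names
    n = config.n_per_group
    return (
        [f"{g1}_{i + 1}" for i in range(n)],
        [f"{g2}_{i + 1}" for i in range(n)],
    )


def assert_close(actual, expected, atol=1e-12, rtol=0.0):
    np.testing.assert_allclose(actual, expected, atol=atol, rtol=rtol)
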