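import numpy as np
import pandas as pd
import pytest

from hipokit.ldscore import LDPanel
from hipokit.simulate import (
    LIPID_SIGMA_G_PATTERN,
    LIPID_SIGMA_Y,
    PSYCH_SIGMA_G_PATTERN,
    PSYCH_SIGMA_Y,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def lipid_matrices():
    """Blood-lipid genetic covariance pattern and phenotypic covariance."""
    return LIPID_SIGMA_G_PATTERN.copy(), LIPID_SIGMA_Y.copy()


@pytest.fixture(scope="session")
def psych_matrices():
    return PSYCH_SIGMA_G_PATTERN.copy(), PSYCH_SIGMA_Y.copy()


def make_panel(blocks, positions=None, chrom=None, window_bp=1_000_000):
    """Hand-built LD panel for small oracle tests."""
    sizes = [len(b) for b in blocks]
    M = sum(sizes)
    if positions is None:
        positions = 10_000 * (1 + np.arange(M))
    if chrom is None:
        chrom = np.ones(M, dtype=int)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(M)],
            "chrom": np.asarray(chrom, int),
            "pos_bp": np.asarray(positions, int),
            "maf": np.full(M, 0.3),
        }
    )
    return LDPanel(snps=snps, blocks=[np.asarray(b, float) for b in blocks],
                   window_bp=window_bp)


@pytest.fixture
def three_snp_panel():
    """One 3-SNP block with r12=0.5, r13=0, r23=0.2."""
    R = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]])
    return make_panel([R])
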