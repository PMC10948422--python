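import logging

import numpy as np
import pandas as pd
import pytest

from mrcoloc import GwasRecord, HarmonizedSet

logging.getLogger("mrcoloc").setLevel(logging.ERROR)


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-8,
    n=20000,
):
    return GwasRecord(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


@pytest.fixture
def three_pair_set():
    """Unit exposure effects so Wald ratios equal the outcome betas:
    ratios (0.2, 0.3, 0.5) with outcome ses (0.1, 0.2, 0.1)."""
    return HarmonizedSet.from_arrays(
        beta_exposure=[1.0, 1.0, 1.0],
        se_exposure=[0.01, 0.01, 0.01],
        beta_outcome=[0.2, 0.3, 0.5],
        se_outcome=[0.1, 0.2, 0.1],
    )


@pytest.fixture
def sumstats_tsv(tmp_path):
    """Well-formed 3-row summary table on disk with canonical headers."""
    df = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["1", "1", "2"],
            "BP": [1000, 2000, 500],
            "A1": ["A", "C", "G"],
            "A2": ["G", "T", "A"],
            "EAF": [0.3, 0.45, 0.12],
            "BETA": [0.10, -0.05, 0.02],
            "SE": [0.02, 0.01, 0.005],
            "P": [1e-8, 5e-7, 2e-4],
            "N": [20000, 20000, 20000],
        }
    )
    path = tmp_path / "sumstats.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path, df
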