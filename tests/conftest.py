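import numpy as np
import pandas as pd
import pytest

from allelospec.io_formats import REF_CHIMP, REF_HUMAN, AllelicCountTable
from allelospec.synthetic_data import SimConfig, simulate_allelic_counts


def make_table(human, chimp, cell_types, chrom=None, reference=REF_HUMAN,
               assay="RNA", lines=None):
    """Small hand-built count table; columns are (cell_type, line) samples."""
    human = pd.DataFrame(human)
    chimp = pd.DataFrame(chimp)
    n_feat, n_samp = human.shape
    features = [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"s{j}" for j in range(n_samp)]
    human.index = chimp.index = pd.Index(features, name="feature_id")
    human.columns = chimp.columns = sample_ids
    if lines is None:
        lines = ["hybrid1"] * n_samp
    meta = pd.DataFrame({
        "cell_type": cell_types,
        "hybrid_line": lines,
        "replicate": list(range(1, n_samp + 1)),
        "assay": assay,
    }, index=pd.Index(sample_ids, name="sample_id"))
    if chrom is None:
        chrom = ["chr1"] * n_feat
    return AllelicCountTable(
        human=human, chimp=chimp, meta=meta,
        chrom=pd.Series(chrom, index=human.index), reference=reference,
    )


@pytest.fixture(scope="session")
def mixed_sim():
    """Small mixture simulation shared across tests (default class mix)."""
    cfg = SimConfig(n_genes=600, n_peaks=600, depth_per_sample=2e5, seed=11)
    rna = simulate_allelic_counts(cfg, assay="RNA")
    atac = simulate_allelic_counts(cfg, assay="ATAC")
    return {"config": cfg, "rna": rna, "atac": atac}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
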