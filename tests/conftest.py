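import pandas as pd
import pytest

from alttss.config import SimConfig
from alttss.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated experiment shared across tests."""
    cfg = SimConfig(n_genes=30, n_cells=80, seed=11, n_usage_shift_genes=1)
    annotation, truth, reads = simulate_dataset(cfg)
    return cfg, annotation, truth, reads


@pytest.fixture()
def toy_tss():
    """Three disjoint curated-style TSS windows on one plus-strand gene."""
    df = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB"],
            "tss_id": ["gA:T0", "gA:T1", "gB:T0"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [100, 700, 5000],
            "end": [200, 800, 5100],
            "strand": ["+", "+", "-"],
        }
    )
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def make_molecules(rows):
    """Molecule table from (cell, chrom, strand, pos5) tuples."""
    return pd.DataFrame(
        [
            {
                "cell_id": c,
                "chrom": ch,
                "strand": s,
                "pos5": p,
                "umi": "AAAAAA",
                "n_reads": 2,
            }
            for c, ch, s, p in rows
        ],
        columns=["cell_id", "chrom", "strand", "pos5", "umi", "n_reads"],
    )
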