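"""Shared configuration of the synthetic alternative-TSS study.

One simulated experiment — 100 genes, 250 cells in two cell types, two
engineered usage-switch genes and a sprinkle of bimodal-ratio genes — is
analysed start to finish by the numbered scripts. Raw simulated data and
stage outputs live under scratch/ (regenerated on demand); the small
summary tables the scripts report land in results/.
"""
from pathlib import Path

from alttss.config import PipelineConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"
RUN_DIR = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"
SEED = 1729

SIM_CONFIG = SimConfig(
    n_genes=100,
    n_cells=250,
    n_usage_shift_genes=2,
    mode_probs={"shared": 0.85, "independent": 0.08,
                "exclusive": 0.02, "bimodal_ratio": 0.05},
    seed=SEED,
)


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        annotation=str(SIM_DIR / "tss.bed"),
        gene_models=str(SIM_DIR / "genes.bed12"),
        reads=str(SIM_DIR / "reads.tsv"),
        spikeins=str(SIM_DIR / "spikeins.tsv"),
        cell_labels=str(SIM_DIR / "cells.tsv"),
        rpk_cell_gate=150,  # scaled to the synthetic depth (~350 TSS molecules/cell)
        seed=SEED,
    )


def publish(workdir_file: str, as_name: str | None = None) -> Path:
    """Copy a small stage table from the run directory into results/."""
    import shutil

    RESULTS.mkdir(parents=True, exist_ok=True)
    src = RUN_DIR / workdir_file
    dst = RESULTS / (as_name or workdir_file)
    shutil.copyfile(src, dst)
    return dst
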