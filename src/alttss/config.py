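"""Configuration objects for the simulator and the analysis pipeline.

Both configs serialize to a flat ``key = value`` text file (one field per
line, values JSON-encoded) and round-trip unchanged, so a run is fully
described by one small file plus a seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

COACTIVATION_MODES = ("shared", "independent", "exclusive", "bimodal_ratio")


def _dump_flat(obj: Any, path: str | Path) -> None:
    lines = []
    for f in fields(obj):
        value = getattr(obj, f.name)
        if isinstance(value, tuple):
            value = list(value)
        lines.append(f"{f.name} = {json.dumps(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _load_flat(cls, path: str | Path):
    raw: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        raw[key.strip()] = json.loads(value.strip())
    known = {f.name: f for f in fields(cls)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        f = known[name]
        if isinstance(value, list) and f.type in ("tuple", tuple) or isinstance(
            getattr(cls(), name, None), tuple
        ):
            value = tuple(value)
        if isinstance(value, dict):
            # JSON forces string keys; restore int keys where the default uses them
            default = getattr(cls(), name, None)
            if isinstance(default, dict) and default and all(
                isinstance(k, int) for k in default
            ):
                value = {int(k): v for k, v in value.items()}
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class SimConfig:
    """Parameters of the synthetic 5'-tag single-cell experiment.

    Rates are expressed per mean mRNA lifetime (``degradation_rate`` sets the
    time unit), so ``burst_on_rate / degradation_rate`` and
    ``burst_off_rate / degradation_rate`` are the shape parameters of the
    steady-state Beta promoter-occupancy distribution of the two-state
    telegraph model, and ``transcription_rate / degradation_rate`` is the
    mean number of transcripts a continuously active TSS maintains.
    """

    n_genes: int = 100
    n_cells: int = 200
    #: fraction of cells per cell-type label; fractions sum to 1
    cell_types: dict = field(default_factory=lambda: {"typeA": 0.5, "typeB": 0.5})
    #: distribution of the number of TSSs per gene over {1, 2, 3}
    tss_per_gene: dict = field(default_factory=lambda: {1: 0.35, 2: 0.55, 3: 0.10})
    #: probability that a consecutive TSS pair is placed >= 1 kb apart
    prob_promoter_pair: float = 0.10
    proximal_distance: tuple = (50, 900)       # edge-to-edge bp, < 1 kb class
    promoter_distance: tuple = (1000, 4000)    # edge-to-edge bp, >= 1 kb class
    #: per-gene co-activation mode probabilities
    mode_probs: dict = field(
        default_factory=lambda: {
            "shared": 0.90,
            "independent": 0.08,
            "exclusive": 0.0,
            "bimodal_ratio": 0.02,
        }
    )
    burst_on_rate: float = 1.0
    burst_off_rate: float = 1.0
    transcription_rate: float = 40.0
    degradation_rate: float = 1.0
    #: concentration of the activity split between exclusive TSSs; small values
    #: mean slow switching (cells caught using one TSS), large values mean fast
    #: switching (time-averaged, both TSSs share each cell)
    exclusive_mixing: float = 0.5
    #: major-fraction components of the two-group bimodal_ratio mixture
    bimodal_fractions: tuple = (0.9, 0.5)
    bimodal_weight: float = 0.5
    capture_efficiency: float = 0.2
    #: sigma of the mean-one lognormal per-cell size factor; 0 disables
    cell_size_sigma: float = 0.4
    #: SD (bp) of gaussian jitter of each molecule's 5' position around its TSS
    scatter_sd: float = 10.0
    #: expected degradation-background molecules per gene-kb per cell
    background_rate: float = 0.5
    tss_width: int = 60
    gene_length: int = 10_000
    n_spikeins: int = 20
    #: mean detected spike-in molecules per cell (not scaled by cell size)
    spikein_mean: float = 2.0
    #: fraction of spike-in molecules whose 5' end maps exactly at the start
    spikein_exact_frac: float = 0.75
    umi_length: int = 6
    #: reads per molecule: an int for a constant, or {reads: probability}
    duplication: Any = field(default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2})
    #: assign UMIs so no two molecules at one position collide (for audits)
    collision_free_umis: bool = False
    #: number of 2-TSS shared genes given a cell-type-dependent minor fraction
    n_usage_shift_genes: int = 0
    usage_shift_delta: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        # 1.0 permitted as the lossless edge case used in audits
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must lie in (0, 1]")
        for name in ("burst_on_rate", "burst_off_rate", "transcription_rate",
                     "degradation_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if abs(sum(self.cell_types.values()) - 1.0) > 1e-9:
            raise ValueError("cell_types fractions must sum to 1")
        if abs(sum(self.tss_per_gene.values()) - 1.0) > 1e-9:
            raise ValueError("tss_per_gene probabilities must sum to 1")
        if set(self.tss_per_gene) - {1, 2, 3}:
            raise ValueError("tss_per_gene supports 1-3 TSSs per gene")
        if abs(sum(self.mode_probs.values()) - 1.0) > 1e-9:
            raise ValueError("mode_probs must sum to 1")
        if set(self.mode_probs) - set(COACTIVATION_MODES):
            raise ValueError(f"modes must be among {COACTIVATION_MODES}")
        if isinstance(self.duplication, dict):
            if abs(sum(self.duplication.values()) - 1.0) > 1e-9:
                raise ValueError("duplication probabilities must sum to 1")
            if min(self.duplication) < 1:
                raise ValueError("duplication must be >= 1 read per molecule")
        elif int(self.duplication) < 1:
            raise ValueError("duplication must be >= 1 read per molecule")
        if self.scatter_sd < 0 or self.background_rate < 0:
            raise ValueError("scatter_sd and background_rate must be >= 0")
        if self.tss_width < 1:
            raise ValueError("tss_width must be >= 1")
        # geometry feasibility: the widest TSS layout must fit in the gene span
        max_n = max(k for k, p in self.tss_per_gene.items() if p > 0)
        worst = max_n * self.tss_width + (max_n - 1) * max(
            self.promoter_distance[1]
            if self.prob_promoter_pair > 0
            else self.proximal_distance[1],
            self.proximal_distance[1],
        )
        if worst > self.gene_length:
            raise ValueError(
                "infeasible geometry: TSS windows and inter-TSS distances "
                f"cannot fit in gene_length={self.gene_length}"
            )

    def to_file(self, path: str | Path) -> None:
        _dump_flat(self, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        cfg = _load_flat(cls, path)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full analysis run.

    Every numeric threshold of the analysis is exposed here; the defaults are
    the values the method is defined with (20% reference filter, 1 kb
    promoter distance, 100-molecule and 0.3 / 0.5 molecules-per-cell
    expression gates, 2,000-molecule cell gate for rpk, binomial alpha 0.05,
    >5-molecule / 2:1 bimodal split, 20% expressed-cell and 0.3
    minor-fraction-difference rules, 0.5-mean / 2-fold DE gates).
    """

    annotation: str = "tss.bed"
    gene_models: str = "genes.bed12"
    reads: str = "reads.tsv"
    spikeins: str = "spikeins.tsv"
    cell_labels: str = "cells.tsv"
    ref_filter_threshold: float = 0.20
    promoter_distance_bp: int = 1000
    min_tss_total: int = 100
    min_pair_per_cell: float = 0.3
    min_pair_per_cell_de: float = 0.5
    rpk_cell_gate: int = 2000
    binomial_alpha: float = 0.05
    bimodal_min_total: int = 5
    bimodal_ratio: float = 2.0
    usage_min_expressed_frac: float = 0.20
    usage_min_delta: float = 0.3
    de_min_mean: float = 0.5
    de_fold_change: float = 2.0
    de_alpha: float = 0.05
    group_test: str = "t"          # "t" or "mannwhitney" for pair-group compares
    analysis_cell_type: str = "typeA"
    compare_cell_types: tuple = ("typeA", "typeB")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ref_filter_threshold <= 1.0:
            raise ValueError("ref_filter_threshold must lie in [0, 1]")
        if self.group_test not in ("t", "mannwhitney"):
            raise ValueError("group_test must be 't' or 'mannwhitney'")
        if len(self.compare_cell_types) != 2:
            raise ValueError("compare_cell_types must name exactly two types")

    def to_file(self, path: str | Path) -> None:
        _dump_flat(self, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cfg = _load_flat(cls, path)
        cfg.validate()
        return cfg

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
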