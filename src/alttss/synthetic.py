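"""Synthetic 5'-tag single-cell data with known ground truth.

The generator emulates an STRT-like experiment: genes carry one to three
CAGE-style TSS windows; per cell, each TSS's mRNA count is drawn from the
steady state of a two-state (telegraph) promoter, with the TSSs of a gene
coupled according to a per-gene co-activation mode:

* ``shared`` — both TSSs see one common on/off promoter state, so their
  counts fluctuate together (beyond what cell size alone induces);
* ``independent`` — each TSS has its own telegraph state;
* ``exclusive`` — a common activity budget is split between the TSSs, with
  slow switching concentrating each cell on one TSS (anti-correlation);
* ``bimodal_ratio`` — cells fall into two groups with different major:minor
  proportions (a Cst3-like fixed-ratio violation).

Counts are scaled by a per-cell size factor, thinned binomially at the
capture efficiency (default 0.2 — detected molecules are a ~20% sample of
the transcriptome), and emitted as 5'-tag reads: TSS-anchored positions with
gaussian scatter, a uniform degradation background along gene bodies,
spike-ins with known lengths, per-molecule UMIs and >= 1 reads per molecule.

Steady-state draws use the Beta-Poisson representation of the telegraph
model: promoter occupancy B ~ Beta(k_on/delta, k_off/delta) and
count | B ~ Poisson((k_tx/delta) * B).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

_BASES = np.array(list("ACGT"))


@dataclass
class Annotation:
    """Genomic layout of a simulated experiment."""

    tss: pd.DataFrame       # gene_id, tss_id, chrom, start, end, strand
    genes: pd.DataFrame     # gene_id, chrom, start, end, strand, exon_starts, exon_sizes
    spikeins: pd.DataFrame  # spike_id, length, chrom, start


@dataclass
class GroundTruth:
    """True per-cell molecule counts and per-gene regime labels."""

    cells: pd.DataFrame          # cell_id, cell_type, size_factor
    expressed: pd.DataFrame      # cells x tss_id, pre-capture counts
    captured: pd.DataFrame       # cells x tss_id, post-capture counts
    background: pd.DataFrame     # cells x gene_id, captured background molecules
    spike_counts: pd.DataFrame   # cells x spike_id
    gene_modes: pd.DataFrame     # gene_id, mode, n_tss, major_tss, minor_tss, usage_shift
    bimodal_group: pd.DataFrame  # cells x gene_id (bimodal genes only), 0/1 labels


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent child streams so each stage is deterministic on its own
    return np.random.default_rng([config.seed, stream])


def generate_annotation(config: SimConfig) -> Annotation:
    """Place genes, TSS windows, exon models and spike-in references.

    Genes alternate strands along two chromosomes. Each gene's first TSS sits
    at its 5' end and subsequent TSSs follow at edge-to-edge distances drawn
    from a proximal (<1 kb) / promoter-scale (>=1 kb) mixture, so windows are
    non-overlapping by construction (minimum gap well above 1 bp).
    """
    config.validate()
    rng = _rng(config, 0)
    w = config.tss_width
    glen = config.gene_length
    gap = 20_000  # intergenic spacing; keeps reference regions off neighbours

    tss_rows, gene_rows = [], []
    cursor = {"chr1": 10_000, "chr2": 10_000}
    ks = sorted(config.tss_per_gene)
    probs = [config.tss_per_gene[k] for k in ks]
    for i in range(config.n_genes):
        gene_id = f"G{i:04d}"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        strand = "+" if (i // 2) % 2 == 0 else "-"
        gstart = cursor[chrom]
        gend = gstart + glen
        cursor[chrom] = gend + gap

        n_tss = int(rng.choice(ks, p=probs))
        dists = []
        for _ in range(n_tss - 1):
            lo, hi = (
                config.promoter_distance
                if rng.random() < config.prob_promoter_pair
                else config.proximal_distance
            )
            dists.append(int(rng.integers(lo, hi + 1)))
        if n_tss * w + sum(dists) > glen:
            raise ValueError(
                f"infeasible geometry for {gene_id}: TSS layout exceeds gene span"
            )
        # windows ordered 5' -> 3' in transcription direction
        offsets = [0]
        for d in dists:
            offsets.append(offsets[-1] + w + d)
        for j, off in enumerate(offsets):
            if strand == "+":
                start = gstart + off
            else:
                start = gend - off - w
            tss_rows.append(
                {
                    "gene_id": gene_id,
                    "tss_id": f"{gene_id}:T{j}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + w,
                    "strand": strand,
                }
            )
        # three exons: 5' 20%, middle 10%, 3' 20% of the span (in genomic coords)
        exon_starts = [0, int(0.4 * glen), int(0.8 * glen)]
        exon_sizes = [int(0.2 * glen), int(0.1 * glen), glen - int(0.8 * glen)]
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": gstart,
                "end": gend,
                "strand": strand,
                "exon_starts": ",".join(str(s) for s in exon_starts),
                "exon_sizes": ",".join(str(s) for s in exon_sizes),
            }
        )

    spike_rows = []
    pos = 1000
    for s in range(config.n_spikeins):
        length = int(rng.integers(250, 2001))  # ERCC-style 250-2,000 bp
        spike_rows.append(
            {"spike_id": f"SPIKE{s:03d}", "length": length, "chrom": "ercc", "start": pos}
        )
        pos += length + 1000

    tss = pd.DataFrame(
        tss_rows, columns=["gene_id", "tss_id", "chrom", "start", "end", "strand"]
    )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_sizes"],
    )
    spikes = pd.DataFrame(spike_rows, columns=["spike_id", "length", "chrom", "start"])
    return Annotation(tss=tss, genes=genes, spikeins=spikes)


def _cell_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cells
    types = []
    names = list(config.cell_types)
    counts = [int(round(config.cell_types[t] * n)) for t in names]
    counts[-1] = n - sum(counts[:-1])
    for t, c in zip(names, counts):
        types.extend([t] * c)
    if config.cell_size_sigma > 0:
        sizes = rng.lognormal(
            mean=-0.5 * config.cell_size_sigma**2, sigma=config.cell_size_sigma, size=n
        )
    else:
        sizes = np.ones(n)
    return pd.DataFrame(
        {
            "cell_id": [f"C{i:04d}" for i in range(n)],
            "cell_type": types,
            "size_factor": sizes,
        }
    )


def simulate_cells(annotation: Annotation, config: SimConfig) -> GroundTruth:
    """Draw true and captured molecule counts per cell and TSS.

    Each gene gets TSS activity weights from a Dirichlet draw (sorted so the
    ground-truth major TSS is well defined), a co-activation mode, and
    per-cell steady-state telegraph counts coupled according to that mode.
    Captured counts are a binomial thinning at ``capture_efficiency``.
    """
    config.validate()
    rng = _rng(config, 1)
    cells = _cell_table(config, rng)
    n_cells = len(cells)
    sizes = cells["size_factor"].to_numpy()
    type_b_mask = (
        cells["cell_type"] == list(config.cell_types)[-1]
    ).to_numpy() if len(config.cell_types) > 1 else np.zeros(n_cells, bool)

    a = config.burst_on_rate / config.degradation_rate
    b = config.burst_off_rate / config.degradation_rate
    lam = config.transcription_rate / config.degradation_rate

    tss_by_gene = {g: df for g, df in annotation.tss.groupby("gene_id", sort=False)}
    mode_names = list(config.mode_probs)
    mode_p = np.array([config.mode_probs[m] for m in mode_names])

    expressed_cols: dict[str, np.ndarray] = {}
    mode_rows = []
    bimodal_cols: dict[str, np.ndarray] = {}
    shift_budget = config.n_usage_shift_genes

    for gene_id, gtss in tss_by_gene.items():
        gtss = gtss.sort_values("tss_id")  # T0 (5'-most) first
        n_tss = len(gtss)
        ids = gtss["tss_id"].tolist()
        mode = str(rng.choice(mode_names, p=mode_p))
        if n_tss == 1:
            mode = "independent"  # coupling is undefined for a single TSS
        if mode in ("exclusive", "bimodal_ratio") and n_tss != 2:
            mode = "shared"  # these regimes are defined for TSS pairs

        # activity weights; sorted descending so T0 is the true major TSS
        weights = np.sort(rng.dirichlet(np.full(n_tss, 1.5)))[::-1]
        usage_shift = False
        if (
            shift_budget > 0
            and mode == "shared"
            and n_tss == 2
            and type_b_mask.any()
        ):
            usage_shift = True
            shift_budget -= 1

        B = None
        counts = np.zeros((n_tss, n_cells), dtype=np.int64)
        if mode == "bimodal_ratio":
            group = (rng.random(n_cells) < config.bimodal_weight).astype(np.int64)
            p_major = np.where(
                group == 0, config.bimodal_fractions[0], config.bimodal_fractions[1]
            )
            B = rng.beta(a, b, size=n_cells)
            total = rng.poisson(lam * n_tss * B * sizes)
            counts[0] = rng.binomial(total, p_major)
            counts[1] = total - counts[0]
            bimodal_cols[gene_id] = group
        elif mode == "exclusive":
            B = rng.beta(a, b, size=n_cells)
            m = config.exclusive_mixing
            u = rng.beta(m * weights[0], m * weights[1], size=n_cells)
            shares = np.vstack([u, 1.0 - u])
            for t in range(n_tss):
                counts[t] = rng.poisson(lam * n_tss * B * shares[t] * sizes)
        else:
            if mode == "shared":
                B = rng.beta(a, b, size=n_cells)
            for t in range(n_tss):
                Bt = B if mode == "shared" else rng.beta(a, b, size=n_cells)
                w_t = np.full(n_cells, weights[t])
                if usage_shift and t == 1:
                    w_t = np.where(
                        type_b_mask,
                        np.minimum(weights[1] + config.usage_shift_delta, 0.95),
                        weights[1],
                    )
                if usage_shift and t == 0:
                    w_t = np.where(
                        type_b_mask,
                        np.maximum(weights[0] - config.usage_shift_delta, 0.05),
                        weights[0],
                    )
                counts[t] = rng.poisson(lam * n_tss * w_t * Bt * sizes)

        for t, tid in enumerate(ids):
            expressed_cols[tid] = counts[t]
        totals = counts.sum(axis=1)
        order = np.argsort(-totals, kind="stable")
        mode_rows.append(
            {
                "gene_id": gene_id,
                "mode": mode,
                "n_tss": n_tss,
                "major_tss": ids[order[0]],
                "minor_tss": ids[order[1]] if n_tss > 1 else "",
                "usage_shift": usage_shift,
            }
        )

    cell_index = pd.Index(cells["cell_id"], name="cell_id")
    expressed = pd.DataFrame(expressed_cols, index=cell_index)
    captured = pd.DataFrame(
        rng.binomial(expressed.to_numpy(), config.capture_efficiency),
        index=cell_index,
        columns=expressed.columns,
    )

    glen_kb = config.gene_length / 1000.0
    bg_mu = config.background_rate * glen_kb * sizes[:, None]
    background = pd.DataFrame(
        rng.poisson(np.broadcast_to(bg_mu, (n_cells, len(tss_by_gene)))),
        index=cell_index,
        columns=list(tss_by_gene),
    )

    spikes = annotation.spikeins
    spike_counts = pd.DataFrame(
        rng.poisson(config.spikein_mean, size=(n_cells, len(spikes))),
        index=cell_index,
        columns=spikes["spike_id"].tolist(),
    )

    return GroundTruth(
        cells=cells,
        expressed=expressed,
        captured=captured,
        background=background,
        spike_counts=spike_counts,
        gene_modes=pd.DataFrame(mode_rows),
        bimodal_group=pd.DataFrame(bimodal_cols, index=cell_index),
    )


def _encode_umis(codes: np.ndarray, length: int) -> np.ndarray:
    """Base-4 encode integers as A/C/G/T strings of fixed length."""
    digits = np.empty((len(codes), length), dtype=np.int64)
    rem = codes.copy()
    for j in range(length - 1, -1, -1):
        digits[:, j] = rem % 4
        rem //= 4
    chars = _BASES[digits]
    return np.array(["".join(row) for row in chars], dtype=object)


def emit_tags(truth: GroundTruth, annotation: Annotation, config: SimConfig) -> pd.DataFrame:
    """Expand captured molecules into a shuffled 5'-tag read table.

    One output row per read, columns ``cell, chrom, pos0, strand, umi``.
    TSS molecules anchor at the TSS window centre with gaussian scatter; for
    minus-strand genes the 5' position is the rightmost transcribed base, so
    anchoring and jitter are symmetric in genomic coordinates. Background
    molecules are uniform over the gene span; spike-in molecules map exactly
    at the spike 5' start with probability ``spikein_exact_frac`` and
    uniformly along the transcript otherwise. Every molecule receives a UMI
    (uniform over 4^umi_length unless ``collision_free_umis``) and >= 1 reads.
    """
    rng = _rng(config, 2)
    tss = annotation.tss.set_index("tss_id")
    cells = truth.cells["cell_id"].to_numpy()

    cell_col, chrom_col, pos_col, strand_col = [], [], [], []

    def _append(cell_ids, chroms, positions, strands):
        cell_col.append(cell_ids)
        chrom_col.append(chroms)
        pos_col.append(positions)
        strand_col.append(strands)

    # --- TSS-anchored molecules
    cap = truth.captured
    if cap.size:
        mat = cap.to_numpy()
        cell_idx, tss_idx = np.nonzero(mat)
        reps = mat[cell_idx, tss_idx]
        cell_ids = np.repeat(cells[cell_idx], reps)
        tss_per_mol = np.repeat(cap.columns.to_numpy()[tss_idx], reps)
        meta = tss.loc[tss_per_mol]
        centers = ((meta["start"] + meta["end"]) // 2).to_numpy()
        if config.scatter_sd > 0:
            jitter = np.rint(rng.normal(0.0, config.scatter_sd, len(centers))).astype(int)
        else:
            jitter = np.zeros(len(centers), dtype=int)
        _append(
            cell_ids,
            meta["chrom"].to_numpy(),
            np.maximum(centers + jitter, 0),
            meta["strand"].to_numpy(),
        )

    # --- uniform gene-body background
    bg = truth.background
    if bg.size and bg.to_numpy().sum() > 0:
        gmeta = annotation.genes.set_index("gene_id")
        mat = bg.to_numpy()
        cell_idx, gene_idx = np.nonzero(mat)
        reps = mat[cell_idx, gene_idx]
        cell_ids = np.repeat(cells[cell_idx], reps)
        genes_per_mol = np.repeat(bg.columns.to_numpy()[gene_idx], reps)
        meta = gmeta.loc[genes_per_mol]
        starts = meta["start"].to_numpy()
        ends = meta["end"].to_numpy()
        positions = rng.integers(starts, ends)
        _append(cell_ids, meta["chrom"].to_numpy(), positions, meta["strand"].to_numpy())

    # --- spike-ins
    sp = truth.spike_counts
    if sp.size and sp.to_numpy().sum() > 0:
        smeta = annotation.spikeins.set_index("spike_id")
        mat = sp.to_numpy()
        cell_idx, sp_idx = np.nonzero(mat)
        reps = mat[cell_idx, sp_idx]
        cell_ids = np.repeat(cells[cell_idx], reps)
        spikes_per_mol = np.repeat(sp.columns.to_numpy()[sp_idx], reps)
        meta = smeta.loc[spikes_per_mol]
        starts = meta["start"].to_numpy()
        lengths = meta["length"].to_numpy()
        exact = rng.random(len(starts)) < config.spikein_exact_frac
        scattered = starts + 1 + (rng.random(len(starts)) * (lengths - 1)).astype(int)
        positions = np.where(exact, starts, scattered)
        _append(
            cell_ids,
            meta["chrom"].to_numpy(),
            positions,
            np.full(len(starts), "+", dtype=object),
        )

    if not cell_col:
        return pd.DataFrame(columns=["cell", "chrom", "pos0", "strand", "umi"])

    mol = pd.DataFrame(
        {
            "cell": np.concatenate(cell_col),
            "chrom": np.concatenate(chrom_col),
            "pos0": np.concatenate(pos_col).astype(np.int64),
            "strand": np.concatenate(strand_col),
        }
    )

    n_mol = len(mol)
    space = 4 ** config.umi_length
    if config.collision_free_umis:
        # sequential codes within each (cell, chrom, strand, pos0) group
        codes = mol.groupby(["cell", "chrom", "strand", "pos0"]).cumcount().to_numpy()
        if codes.max(initial=0) >= space:
            raise ValueError("UMI space too small for collision-free assignment")
    else:
        codes = rng.integers(0, space, size=n_mol)
    mol["umi"] = _encode_umis(codes.astype(np.int64), config.umi_length)

    if isinstance(config.duplication, dict):
        ks = np.array(sorted(config.duplication))
        ps = np.array([config.duplication[k] for k in ks], dtype=float)
        dup = rng.choice(ks, size=n_mol, p=ps / ps.sum())
    else:
        dup = np.full(n_mol, int(config.duplication))

    reads = mol.loc[mol.index.repeat(dup)].reset_index(drop=True)
    reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    return reads[["cell", "chrom", "pos0", "strand", "umi"]]


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: annotation, ground truth and read table."""
    annotation = generate_annotation(config)
    truth = simulate_cells(annotation, config)
    reads = emit_tags(truth, annotation, config)
    return annotation, truth, reads


def truth_count_matrix(truth: GroundTruth, annotation: Annotation):
    """Ground-truth captured counts as a :class:`TssCountMatrix`.

    Bypasses tag emission and UMI collapse: the matrix a perfect quantifier
    would recover. Used for statistical-recovery checks at scales where
    emitting reads is unnecessary.
    """
    from .quantify import TssCountMatrix

    cell_types = truth.cells.set_index("cell_id")["cell_type"]
    tss = annotation.tss.copy()
    tss["center"] = (tss["start"] + tss["end"]) // 2
    counts = truth.captured.reindex(columns=tss["tss_id"], fill_value=0)
    return TssCountMatrix(counts=counts, cell_types=cell_types, tss=tss)


def write_dataset(
    annotation: Annotation,
    truth: GroundTruth,
    reads: pd.DataFrame,
    config: SimConfig,
    outdir,
) -> dict:
    """Write a simulated experiment to disk in the pipeline's input formats.

    Returns the file-path map. Ground-truth tables go under ``truth_*`` and
    are never read by the pipeline itself.
    """
    from pathlib import Path

    from .io import write_gene_bed12, write_tss_bed, write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "tss.bed",
        "gene_models": outdir / "genes.bed12",
        "reads": outdir / "reads.tsv",
        "spikeins": outdir / "spikeins.tsv",
        "cell_labels": outdir / "cells.tsv",
        "config": outdir / "sim_config.txt",
    }
    write_tss_bed(annotation.tss, paths["annotation"])
    write_gene_bed12(annotation.genes, paths["gene_models"])
    write_tsv(reads, paths["reads"])
    write_tsv(annotation.spikeins, paths["spikeins"])
    write_tsv(truth.cells[["cell_id", "cell_type"]], paths["cell_labels"])
    config.to_file(paths["config"])
    write_tsv(truth.cells, outdir / "truth_cells.tsv")
    write_tsv(truth.expressed.reset_index(), outdir / "truth_expressed.tsv")
    write_tsv(truth.captured.reset_index(), outdir / "truth_captured.tsv")
    write_tsv(truth.background.reset_index(), outdir / "truth_background.tsv")
    write_tsv(truth.gene_modes, outdir / "truth_gene_modes.tsv")
    if len(truth.bimodal_group.columns):
        write_tsv(truth.bimodal_group.reset_index(), outdir / "truth_bimodal_group.tsv")
    return {k: str(v) for k, v in paths.items()}
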