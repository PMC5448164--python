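"""End-to-end orchestration: quantify -> filter -> coexpress -> usage tests
-> report.

Each stage reads its inputs from the run directory (prior stages' TSVs plus
the paths named in the config), writes its own TSV/JSON outputs there, and
records record counts in a shared manifest. ``run_pipeline`` composes the
stages; the CLI exposes them individually. Stage timings go to the log
only, so identical configs and seeds yield byte-identical output bundles.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coexpression import (
    compare_pair_groups,
    correlation_vs_expression,
    major_preference,
    pair_correlation,
    rpk_normalize,
    whole_gene_counts,
    whole_gene_vs_major_tss,
)
from .io import read_gene_bed12, read_tss_bed, read_tsv, write_bedgraph, write_tsv
from .quantify import (
    TssCountMatrix,
    assign_molecules,
    classify_reads,
    collapse_umis,
    curate_tss,
    gene_body_profile,
    spikein_deviation_profile,
    tss_vicinity_profile,
)
from .select_filter import (
    build_reference_regions,
    expression_gate_pairs,
    expression_gate_tss,
    reference_filter,
    select_major_minor,
    surviving_tss,
)
from .usage import binomial_deviation, bimodal_split, differential_usage, ratio_group_de

log = logging.getLogger(__name__)

MOLECULE_DTYPES = {"cell_id": str, "chrom": str, "strand": str, "pos5": int,
                   "umi": str, "n_reads": int}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else round(f, 10)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _read_json(path: Path) -> dict:
    return json.loads(path.read_text()) if path.exists() else {}


def _record_stage(workdir: Path, name: str, n_in: int, n_out: int, t0: float) -> None:
    path = workdir / "manifest.json"
    manifest = _read_json(path)
    manifest.setdefault("stages", {})[name] = {
        "records_in": int(n_in), "records_out": int(n_out),
    }
    _write_json(manifest, path)
    log.info("%s: %d -> %d records (%.2fs)", name, n_in, n_out, time.perf_counter() - t0)


def _load_labels(config: PipelineConfig) -> pd.Series:
    labels = read_tsv(config.cell_labels, dtype={"cell_id": str, "cell_type": str})
    return labels.set_index("cell_id")["cell_type"]


def _load_matrix(config: PipelineConfig, workdir: Path) -> TssCountMatrix:
    counts = read_tsv(workdir / "tss_counts.tsv", index_col="cell_id")
    counts.index = counts.index.astype(str)
    curated = read_tsv(workdir / "curated_tss.tsv",
                       dtype={"gene_id": str, "tss_id": str, "chrom": str, "strand": str})
    return TssCountMatrix(counts=counts, cell_types=_load_labels(config), tss=curated)


def _load_molecules(workdir: Path) -> pd.DataFrame:
    return read_tsv(workdir / "molecules.tsv", dtype=MOLECULE_DTYPES)


def _load_pairs(workdir: Path, gated: bool = True) -> pd.DataFrame:
    name = "gated_pairs.tsv" if gated else "gene_pairs.tsv"
    path = workdir / name
    df = read_tsv(path, dtype={"gene_id": str, "major_tss": str, "minor_tss": str})
    return df


def _major_minor_matrices(matrix: TssCountMatrix, pairs: pd.DataFrame, cell_type: str):
    sub = matrix.subset_cells(cell_type)
    major = sub.counts.reindex(columns=pairs["major_tss"], fill_value=0)
    minor = sub.counts.reindex(columns=pairs["minor_tss"], fill_value=0)
    major.columns = pairs["gene_id"].to_numpy()
    minor.columns = pairs["gene_id"].to_numpy()
    return major, minor


# ---------------------------------------------------------------- stages


def stage_quantify(config: PipelineConfig, workdir: str | Path) -> None:
    """Collapse reads to molecules, curate TSSs, count, and run QC."""
    t0 = time.perf_counter()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    _write_json(
        {
            "software": f"alttss {__version__}",
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
            "stages": {},
        },
        workdir / "manifest.json",
    )

    tss_raw = read_tss_bed(config.annotation)
    genes = read_gene_bed12(config.gene_models)
    reads = read_tsv(config.reads, dtype={"cell": str, "chrom": str, "umi": str})
    spikeins = read_tsv(config.spikeins)
    cell_types = _load_labels(config)

    unlabeled = sorted(set(reads["cell"]) - set(cell_types.index))
    if unlabeled:
        raise ValueError(f"cells without a cell-type label: {unlabeled}")

    molecules = collapse_umis(reads)
    _record_stage(workdir, "collapse_umis", len(reads), len(molecules), t0)
    write_tsv(molecules, workdir / "molecules.tsv")

    curated = curate_tss(tss_raw)
    _record_stage(workdir, "curate_tss", len(tss_raw), len(curated), t0)
    write_tsv(curated, workdir / "curated_tss.tsv")

    matrix, _side = assign_molecules(molecules, curated, cell_types)
    _record_stage(workdir, "assign_molecules", len(molecules),
                  int(matrix.counts.to_numpy().sum()), t0)
    write_tsv(matrix.counts.reset_index(), workdir / "tss_counts.tsv")

    qc: dict = {}
    categories = classify_reads(molecules, genes, curated)
    write_tsv(categories, workdir / "read_categories.tsv")
    qc["read_categories"] = dict(
        zip(categories["category"], categories["fraction"].astype(float))
    )
    try:
        spike_profile = spikein_deviation_profile(molecules, spikeins)
        write_tsv(spike_profile, workdir / "spikein_profile.tsv")
        qc["spikein_percent_exact"] = float(
            100.0 * spike_profile.loc[spike_profile["offset"] == 0, "n_molecules"].sum()
            / spike_profile["n_molecules"].sum()
        )
    except ValueError as err:
        log.warning("spike-in profile skipped: %s", err)
        qc["spikein_percent_exact"] = float("nan")
    vicinity, within50 = tss_vicinity_profile(molecules, curated)
    write_tsv(vicinity, workdir / "tss_vicinity_profile.tsv")
    qc["tss_fraction_within_50bp"] = within50
    body = gene_body_profile(molecules, genes)
    write_tsv(body, workdir / "gene_body_profile.tsv")
    qc["n_reads"] = int(len(reads))
    qc["n_molecules"] = int(len(molecules))
    qc["n_cells"] = int(len(cell_types))
    _write_json(qc, workdir / "qc.json")


def stage_filter(config: PipelineConfig, workdir: str | Path) -> None:
    """Reference-region filtering, expression gating, pair selection."""
    t0 = time.perf_counter()
    workdir = Path(workdir)
    matrix = _load_matrix(config, workdir)
    molecules = _load_molecules(workdir)
    curated = matrix.tss

    refs = build_reference_regions(curated)
    write_tsv(refs, workdir / "reference_regions.tsv")
    filt = reference_filter(matrix, molecules, refs, config.ref_filter_threshold)
    write_tsv(filt, workdir / "reference_filter.tsv")
    surviving = surviving_tss(filt)
    _record_stage(workdir, "reference_filter", len(curated), len(surviving), t0)

    info: dict = {
        "n_tss_curated": int(len(curated)),
        "n_tss_surviving": int(len(surviving)),
        "filter_removed_fraction": float(1 - len(surviving) / len(curated))
        if len(curated) else float("nan"),
    }
    gated = expression_gate_tss(matrix, config.min_tss_total)
    usable = [t for t in gated if t in set(surviving)]
    pairs = select_major_minor(matrix, usable, config.promoter_distance_bp)
    _record_stage(workdir, "select_major_minor", len(usable), len(pairs), t0)
    write_tsv(pairs, workdir / "gene_pairs.tsv")

    gated_pairs = expression_gate_pairs(
        matrix, pairs, config.min_pair_per_cell, cell_type=config.analysis_cell_type
    )
    write_tsv(gated_pairs, workdir / "gated_pairs.tsv")
    info["n_tss_gated"] = len(usable)
    info["n_gene_pairs"] = int(len(pairs))
    info["n_pairs_expression_gated"] = int(len(gated_pairs))
    if not surviving:
        info["stopped_after"] = "reference_filter"
        log.warning("no TSS survived the reference filter")
    elif gated_pairs.empty:
        info["stopped_after"] = "expression_gate"
        log.warning("0 pairs pass the expression gate")
    _write_json(info, workdir / "filter.json")


def stage_coexpress(config: PipelineConfig, workdir: str | Path) -> None:
    """Pair correlations, regression, group comparisons, rpk contrast."""
    t0 = time.perf_counter()
    workdir = Path(workdir)
    matrix = _load_matrix(config, workdir)
    gated_pairs = _load_pairs(workdir)
    ct = config.analysis_cell_type
    out: dict = {}

    if gated_pairs.empty:
        _write_json({"skipped": "no gated pairs"}, workdir / "coexpression.json")
        return

    sub = matrix.subset_cells(ct)
    paircorr = pair_correlation(sub.counts, gated_pairs, normalization="counts")
    write_tsv(paircorr, workdir / "pair_correlations.tsv")
    _record_stage(workdir, "pair_correlation", len(gated_pairs),
                  int(paircorr["computable"].sum()), t0)
    ok = paircorr.loc[paircorr["computable"]]
    out["mean_pair_r_counts"] = float(ok["r"].mean()) if len(ok) else float("nan")

    filt = read_tsv(workdir / "reference_filter.tsv", dtype={"tss_id": str})
    usable = [t for t in surviving_tss(filt) if t in sub.counts.columns]
    pref, pref_hist = major_preference(
        TssCountMatrix(sub.counts[usable], sub.cell_types, matrix.tss), bins=10
    )
    write_tsv(pref_hist, workdir / "major_preference_hist.tsv")
    out["major_preference_ge_0.9_fraction"] = (
        float((pref >= 0.9).mean()) if len(pref) else float("nan")
    )

    try:
        out["r_vs_expression"] = correlation_vs_expression(paircorr)
    except ValueError as err:
        log.warning("r-vs-expression regression skipped: %s", err)
    for grouping in ("pair_class", "major_is_upstream"):
        try:
            out[grouping] = compare_pair_groups(paircorr, grouping, config.group_test)
        except ValueError as err:
            log.warning("group comparison %s skipped: %s", grouping, err)

    rpk, _excluded = rpk_normalize(sub, config.rpk_cell_gate)
    if len(rpk) >= 3:
        paircorr_rpk = pair_correlation(rpk, gated_pairs, normalization="rpk")
        write_tsv(paircorr_rpk, workdir / "pair_correlations_rpk.tsv")
        ok_rpk = paircorr_rpk.loc[paircorr_rpk["computable"]]
        out["mean_pair_r_rpk"] = (
            float(ok_rpk["r"].mean()) if len(ok_rpk) else float("nan")
        )
        out["n_cells_rpk"] = int(len(rpk))

    molecules = _load_molecules(workdir)
    genes = read_gene_bed12(config.gene_models)
    gene_counts = whole_gene_counts(molecules, genes, sub.counts.index)
    major_mat, _ = _major_minor_matrices(matrix, gated_pairs, ct)
    pooled = whole_gene_vs_major_tss(gene_counts, major_mat, mode="pooled",
                                     seed=config.seed)
    write_tsv(pooled, workdir / "whole_gene_vs_major_tss.tsv")
    _write_json(out, workdir / "coexpression.json")


def stage_usagetest(config: PipelineConfig, workdir: str | Path) -> None:
    """Binomial ratio deviation, bimodal split + DE, differential usage."""
    t0 = time.perf_counter()
    workdir = Path(workdir)
    matrix = _load_matrix(config, workdir)
    gated_pairs = _load_pairs(workdir)
    ct = config.analysis_cell_type
    out: dict = {}

    if gated_pairs.empty:
        _write_json({"skipped": "no gated pairs"}, workdir / "usage.json")
        return

    major_mat, minor_mat = _major_minor_matrices(matrix, gated_pairs, ct)
    dev_rows = []
    for gene in gated_pairs["gene_id"]:
        try:
            res = binomial_deviation(
                major_mat[gene], minor_mat[gene], config.binomial_alpha, gene_id=gene
            )
        except ValueError:
            continue
        dev_rows.append(
            {
                "gene_id": gene,
                "p0": res.p0,
                "n_eligible": res.n_eligible,
                "percent_deviating": res.percent_deviating,
                "degenerate_p0": res.degenerate_p0,
            }
        )
    deviation = pd.DataFrame(
        dev_rows,
        columns=["gene_id", "p0", "n_eligible", "percent_deviating", "degenerate_p0"],
    )
    write_tsv(deviation, workdir / "binomial_deviation.tsv")
    _record_stage(workdir, "binomial_deviation", len(gated_pairs), len(deviation), t0)

    if len(deviation):
        out["mean_percent_deviating"] = float(deviation["percent_deviating"].mean())
        top = deviation.sort_values(
            ["percent_deviating", "gene_id"], ascending=[False, True]
        ).iloc[0]
        out["most_bimodal_gene"] = {
            "gene_id": str(top["gene_id"]),
            "percent_deviating": float(top["percent_deviating"]),
        }
        split = bimodal_split(
            major_mat[top["gene_id"]], minor_mat[top["gene_id"]],
            config.bimodal_min_total, config.bimodal_ratio,
        )
        write_tsv(split, workdir / "bimodal_split.tsv")
        eligible = split.loc[split["eligible"]]
        if ((eligible["group"] == "major_high").sum() >= 2
                and (eligible["group"] == "major_low").sum() >= 2):
            molecules = _load_molecules(workdir)
            genes = read_gene_bed12(config.gene_models)
            sub_cells = matrix.subset_cells(ct).counts.index
            gene_counts = whole_gene_counts(molecules, genes, sub_cells)
            de = ratio_group_de(
                gene_counts, split, config.de_min_mean,
                config.de_fold_change, config.de_alpha,
            )
            write_tsv(de, workdir / "ratio_group_de.tsv")
            out["ratio_group_de"] = {
                "n_tested": int(len(de)),
                "n_significant": int(de["significant"].sum()),
                "n_significant_fc": int((de["significant"] & de["passes_fc"]).sum()),
            }

    ct_a, ct_b = config.compare_cell_types
    ma, na = _major_minor_matrices(matrix, gated_pairs, ct_a)
    mb, nb = _major_minor_matrices(matrix, gated_pairs, ct_b)
    du = differential_usage(
        ma, na, mb, nb,
        alpha=config.de_alpha,
        min_expressed_frac=config.usage_min_expressed_frac,
        min_delta=config.usage_min_delta,
    )
    write_tsv(du, workdir / "differential_usage.tsv")
    out["differential_usage"] = {
        "n_tested": int(len(du)),
        "n_flagged": int(du["flagged"].sum()) if len(du) else 0,
        "flagged_genes": sorted(du.loc[du["flagged"], "gene_id"].tolist())
        if len(du) else [],
    }
    _write_json(out, workdir / "usage.json")


def stage_report(config: PipelineConfig, workdir: str | Path) -> dict:
    """Collate stage outputs into summary.json and a plain-text digest."""
    workdir = Path(workdir)
    summary: dict = {}
    for name in ("qc", "filter", "coexpression", "usage"):
        payload = _read_json(workdir / f"{name}.json")
        if payload:
            summary[name] = payload
    _write_json(summary, workdir / "summary.json")
    lines = ["alttss run summary", "==================="]
    for section, payload in summary.items():
        lines.append(f"[{section}]")
        for key, value in sorted(payload.items()):
            lines.append(f"  {key}: {json.dumps(_jsonable(value), sort_keys=True)}")
    (workdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> dict:
    """Run all stages in order and return the result bundle."""
    config.validate()
    workdir = Path(workdir)
    stage_quantify(config, workdir)
    stage_filter(config, workdir)
    stage_coexpress(config, workdir)
    stage_usagetest(config, workdir)
    summary = stage_report(config, workdir)
    bundle = {"summary": summary, "manifest": _read_json(workdir / "manifest.json")}
    bundle["matrix"] = _load_matrix(config, workdir)
    bundle["pairs"] = _load_pairs(workdir, gated=False)
    bundle["gated_pairs"] = _load_pairs(workdir)
    for key, name in [
        ("pair_correlations", "pair_correlations.tsv"),
        ("deviation", "binomial_deviation.tsv"),
        ("differential_usage", "differential_usage.tsv"),
    ]:
        path = workdir / name
        if path.exists():
            bundle[key] = read_tsv(path)
    return bundle


def export_tracks(
    matrix: TssCountMatrix, outdir: str | Path, cells: list[str] | None = None
) -> None:
    """Write per-cell and pooled molecule-count bedGraph tracks over TSSs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tss = matrix.tss.set_index("tss_id")

    def _intervals(counts: pd.Series) -> pd.DataFrame:
        nz = counts[counts > 0]
        if nz.empty:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        meta = tss.loc[nz.index]
        return (
            pd.DataFrame(
                {
                    "chrom": meta["chrom"].to_numpy(),
                    "start": meta["start"].to_numpy(),
                    "end": meta["end"].to_numpy(),
                    "value": nz.to_numpy(),
                }
            )
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )

    for cell in (cells or []):
        write_bedgraph(
            _intervals(matrix.counts.loc[cell]), outdir / f"{cell}.bedgraph", cell
        )
    write_bedgraph(
        _intervals(matrix.counts.sum(axis=0)), outdir / "pooled.bedgraph", "pooled"
    )
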