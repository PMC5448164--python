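"""Degradation filtering and major/minor TSS selection.

Each TSS gets an upstream and a downstream *reference region* of equal
width placed immediately adjacent (shifted past any blocking TSS). A TSS
whose reference region on either side captures strictly more than 20% of
the combined TSS + reference molecules is considered degradation-
contaminated and removed. Among surviving TSSs, the major and minor TSS of
a gene are the two with the largest dataset-wide molecule totals, pooling
all cell types; pairs are classified proximal (<1 kb edge distance) or
promoter (>= 1 kb).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantify import TssCountMatrix, _containment_lookup

log = logging.getLogger(__name__)


def build_reference_regions(curated_tss: pd.DataFrame) -> pd.DataFrame:
    """One upstream and one downstream flank of TSS width per TSS.

    Flanks sit immediately adjacent to the TSS; a flank whose slot overlaps
    another curated TSS is shifted immediately beyond that TSS's far edge,
    iterating until clear. Side labels follow the transcription direction
    (for minus-strand TSSs "upstream" lies at higher coordinates). A flank
    that would run past the chromosome start is reported absent (logged).
    Reference regions may overlap each other but never a TSS.
    """
    rows = []
    for (chrom, strand), grp in curated_tss.groupby(["chrom", "strand"], sort=True):
        iv = grp.sort_values("start")
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        for _, t in iv.iterrows():
            width = int(t["end"] - t["start"])
            for genomic_side in ("left", "right"):
                if genomic_side == "left":
                    end = int(t["start"])
                    start = end - width
                    # shift past any TSS overlapping [start, end)
                    while True:
                        mask = (starts < end) & (ends > start)
                        mask &= ~((starts == t["start"]) & (ends == t["end"]))
                        if not mask.any():
                            break
                        end = int(starts[mask].min())
                        start = end - width
                    absent = start < 0
                else:
                    start = int(t["end"])
                    end = start + width
                    while True:
                        mask = (starts < end) & (ends > start)
                        mask &= ~((starts == t["start"]) & (ends == t["end"]))
                        if not mask.any():
                            break
                        start = int(ends[mask].max())
                        end = start + width
                    absent = False
                side = (
                    "upstream"
                    if (genomic_side == "left") == (strand == "+")
                    else "downstream"
                )
                if absent:
                    log.warning(
                        "build_reference_regions: %s %s flank runs off %s start",
                        t["tss_id"], side, chrom,
                    )
                    continue
                rows.append(
                    {
                        "tss_id": t["tss_id"],
                        "side": side,
                        "chrom": chrom,
                        "strand": strand,
                        "start": start,
                        "end": end,
                    }
                )
    return pd.DataFrame(rows, columns=["tss_id", "side", "chrom", "strand", "start", "end"])


def reference_filter(
    matrix: TssCountMatrix,
    molecules: pd.DataFrame,
    reference_regions: pd.DataFrame,
    threshold: float = 0.20,
) -> pd.DataFrame:
    """Flag TSSs whose flanks carry > threshold of TSS + flank molecules.

    Molecule counts are dataset-pooled. ``molecules`` should be the full
    molecule table (assigned + side channel); reference regions never
    overlap TSSs, so TSS molecules are never double counted. Returns a per-
    TSS frame with flank counts, the per-side ratios, and a status among
    ``kept`` / ``removed`` / ``untested`` (no molecules on either the TSS or
    its flanks).
    """
    tss_totals = matrix.counts.sum(axis=0)

    ref = reference_regions.copy()
    ref["region_id"] = ref["tss_id"] + "|" + ref["side"]
    hits = _containment_lookup(
        molecules,
        ref[["region_id", "chrom", "strand", "start", "end"]],
        stranded=True,
    )
    ref_counts = hits.dropna().value_counts()

    rows = []
    for tss_id in matrix.counts.columns:
        t = int(tss_totals.get(tss_id, 0))
        sides = {}
        for side in ("upstream", "downstream"):
            rid = f"{tss_id}|{side}"
            present = (ref["region_id"] == rid).any()
            sides[side] = int(ref_counts.get(rid, 0)) if present else None
        ratios = {}
        removed = False
        tested = False
        for side, c in sides.items():
            if c is None:
                ratios[side] = np.nan
                continue
            denom = t + c
            if denom == 0:
                ratios[side] = np.nan
                continue
            tested = True
            ratios[side] = c / denom
            if c / denom > threshold:  # strictly more than
                removed = True
        status = "removed" if removed else ("kept" if tested else "untested")
        rows.append(
            {
                "tss_id": tss_id,
                "tss_total": t,
                "ref_upstream": -1 if sides["upstream"] is None else sides["upstream"],
                "ref_downstream": -1 if sides["downstream"] is None else sides["downstream"],
                "ratio_upstream": ratios["upstream"],
                "ratio_downstream": ratios["downstream"],
                "status": status,
            }
        )
    result = pd.DataFrame(rows)
    n_removed = int((result["status"] == "removed").sum())
    log.info(
        "reference_filter: removed %d/%d TSSs (%.1f%%) at threshold %.2f",
        n_removed, len(result),
        100.0 * n_removed / len(result) if len(result) else 0.0, threshold,
    )
    return result


def surviving_tss(filter_result: pd.DataFrame) -> list[str]:
    """TSS ids not removed by the reference filter (untested ones retained)."""
    return filter_result.loc[filter_result["status"] != "removed", "tss_id"].tolist()


def select_major_minor(
    matrix: TssCountMatrix, surviving: list[str] | None = None,
    promoter_distance_bp: int = 1000,
) -> pd.DataFrame:
    """Per-gene major/minor TSS pairs from dataset-wide totals.

    The major TSS has the greatest molecule total across the entire dataset
    (all cell types pooled) and the minor the second greatest — so the major
    TSS need not lead within any one cell type. Exact ties break towards the
    TSS lying upstream in the transcription direction (logged). Genes with
    fewer than two surviving TSSs are excluded. Edge distance is the gap
    between the nearest interval edges; pairs at >= ``promoter_distance_bp``
    are classified ``promoter``, closer pairs ``proximal``.
    """
    tss = matrix.tss
    if surviving is not None:
        tss = tss.loc[tss["tss_id"].isin(surviving)]
    totals = matrix.counts.sum(axis=0)

    rows = []
    for gene_id, grp in tss.groupby("gene_id", sort=True):
        if len(grp) < 2:
            continue
        strand = grp["strand"].iloc[0]
        grp = grp.assign(total=[int(totals.get(t, 0)) for t in grp["tss_id"]])
        # upstream in transcription direction first, as the tie-break order
        grp = grp.sort_values("start", ascending=(strand == "+"))
        grp = grp.sort_values("total", ascending=False, kind="stable")
        major, minor = grp.iloc[0], grp.iloc[1]
        if major["total"] == minor["total"]:
            log.info("select_major_minor: %s tie broken towards upstream TSS", gene_id)
        gap = max(minor["start"] - major["end"], major["start"] - minor["end"])
        if gap < 1:
            log.warning("select_major_minor: %s pair not separated (gap %d)", gene_id, gap)
        if strand == "+":
            major_is_upstream = major["start"] < minor["start"]
        else:
            major_is_upstream = major["start"] > minor["start"]
        rows.append(
            {
                "gene_id": gene_id,
                "major_tss": major["tss_id"],
                "minor_tss": minor["tss_id"],
                "major_total": int(major["total"]),
                "minor_total": int(minor["total"]),
                "edge_distance": int(gap),
                "pair_class": "promoter" if gap >= promoter_distance_bp else "proximal",
                "major_is_upstream": bool(major_is_upstream),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "major_tss", "minor_tss", "major_total", "minor_total",
            "edge_distance", "pair_class", "major_is_upstream",
        ],
    )


def expression_gate_tss(matrix: TssCountMatrix, min_total: int = 100) -> list[str]:
    """TSSs with at least ``min_total`` molecules across all cells (inclusive)."""
    totals = matrix.counts.sum(axis=0)
    return totals.index[totals >= min_total].tolist()


def expression_gate_pairs(
    matrix: TssCountMatrix,
    pairs: pd.DataFrame,
    min_per_cell: float = 0.3,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Pairs averaging >= ``min_per_cell`` molecules per cell per TSS.

    The per-pair statistic is the mean of the two TSS per-cell means, i.e.
    pair total / (2 * n_cells), within the analysed cell type (all cells if
    None). The boundary is inclusive.
    """
    m = matrix if cell_type is None else matrix.subset_cells(cell_type)
    n = len(m.counts)
    if n == 0 or pairs.empty:
        return pairs.iloc[0:0].copy()
    mean_pair = (
        m.counts.reindex(columns=pairs["major_tss"], fill_value=0).to_numpy().sum(axis=0)
        + m.counts.reindex(columns=pairs["minor_tss"], fill_value=0).to_numpy().sum(axis=0)
    ) / (2.0 * n)
    out = pairs.assign(mean_pair_expression=mean_pair)
    return out.loc[out["mean_pair_expression"] >= min_per_cell].reset_index(drop=True)
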