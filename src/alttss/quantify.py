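"""From 5'-tag reads to molecules and TSS counts, with positional QC.

A *molecule* is a group of >= 2 reads sharing (cell, chrom, strand, 5'
position, UMI); singleton-read UMIs are treated as errors and dropped.
Molecules are allocated to curated, disjoint TSS windows by strand-aware
containment of the 5' base, and the remainder feeds the read-category and
degradation profiles.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

READ_COLUMNS = ["cell", "chrom", "pos0", "strand", "umi"]


@dataclass
class TssCountMatrix:
    """Cells x TSS molecule counts with per-cell labels.

    ``counts`` is indexed by cell_id with one column per tss_id;
    ``cell_types`` maps cell_id -> label; ``tss`` carries the curated
    interval table for the columns.
    """

    counts: pd.DataFrame
    cell_types: pd.Series
    tss: pd.DataFrame

    @property
    def cell_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_cells(self, cell_type: str) -> "TssCountMatrix":
        keep = self.cell_types.index[self.cell_types == cell_type]
        return TssCountMatrix(
            counts=self.counts.loc[keep],
            cell_types=self.cell_types.loc[keep],
            tss=self.tss,
        )


def collapse_umis(reads: pd.DataFrame, umi_length: int | None = None) -> pd.DataFrame:
    """Collapse reads into molecules; singleton-read UMIs are removed.

    Returns one row per (cell, chrom, strand, pos0, umi) group with >= 2
    reads, with the group size recorded as ``n_reads``. Rows whose UMI
    contains characters outside A/C/G/T (or with unexpected length, if
    ``umi_length`` is given) are rejected and counted in the log, never a
    crash.
    """
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table lacks columns {missing}")
    if len(reads) == 0:
        return pd.DataFrame(
            columns=["cell_id", "chrom", "strand", "pos5", "umi", "n_reads"]
        )
    pattern = re.compile(
        f"^[ACGT]{{{umi_length}}}$" if umi_length else "^[ACGT]+$"
    )
    valid = reads["umi"].astype(str).str.match(pattern)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("collapse_umis: rejected %d reads with malformed UMIs", n_bad)
        reads = reads.loc[valid]

    grouped = (
        reads.groupby(["cell", "chrom", "strand", "pos0", "umi"], sort=True, observed=True)
        .size()
        .rename("n_reads")
        .reset_index()
    )
    molecules = grouped.loc[grouped["n_reads"] >= 2].reset_index(drop=True)
    log.info(
        "collapse_umis: %d reads -> %d molecules (%d singleton UMI groups removed)",
        len(reads), len(molecules), int((grouped["n_reads"] == 1).sum()),
    )
    return molecules.rename(columns={"cell": "cell_id", "pos0": "pos5"})[
        ["cell_id", "chrom", "strand", "pos5", "umi", "n_reads"]
    ]


def curate_tss(raw: pd.DataFrame) -> pd.DataFrame:
    """Resolve overlaps among gene-associated TSS intervals.

    Intervals without a gene association (empty/NA gene_id) are discarded.
    Where two intervals on the same chrom/strand overlap, the longer one is
    trimmed on its overlapping side so a 1 bp gap remains; equal lengths trim
    the downstream-in-genome one (larger start). An interval that fully
    contains a shorter one cannot be trimmed into a single valid window and
    is dropped (logged). Output is disjoint with gap >= 1 bp and gains a
    ``center`` column (floor midpoint).
    """
    tss = raw.copy()
    has_gene = tss["gene_id"].notna() & (tss["gene_id"].astype(str) != "")
    if (~has_gene).any():
        log.info("curate_tss: discarded %d gene-less intervals", int((~has_gene).sum()))
        tss = tss.loc[has_gene]
    if (tss["start"] >= tss["end"]).any():
        raise ValueError("invalid interval with start >= end")

    out_frames = []
    for (chrom, strand), grp in tss.groupby(["chrom", "strand"], sort=True):
        rows = grp.sort_values(["start", "end"]).to_dict("records")
        i = 0
        while i < len(rows) - 1:
            a, b = rows[i], rows[i + 1]
            if b["start"] >= a["end"]:  # disjoint; enforce 1 bp gap lazily:
                if b["start"] == a["end"]:
                    # touching counts as needing the 1 bp gap; trim the longer
                    la, lb = a["end"] - a["start"], b["end"] - b["start"]
                    victim = a if la > lb else b  # equal lengths: larger start loses
                    if victim is a:
                        a["end"] = b["start"] - 1
                    else:
                        b["start"] = a["end"] + 1
                    if victim["end"] - victim["start"] < 1:
                        log.warning("curate_tss: dropped %s (trimmed away)", victim["tss_id"])
                        rows.remove(victim)
                        i = max(i - 1, 0)
                        continue
                i += 1
                continue
            la, lb = a["end"] - a["start"], b["end"] - b["start"]
            if a["start"] < b["start"] and b["end"] < a["end"]:
                # shorter b strictly nested inside a: no one-sided trim fixes it
                log.warning("curate_tss: dropped %s (contains %s)", a["tss_id"], b["tss_id"])
                rows.pop(i)
                i = max(i - 1, 0)
                continue
            # partial overlap (possibly sharing an edge): trim the longer on
            # its overlapping side
            if la > lb or (la == lb and a["start"] >= b["start"]):
                victim = a
            else:
                victim = b
            if victim is a:
                a["end"] = b["start"] - 1  # a is the left interval
            else:
                b["start"] = a["end"] + 1
            if victim["end"] - victim["start"] < 1:
                log.warning("curate_tss: dropped %s (trimmed away)", victim["tss_id"])
                rows.remove(victim)
                i = max(i - 1, 0)
                continue
            # re-sort locally in case trimming reordered starts
            rows.sort(key=lambda r: (r["start"], r["end"]))
        out_frames.append(pd.DataFrame(rows))

    curated = (
        pd.concat(out_frames, ignore_index=True)
        if out_frames
        else tss.iloc[0:0].copy()
    )
    if len(curated):
        curated["center"] = (curated["start"] + curated["end"]) // 2
        curated = curated.sort_values(["chrom", "start"]).reset_index(drop=True)
    else:
        curated["center"] = pd.Series(dtype=int)
    return curated


def _containment_lookup(
    molecules: pd.DataFrame, intervals: pd.DataFrame, stranded: bool = True
) -> pd.Series:
    """Map each molecule to the id of the disjoint interval containing pos5.

    Returns a Series (aligned to ``molecules.index``) of interval ids from
    ``intervals``'s first column, or NA when uncontained. ``intervals`` must
    be disjoint within each (chrom[, strand]) group.
    """
    id_col = intervals.columns[0]
    result = pd.Series(pd.NA, index=molecules.index, dtype=object)
    keys = ["chrom", "strand"] if stranded else ["chrom"]
    grouped_iv = dict(tuple(intervals.groupby(keys, sort=False)))
    for key, mgrp in molecules.groupby(keys, sort=False):
        iv = grouped_iv.get(key)
        if iv is None:
            continue
        iv = iv.sort_values("start")
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        ids = iv[id_col].to_numpy()
        pos = mgrp["pos5"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        hit = np.where(ok, idx, -1)
        vals = np.where(hit >= 0, ids[np.maximum(hit, 0)], None)
        result.loc[mgrp.index] = vals
    return result


def assign_molecules(
    molecules: pd.DataFrame,
    curated_tss: pd.DataFrame,
    cell_types: pd.Series,
) -> tuple[TssCountMatrix, pd.DataFrame]:
    """Count molecules whose 5' end lies within a same-strand curated TSS.

    Returns the count matrix over all cells in ``cell_types`` (zero rows for
    cells without TSS molecules) and the side channel of unassigned
    molecules. Total molecules are conserved: assigned + unassigned = input.
    """
    mol = molecules.copy()
    mol["tss_id"] = _containment_lookup(
        mol, curated_tss[["tss_id", "chrom", "strand", "start", "end"]], stranded=True
    )
    assigned = mol.loc[mol["tss_id"].notna()]
    unassigned = mol.loc[mol["tss_id"].isna()].drop(columns=["tss_id"])

    counts = (
        assigned.groupby(["cell_id", "tss_id"], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=cell_types.index, columns=curated_tss["tss_id"], fill_value=0)
        .astype(np.int64)
    )
    counts.index.name = "cell_id"
    counts.columns.name = "tss_id"
    log.info(
        "assign_molecules: %d/%d molecules inside curated TSSs",
        len(assigned), len(mol),
    )
    return (
        TssCountMatrix(counts=counts, cell_types=cell_types, tss=curated_tss),
        unassigned.reset_index(drop=True),
    )


CATEGORIES = ("tss", "exonic", "intronic", "outside")


def classify_reads(
    molecules: pd.DataFrame, genes: pd.DataFrame, curated_tss: pd.DataFrame
) -> pd.DataFrame:
    """Assign each molecule once to TSS > exonic > intronic > outside.

    ``genes`` needs gene_id/chrom/start/end/strand plus comma-separated
    ``exon_starts`` (gene-relative) and ``exon_sizes``. Returns a one-row-
    per-category frame with counts and fractions; counts sum to the input.
    """
    mol = molecules.copy()
    in_tss = _containment_lookup(
        mol, curated_tss[["tss_id", "chrom", "strand", "start", "end"]], stranded=True
    ).notna()
    gene_hit = _containment_lookup(
        mol, genes[["gene_id", "chrom", "strand", "start", "end"]], stranded=True
    )
    in_gene = gene_hit.notna()

    exon_rows = []
    for _, g in genes.iterrows():
        starts = [int(s) for s in str(g["exon_starts"]).split(",") if s != ""]
        sizes = [int(s) for s in str(g["exon_sizes"]).split(",") if s != ""]
        for s, w in zip(starts, sizes):
            exon_rows.append(
                {
                    "exon_id": f"{g['gene_id']}:{s}",
                    "chrom": g["chrom"],
                    "strand": g["strand"],
                    "start": g["start"] + s,
                    "end": g["start"] + s + w,
                }
            )
    if exon_rows:
        exons = pd.DataFrame(exon_rows)
        in_exon = _containment_lookup(mol, exons, stranded=True).notna()
    else:
        in_exon = pd.Series(False, index=mol.index)

    category = np.select(
        [in_tss & in_gene, in_tss, in_gene & in_exon, in_gene],
        ["tss", "tss", "exonic", "intronic"],
        default="outside",
    )
    counts = pd.Series(category).value_counts().reindex(CATEGORIES, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "category": CATEGORIES,
            "n_molecules": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    )


def spikein_deviation_profile(
    molecules: pd.DataFrame, spikeins: pd.DataFrame
) -> pd.DataFrame:
    """Offsets of spike-in 5' ends from each spike's median mapped position.

    For every spike-in the median of its mapped positions defines offset 0;
    offsets are pooled across spike-ins and reported as a percentage of the
    offset-0 count. Spike-ins with no molecules are omitted (logged).
    """
    iv = spikeins.copy()
    iv["end"] = iv["start"] + iv["length"]
    hits = _containment_lookup(
        molecules,
        iv[["spike_id", "chrom", "start", "end"]].assign(strand="+"),
        stranded=False,
    )
    mol = molecules.assign(spike_id=hits).dropna(subset=["spike_id"])
    offsets = []
    seen = set()
    for spike_id, grp in mol.groupby("spike_id", sort=True):
        seen.add(spike_id)
        med = int(np.floor(grp["pos5"].median()))
        offsets.append(grp["pos5"].to_numpy() - med)
    skipped = set(spikeins["spike_id"]) - seen
    if skipped:
        log.info("spikein_deviation_profile: %d spike-ins had no molecules", len(skipped))
    if not offsets:
        raise ValueError("no spike-in molecules to profile")
    pooled = np.concatenate(offsets)
    values, counts = np.unique(pooled, return_counts=True)
    at_zero = counts[values == 0].sum()
    if at_zero == 0:
        raise ValueError("no molecules at the median start position")
    return pd.DataFrame(
        {
            "offset": values,
            "n_molecules": counts,
            "percent_of_exact": 100.0 * counts / at_zero,
        }
    )


def tss_vicinity_profile(
    molecules: pd.DataFrame, curated_tss: pd.DataFrame, window: int = 100
) -> tuple[pd.DataFrame, float]:
    """Strand-oriented 5'-end offsets from TSS centres within +/- window bp.

    Positive offsets point downstream in the transcription direction. Also
    returns the fraction of in-window molecules within +/- 50 bp of the
    centre.
    """
    offsets = []
    for (chrom, strand), grp in molecules.groupby(["chrom", "strand"], sort=False):
        iv = curated_tss.loc[
            (curated_tss["chrom"] == chrom) & (curated_tss["strand"] == strand)
        ]
        if iv.empty or grp.empty:
            continue
        centers = np.sort(iv["center"].to_numpy())
        pos = grp["pos5"].to_numpy()
        nearest = np.clip(np.searchsorted(centers, pos), 0, len(centers) - 1)
        left = np.clip(nearest - 1, 0, len(centers) - 1)
        pick = np.where(
            np.abs(centers[nearest] - pos) <= np.abs(centers[left] - pos), nearest, left
        )
        off = pos - centers[pick]
        if strand == "-":
            off = -off
        offsets.append(off[np.abs(off) <= window])
    if not offsets:
        raise ValueError("no molecules within the TSS vicinity window")
    pooled = np.concatenate(offsets)
    values, counts = np.unique(pooled, return_counts=True)
    profile = pd.DataFrame({"offset": values, "n_molecules": counts})
    within50 = float(counts[np.abs(values) <= 50].sum() / counts.sum())
    return profile, within50


def gene_body_profile(
    molecules: pd.DataFrame, genes: pd.DataFrame, n_bins: int = 20
) -> pd.DataFrame:
    """Pooled molecule distribution along gene bodies in equal-width bins.

    Bin 1 is the 5' end in transcription direction. Genes shorter than
    ``n_bins`` bp are excluded (logged); molecules outside every gene are
    ignored. Percentages sum to 100.
    """
    ok = genes["end"] - genes["start"] >= n_bins
    if (~ok).any():
        log.info("gene_body_profile: excluded %d genes shorter than %d bp",
                 int((~ok).sum()), n_bins)
    genes = genes.loc[ok]
    hits = _containment_lookup(
        molecules, genes[["gene_id", "chrom", "strand", "start", "end"]], stranded=True
    )
    mol = molecules.assign(gene_id=hits).dropna(subset=["gene_id"])
    if mol.empty:
        raise ValueError("no molecules mapped inside gene bodies")
    gmeta = genes.set_index("gene_id")
    starts = gmeta.loc[mol["gene_id"], "start"].to_numpy()
    ends = gmeta.loc[mol["gene_id"], "end"].to_numpy()
    strands = gmeta.loc[mol["gene_id"], "strand"].to_numpy()
    rel = (mol["pos5"].to_numpy() - starts) / (ends - starts)
    rel = np.where(strands == "-", 1.0 - rel, rel)  # orient 5' -> 3'
    bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "n_molecules": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )
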