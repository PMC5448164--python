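"""Reading and writing the pipeline's interchange formats.

BED output is native 0-based half-open; GTF gene models are converted to
half-open on read. Stage tables are headered TSVs with a fixed float format
so identical runs are byte-identical.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    """Write TSS intervals as BED6 with name = geneID:tssID."""
    bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["start"],
            "end": tss["end"],
            "name": tss["tss_id"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 TSS intervals; name must be geneID:tssID."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    gene_ids = bed["name"].str.split(":").str[0]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tss_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )


def write_gene_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models (with exon blocks) as BED12."""
    sizes = genes["exon_sizes"].astype(str)
    starts = genes["exon_starts"].astype(str)
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
            "thick_start": genes["start"],
            "thick_end": genes["end"],
            "rgb": "0,0,0",
            "block_count": starts.str.count(",") + 1,
            "block_sizes": sizes + ",",
            "block_starts": starts + ",",
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed12(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=[
            "chrom", "start", "end", "name", "score", "strand", "thick_start",
            "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
        ],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
            "exon_starts": bed["block_starts"].astype(str).str.rstrip(","),
            "exon_sizes": bed["block_sizes"].astype(str).str.rstrip(","),
        }
    )


def write_bedgraph(intervals: pd.DataFrame, path: str | Path, name: str) -> None:
    """Write chrom/start/end/value rows as a track-lined bedGraph."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        if len(intervals):
            intervals.to_csv(fh, sep="\t", header=False, index=False)
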