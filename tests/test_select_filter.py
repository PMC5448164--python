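"""Reference regions, the 20% degradation filter, and major/minor selection."""
import numpy as np
import pandas as pd
import pytest

from alttss.config import SimConfig
from alttss.quantify import TssCountMatrix
from alttss.select_filter import (
    build_reference_regions,
    expression_gate_pairs,
    expression_gate_tss,
    reference_filter,
    select_major_minor,
    surviving_tss,
)
from alttss.synthetic import generate_annotation

from conftest import make_molecules


def _tss(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "tss_id", "chrom", "start", "end", "strand"]
    )
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def _matrix(tss, counts: dict, cells=("c1",)):
    idx = pd.Index(list(cells), name="cell_id")
    mat = pd.DataFrame(0, index=idx, columns=tss["tss_id"])
    for tid, total in counts.items():
        mat.loc[mat.index[0], tid] = total
    types = pd.Series(["typeA"] * len(idx), index=idx, name="cell_type")
    return TssCountMatrix(counts=mat, cell_types=types, tss=tss)


class TestReferenceRegions:
    def test_isolated_tss_adjacent_flanks(self):
        tss = _tss([("g", "T", "chr1", 1000, 1100, "+")])
        refs = build_reference_regions(tss).set_index("side")
        assert (refs.loc["upstream", "start"], refs.loc["upstream", "end"]) == (900, 1000)
        assert (refs.loc["downstream", "start"], refs.loc["downstream", "end"]) == (1100, 1200)

    def test_minus_strand_side_labels_follow_transcription(self):
        tss = _tss([("g", "T", "chr1", 1000, 1100, "-")])
        refs = build_reference_regions(tss).set_index("side")
        assert refs.loc["upstream", "start"] == 1100   # higher coords = upstream
        assert refs.loc["downstream", "end"] == 1000

    def test_blocked_slot_shifted_past_neighbor(self):
        tss = _tss(
            [("g", "A", "chr1", 1000, 1100, "+"), ("g", "B", "chr1", 1101, 1150, "+")]
        )
        refs = build_reference_regions(tss)
        down_a = refs.loc[(refs["tss_id"] == "A") & (refs["side"] == "downstream")].iloc[0]
        assert down_a["start"] == 1150  # begins at B's far edge
        assert down_a["end"] == 1250

    def test_chromosome_start_side_absent(self):
        tss = _tss([("g", "T", "chr1", 30, 130, "+")])
        refs = build_reference_regions(tss)
        assert set(refs["side"]) == {"downstream"}

    def test_width_preserved_and_no_tss_overlap(self):
        ann = generate_annotation(SimConfig(n_genes=40, seed=21))
        tss = ann.tss.copy()
        tss["center"] = (tss["start"] + tss["end"]) // 2
        refs = build_reference_regions(tss)
        widths = tss.set_index("tss_id")["end"] - tss.set_index("tss_id")["start"]
        assert ((refs["end"] - refs["start"]).to_numpy()
                == widths.loc[refs["tss_id"]].to_numpy()).all()
        for ref in refs.itertuples():
            same = tss.loc[(tss["chrom"] == ref.chrom) & (tss["strand"] == ref.strand)]
            overlap = (same["start"] < ref.end) & (same["end"] > ref.start)
            assert not overlap.any()


class TestReferenceFilter:
    def _setup(self, tss_count, ref_up, ref_down=0):
        tss = _tss([("g", "T", "chr1", 1000, 1100, "+")])
        matrix = _matrix(tss, {"T": tss_count})
        refs = build_reference_regions(tss)
        mol = make_molecules(
            [("c1", "chr1", "+", 950)] * ref_up + [("c1", "chr1", "+", 1150)] * ref_down
        )
        return matrix, mol, refs

    def test_strictly_above_threshold_removed(self):
        matrix, mol, refs = self._setup(79, 21)
        out = reference_filter(matrix, mol, refs)
        assert out.iloc[0]["status"] == "removed"  # 21/100 > 0.20

    def test_exactly_at_threshold_kept(self):
        matrix, mol, refs = self._setup(80, 20)
        out = reference_filter(matrix, mol, refs)
        assert out.iloc[0]["status"] == "kept"  # 0.20 not > 0.20

    def test_clean_tss_kept(self):
        matrix, mol, refs = self._setup(100, 0, 0)
        out = reference_filter(matrix, mol, refs)
        assert out.iloc[0]["status"] == "kept"

    def test_zero_everywhere_untested(self):
        matrix, mol, refs = self._setup(0, 0, 0)
        out = reference_filter(matrix, mol, refs)
        assert out.iloc[0]["status"] == "untested"
        assert surviving_tss(out) == ["T"]

    def test_either_side_triggers_removal(self):
        matrix, mol, refs = self._setup(79, 0, 21)
        out = reference_filter(matrix, mol, refs)
        assert out.iloc[0]["status"] == "removed"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        tss = _tss(
            [("g%d" % i, "T%d" % i, "chr1", 10_000 * i + 1000, 10_000 * i + 1100, "+")
             for i in range(20)]
        )
        matrix = _matrix(tss, {f"T{i}": int(rng.integers(0, 60)) for i in range(20)})
        refs = build_reference_regions(tss)
        rows = []
        for ref in refs.itertuples():
            rows += [("c1", ref.chrom, ref.strand, int(ref.start) + 5)] * int(
                rng.integers(0, 30)
            )
        mol = make_molecules(rows)
        removed = [
            (reference_filter(matrix, mol, refs, threshold=t)["status"] == "removed").sum()
            for t in (0.05, 0.2, 0.4, 0.8)
        ]
        assert removed == sorted(removed, reverse=True)


class TestFilterVsBackground:
    def _removed_fraction(self, background_rate: float) -> float:
        from alttss.quantify import assign_molecules, collapse_umis, curate_tss
        from alttss.synthetic import simulate_dataset

        cfg = SimConfig(
            n_genes=30, n_cells=60, tss_per_gene={2: 1.0}, scatter_sd=0.0,
            background_rate=background_rate, spikein_mean=0.0, seed=61,
        )
        ann, truth, reads = simulate_dataset(cfg)
        molecules = collapse_umis(reads)
        curated = curate_tss(ann.tss)
        matrix, _ = assign_molecules(
            molecules, curated, truth.cells.set_index("cell_id")["cell_type"]
        )
        refs = build_reference_regions(curated)
        out = reference_filter(matrix, molecules, refs)
        return float((out["status"] == "removed").mean())

    def test_clean_data_removes_nothing_heavy_background_removes_more(self):
        removed = [self._removed_fraction(b) for b in (0.0, 5.0, 40.0)]
        assert removed[0] == 0.0
        assert removed == sorted(removed)
        assert removed[-1] > 0.0


class TestSelectMajorMinor:
    def test_argmax_and_second(self):
        tss = _tss(
            [("g", "T1", "chr1", 100, 200, "+"), ("g", "T2", "chr1", 700, 800, "+"),
             ("g", "T3", "chr1", 1500, 1600, "+")]
        )
        matrix = _matrix(tss, {"T1": 500, "T2": 100, "T3": 50})
        pairs = select_major_minor(matrix)
        assert pairs.iloc[0]["major_tss"] == "T1"
        assert pairs.iloc[0]["minor_tss"] == "T2"
        assert pairs.iloc[0]["edge_distance"] == 500
        assert pairs.iloc[0]["pair_class"] == "proximal"
        assert bool(pairs.iloc[0]["major_is_upstream"])

    def test_single_surviving_tss_no_pair(self):
        tss = _tss([("g", "T1", "chr1", 100, 200, "+"), ("g", "T2", "chr1", 700, 800, "+")])
        matrix = _matrix(tss, {"T1": 500, "T2": 100})
        assert select_major_minor(matrix, surviving=["T1"]).empty

    def test_promoter_class_at_one_kb(self):
        tss = _tss(
            [("g", "T1", "chr1", 0, 100, "+"), ("g", "T2", "chr1", 1100, 1200, "+")]
        )
        matrix = _matrix(tss, {"T1": 10, "T2": 5})
        pairs = select_major_minor(matrix)
        assert pairs.iloc[0]["edge_distance"] == 1000
        assert pairs.iloc[0]["pair_class"] == "promoter"  # boundary -> promoter

    def test_tie_breaks_to_upstream_in_transcription_direction(self):
        tss = _tss(
            [("g", "T1", "chr1", 100, 200, "-"), ("g", "T2", "chr1", 700, 800, "-")]
        )
        matrix = _matrix(tss, {"T1": 50, "T2": 50})
        pairs = select_major_minor(matrix)
        assert pairs.iloc[0]["major_tss"] == "T2"  # minus strand: larger start upstream
        assert bool(pairs.iloc[0]["major_is_upstream"])

    def test_distance_symmetric_in_pair_order(self):
        tss = _tss(
            [("g", "T1", "chr1", 700, 800, "+"), ("g", "T2", "chr1", 100, 200, "+")]
        )
        for counts in ({"T1": 9, "T2": 5}, {"T1": 5, "T2": 9}):
            pairs = select_major_minor(_matrix(tss, counts))
            assert pairs.iloc[0]["edge_distance"] == 500


class TestExpressionGates:
    def _matrix_n_cells(self, totals: dict, n_cells: int):
        idx = pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id")
        tss = _tss(
            [("g", t, "chr1", 100 + 700 * i, 200 + 700 * i, "+")
             for i, t in enumerate(totals)]
        )
        mat = pd.DataFrame(0, index=idx, columns=list(totals))
        for t, total in totals.items():
            mat[t] = total // n_cells
            mat.iloc[0, mat.columns.get_loc(t)] += total % n_cells
        types = pd.Series(["typeA"] * n_cells, index=idx, name="cell_type")
        return TssCountMatrix(counts=mat, cell_types=types, tss=tss)

    def test_total_gate_inclusive_boundary(self):
        m = self._matrix_n_cells({"T1": 100, "T2": 99}, 10)
        assert expression_gate_tss(m, min_total=100) == ["T1"]

    def test_pair_gate_boundary_inclusive(self):
        m = self._matrix_n_cells({"T1": 40, "T2": 20}, 100)
        pairs = select_major_minor(m)
        gated = expression_gate_pairs(m, pairs, min_per_cell=0.3)
        assert len(gated) == 1  # (40+20)/(2*100) = 0.3 >= 0.3
        gated = expression_gate_pairs(m, pairs, min_per_cell=0.31)
        assert gated.empty

    def test_empty_matrix_empty_gate(self):
        tss = _tss([])
        idx = pd.Index([], name="cell_id")
        m = TssCountMatrix(
            counts=pd.DataFrame(index=idx),
            cell_types=pd.Series(dtype=object),
            tss=tss,
        )
        assert expression_gate_tss(m, 100) == []
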