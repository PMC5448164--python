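"""UMI collapsing, TSS curation, molecule assignment and QC profiles."""
import numpy as np
import pandas as pd
import pytest

from alttss.config import SimConfig
from alttss.quantify import (
    assign_molecules,
    classify_reads,
    collapse_umis,
    curate_tss,
    gene_body_profile,
    spikein_deviation_profile,
    tss_vicinity_profile,
)
from alttss.synthetic import simulate_dataset

from conftest import make_molecules


def _reads(rows):
    return pd.DataFrame(rows, columns=["cell", "chrom", "pos0", "strand", "umi"])


class TestCollapseUmis:
    def test_grouping_and_singleton_removal(self):
        reads = _reads(
            [("cellA", "chr1", 100, "+", "AAAAAA")] * 3
            + [("cellA", "chr1", 100, "+", "CCCCCC")]          # singleton: dropped
            + [("cellA", "chr1", 101, "+", "AAAAAA")] * 2      # position differs
            + [("cellB", "chr1", 100, "+", "AAAAAA")] * 2      # cell differs
            + [("cellA", "chr1", 100, "-", "AAAAAA")] * 2      # strand differs
        )
        mol = collapse_umis(reads)
        assert len(mol) == 4
        key = mol.set_index(["cell_id", "chrom", "strand", "pos5", "umi"])["n_reads"]
        assert key[("cellA", "chr1", "+", 100, "AAAAAA")] == 3
        assert ("cellA", "chr1", "+", 100, "CCCCCC") not in key.index

    def test_exhaustive_grouping_key(self):
        """Molecule count equals the number of distinct 5-field keys with >=2 reads."""
        rng = np.random.default_rng(0)
        cells = rng.choice(["a", "b"], 200)
        pos = rng.integers(100, 104, 200)
        umis = rng.choice(["AAAAAA", "CCCCCC"], 200)
        reads = _reads(list(zip(cells, ["chr1"] * 200, pos, ["+"] * 200, umis)))
        expected = sum(
            1
            for _, grp in reads.groupby(["cell", "chrom", "strand", "pos0", "umi"])
            if len(grp) >= 2
        )
        assert len(collapse_umis(reads)) == expected

    def test_order_invariance(self):
        reads = _reads(
            [("a", "chr1", p, "+", u) for p in (5, 6) for u in ("AAAAAA", "TTTTTT")] * 2
        )
        shuffled = reads.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(collapse_umis(reads), collapse_umis(shuffled))

    def test_malformed_umi_rejected_not_crashed(self):
        reads = _reads(
            [("a", "chr1", 1, "+", "AAAAAA")] * 2 + [("a", "chr1", 1, "+", "AANXAA")] * 2
        )
        mol = collapse_umis(reads)
        assert len(mol) == 1 and mol.iloc[0]["umi"] == "AAAAAA"

    def test_empty_input(self):
        assert len(collapse_umis(_reads([]))) == 0


class TestCurateTss:
    @staticmethod
    def _raw(rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "tss_id", "chrom", "start", "end", "strand"]
        )

    def test_longer_interval_trimmed_to_one_bp_gap(self):
        raw = self._raw(
            [("g", "A", "chr1", 100, 200, "+"), ("g", "B", "chr1", 150, 300, "+")]
        )
        cur = curate_tss(raw).set_index("tss_id")
        assert (cur.loc["A", "start"], cur.loc["A", "end"]) == (100, 200)
        assert (cur.loc["B", "start"], cur.loc["B", "end"]) == (201, 300)

    def test_no_overlap_identity_and_geneless_dropped(self):
        raw = self._raw(
            [("g1", "A", "chr1", 100, 200, "+"), ("g2", "B", "chr1", 400, 500, "+"),
             ("", "C", "chr1", 600, 700, "+")]
        )
        cur = curate_tss(raw)
        assert list(cur["tss_id"]) == ["A", "B"]
        assert cur.set_index("tss_id").loc["A", "end"] == 200

    def test_equal_length_tie_trims_downstream(self):
        raw = self._raw(
            [("g", "A", "chr1", 100, 200, "+"), ("g", "B", "chr1", 150, 250, "+")]
        )
        cur = curate_tss(raw).set_index("tss_id")
        assert (cur.loc["A", "start"], cur.loc["A", "end"]) == (100, 200)
        assert (cur.loc["B", "start"], cur.loc["B", "end"]) == (201, 250)

    def test_strictly_nested_drops_the_longer(self):
        raw = self._raw(
            [("g", "A", "chr1", 100, 400, "+"), ("g", "B", "chr1", 200, 250, "+")]
        )
        cur = curate_tss(raw)
        assert list(cur["tss_id"]) == ["B"]

    def test_output_disjoint_with_gap(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 2000, 40)
        raw = self._raw(
            [("g", f"T{i}", "chr1", int(s), int(s + rng.integers(20, 200)), "+")
             for i, s in enumerate(starts)]
        )
        cur = curate_tss(raw).sort_values("start")
        assert (cur["start"].to_numpy()[1:] >= cur["end"].to_numpy()[:-1] + 1).all()

    def test_different_strands_do_not_interact(self):
        raw = self._raw(
            [("g1", "A", "chr1", 100, 200, "+"), ("g2", "B", "chr1", 150, 300, "-")]
        )
        cur = curate_tss(raw).set_index("tss_id")
        assert cur.loc["B", "start"] == 150  # untouched

    def test_center_is_floor_midpoint(self):
        raw = self._raw([("g", "A", "chr1", 100, 161, "+")])
        assert curate_tss(raw).iloc[0]["center"] == 130


class TestAssignMolecules:
    def _types(self, cells=("c1",)):
        return pd.Series(["typeA"] * len(cells), index=list(cells), name="cell_type")

    def test_containment_boundary_and_strand(self, toy_tss):
        mol = make_molecules(
            [("c1", "chr1", "+", 150),   # inside gA:T0
             ("c1", "chr1", "+", 200),   # half-open: outside
             ("c1", "chr1", "-", 150),   # antisense: outside
             ("c1", "chr1", "-", 5050)]  # inside gB:T0 (minus strand)
        )
        matrix, side = assign_molecules(mol, toy_tss, self._types())
        assert matrix.counts.loc["c1", "gA:T0"] == 1
        assert matrix.counts.loc["c1", "gB:T0"] == 1
        assert len(side) == 2
        assert matrix.counts.to_numpy().sum() + len(side) == len(mol)

    def test_all_cells_present_even_without_molecules(self, toy_tss):
        mol = make_molecules([("c1", "chr1", "+", 150)])
        matrix, _ = assign_molecules(mol, toy_tss, self._types(("c1", "c2")))
        assert list(matrix.counts.index) == ["c1", "c2"]
        assert matrix.counts.loc["c2"].sum() == 0


class TestClassifyReads:
    def _genes(self):
        return pd.DataFrame(
            [{"gene_id": "gA", "chrom": "chr1", "start": 0, "end": 1000,
              "strand": "+", "exon_starts": "0,800", "exon_sizes": "200,200"}]
        )

    def test_priority_tss_over_exon(self, toy_tss):
        tss = toy_tss.iloc[[0]]  # [100,200) inside gA exon 1
        mol = make_molecules(
            [("c", "chr1", "+", 150),  # tss
             ("c", "chr1", "+", 50),   # exonic
             ("c", "chr1", "+", 500),  # intronic
             ("c", "chr1", "+", 5000)]  # outside gene
        )
        out = classify_reads(mol, self._genes(), tss).set_index("category")
        assert out.loc["tss", "n_molecules"] == 1
        assert out.loc["exonic", "n_molecules"] == 1
        assert out.loc["intronic", "n_molecules"] == 1
        assert out.loc["outside", "n_molecules"] == 1
        assert out["n_molecules"].sum() == len(mol)

    def test_all_outside(self, toy_tss):
        mol = make_molecules([("c", "chr9", "+", 10)] * 3)
        out = classify_reads(mol, self._genes(), toy_tss).set_index("category")
        assert out.loc["outside", "fraction"] == 1.0

    def test_zero_noise_synthetic_molecules_all_tss(self):
        cfg = SimConfig(n_genes=10, n_cells=25, scatter_sd=0.0, background_rate=0.0,
                        spikein_mean=0.0, seed=13)
        ann, _, reads = simulate_dataset(cfg)
        mol = collapse_umis(reads)
        cur = curate_tss(ann.tss)
        out = classify_reads(mol, ann.genes, cur).set_index("category")
        assert out.loc["tss", "fraction"] == 1.0


class TestSpikeinProfile:
    def test_hand_computed_offsets(self):
        spikes = pd.DataFrame(
            [{"spike_id": "S1", "length": 500, "chrom": "ercc", "start": 0}]
        )
        mol = make_molecules(
            [("c", "ercc", "+", 100)] * 3 + [("c", "ercc", "+", 105)]
        )
        prof = spikein_deviation_profile(mol, spikes).set_index("offset")
        assert prof.loc[0, "n_molecules"] == 3
        assert prof.loc[0, "percent_of_exact"] == 100.0
        assert prof.loc[5, "percent_of_exact"] == pytest.approx(100 / 3)

    def test_zero_scatter_all_mass_at_zero(self):
        spikes = pd.DataFrame(
            [{"spike_id": "S1", "length": 300, "chrom": "ercc", "start": 50}]
        )
        mol = make_molecules([("c", "ercc", "+", 50)] * 5)
        prof = spikein_deviation_profile(mol, spikes)
        assert list(prof["offset"]) == [0]

    def test_empty_spikein_omitted(self):
        spikes = pd.DataFrame(
            [{"spike_id": "S1", "length": 300, "chrom": "ercc", "start": 0},
             {"spike_id": "S2", "length": 300, "chrom": "ercc", "start": 1000}]
        )
        mol = make_molecules([("c", "ercc", "+", 10)] * 4)
        prof = spikein_deviation_profile(mol, spikes)
        assert prof["n_molecules"].sum() == 4


class TestVicinityProfile:
    def test_plus_strand_center_offset_zero(self, toy_tss):
        mol = make_molecules([("c", "chr1", "+", 150)])
        prof, within50 = tss_vicinity_profile(mol, toy_tss)
        assert list(prof["offset"]) == [0]
        assert within50 == 1.0

    def test_minus_strand_left_is_downstream(self, toy_tss):
        # gB:T0 = [5000,5100) minus strand, center 5050; 10 bp left -> +10
        mol = make_molecules([("c", "chr1", "-", 5040)])
        prof, _ = tss_vicinity_profile(mol, toy_tss)
        assert list(prof["offset"]) == [10]

    def test_zero_scatter_synthetic_within50_is_one(self):
        cfg = SimConfig(n_genes=10, n_cells=25, scatter_sd=0.0, background_rate=0.0,
                        spikein_mean=0.0, seed=13)
        ann, _, reads = simulate_dataset(cfg)
        mol = collapse_umis(reads)
        _, within50 = tss_vicinity_profile(mol, curate_tss(ann.tss))
        assert within50 == 1.0


class TestGeneBodyProfile:
    def _genes(self):
        return pd.DataFrame(
            [{"gene_id": "gP", "chrom": "chr1", "start": 0, "end": 2000, "strand": "+",
              "exon_starts": "0", "exon_sizes": "2000"},
             {"gene_id": "gM", "chrom": "chr2", "start": 0, "end": 2000, "strand": "-",
              "exon_starts": "0", "exon_sizes": "2000"}]
        )

    def test_five_prime_molecules_land_in_bin_one(self):
        mol = make_molecules(
            [("c", "chr1", "+", 10)] * 3 + [("c", "chr2", "-", 1990)] * 3
        )
        prof = gene_body_profile(mol, self._genes())
        assert prof.set_index("bin").loc[1, "percent"] == 100.0

    def test_uniform_background_is_flat(self):
        rng = np.random.default_rng(2)
        mol = make_molecules(
            [("c", "chr1", "+", int(p)) for p in rng.integers(0, 2000, 4000)]
        )
        prof = gene_body_profile(mol, self._genes())
        assert prof["percent"].sum() == pytest.approx(100.0)
        assert np.allclose(prof["percent"], 5.0, atol=1.5)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no molecules"):
            gene_body_profile(make_molecules([]), self._genes())

    def test_short_gene_excluded(self):
        genes = pd.concat(
            [self._genes(),
             pd.DataFrame([{"gene_id": "tiny", "chrom": "chr3", "start": 0, "end": 10,
                            "strand": "+", "exon_starts": "0", "exon_sizes": "10"}])],
            ignore_index=True,
        )
        mol = make_molecules([("c", "chr1", "+", 10)] * 2 + [("c", "chr3", "+", 5)])
        prof = gene_body_profile(mol, genes)
        assert prof["n_molecules"].sum() == 2
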