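"""Per-gene scoring, sextile binning, selection comparison, supermatrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import nrcfv as nv
from nrcfv.alphabets import MISSING

from conftest import make_random_alignment


def metrics_table(values, lengths=None):
    """Minimal GeneMetricsTable for binning tests."""
    genes = [f"g{i:03d}" for i in range(len(values))]
    lengths = lengths or [100] * len(values)
    return pd.DataFrame(
        {
            "gene": genes,
            "n_taxa": 10,
            "length": lengths,
            "n_states": 4,
            "rcfv": values,
            "nrcfv": values,
        }
    )


class TestScorePartitions:
    def test_homogeneous_gene_scores_near_zero(self):
        genes = nv.simulate_graded_genes(3, n_taxa=15, lengths=800, seed=1)
        tbl = nv.score_partitions(genes[:1])  # gene 0 has zero skew weight
        assert (tbl.rcfv < 0.1).all()
        assert (tbl.nrcfv < 0.005).all()

    def test_column_duplication_shifts_nrcfv_by_sqrt2(self):
        aln = make_random_alignment(seed=6, skew=1.0)
        doubled = nv.Alignment(
            list(aln.taxa),
            np.concatenate([aln.codes, aln.codes], axis=1),
            aln.alphabet,
        )
        tbl = nv.score_partitions([("a", aln), ("b", doubled)])
        assert tbl.rcfv[0] == pytest.approx(tbl.rcfv[1], abs=1e-12)
        assert tbl.nrcfv[1] == pytest.approx(
            tbl.nrcfv[0] * np.sqrt(2), rel=1e-12
        )

    def test_taxa_without_data_excluded_from_gene_n(self):
        codes = np.zeros((3, 10), dtype=np.uint8)
        codes[2] = MISSING
        aln = nv.Alignment(["a", "b", "void"], codes, nv.DNA)
        tbl = nv.score_partitions([("g", aln)])
        assert tbl.n_taxa[0] == 2

    def test_gradient_recovered_in_rank_order(self):
        genes = nv.simulate_graded_genes(
            30, n_taxa=20, lengths=1500, seed=3, max_skew=0.6
        )
        tbl = nv.score_partitions(genes)
        rho = spearmanr(np.arange(30), tbl.nrcfv).statistic
        assert rho > 0.95

    def test_empty_and_duplicate_inputs(self):
        with pytest.raises(ValueError):
            nv.score_partitions([])
        aln = make_random_alignment(seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            nv.score_partitions([("g", aln), ("g", aln)])


class TestAssignQuantiles:
    def test_twelve_genes_six_bins_of_two(self):
        a = nv.assign_quantiles(metrics_table(list(range(12))), "nrcfv", k=6)
        assert a.bin_sizes == [2] * 6
        assert a.bins["g000"] == 1 and a.bins["g011"] == 6

    def test_638_genes_remainder_to_earliest_bins(self):
        rng = np.random.default_rng(0)
        a = nv.assign_quantiles(metrics_table(rng.random(638)), "nrcfv", k=6)
        assert a.bin_sizes == [107, 107, 106, 106, 106, 106]

    def test_ascending_by_metric(self):
        values = [0.5, 0.1, 0.9, 0.3, 0.7, 0.2]
        a = nv.assign_quantiles(metrics_table(values), "nrcfv", k=3)
        # sorted genes: g001(.1) g005(.2) | g003(.3) g000(.5) | g004(.7) g002(.9)
        assert a.bins == {
            "g001": 1, "g005": 1, "g003": 2, "g000": 2, "g004": 3, "g002": 3,
        }

    def test_ties_broken_by_gene_name(self):
        a = nv.assign_quantiles(metrics_table([0.4] * 6), "nrcfv", k=3)
        assert a.bins == {
            "g000": 1, "g001": 1, "g002": 2, "g003": 2, "g004": 3, "g005": 3,
        }

    def test_invalid_k(self):
        tbl = metrics_table([1, 2, 3])
        with pytest.raises(ValueError):
            nv.assign_quantiles(tbl, "nrcfv", k=0)
        with pytest.raises(ValueError):
            nv.assign_quantiles(tbl, "nrcfv", k=4)


class TestCompareSelections:
    def test_identical_assignments_share_everything(self):
        tbl = metrics_table(list(range(12)))
        a = nv.assign_quantiles(tbl, "rcfv", k=6)
        b = nv.assign_quantiles(tbl, "nrcfv", k=6)
        cmp = nv.compare_selections(a, b, tbl)
        assert (cmp.table.pct_non_shared == 0).all()
        assert cmp.crosstab.to_numpy().sum() == 0

    def test_disjoint_bins_are_fully_non_shared(self):
        tbl = metrics_table(list(range(4)))
        a = nv.QuantileAssignment("rcfv", 2, {"g000": 1, "g001": 1, "g002": 2, "g003": 2}, [2, 2])
        b = nv.QuantileAssignment("nrcfv", 2, {"g002": 1, "g003": 1, "g000": 2, "g001": 2}, [2, 2])
        cmp = nv.compare_selections(a, b, tbl)
        assert (cmp.table.pct_non_shared == 100).all()

    def test_hand_built_permutation_counts(self):
        # 20 genes, 4 bins of 5 under both metrics; b moves exactly two
        # genes out of each of a's first two bins.
        genes = [f"g{i:03d}" for i in range(20)]
        tbl = metrics_table(list(range(20)), lengths=[10 * (i + 1) for i in range(20)])
        a_bins = {g: i // 5 + 1 for i, g in enumerate(genes)}
        b_bins = dict(a_bins)
        # swap g000,g001 (a-bin 1) with g005,g006 (a-bin 2)
        b_bins["g000"], b_bins["g005"] = 2, 1
        b_bins["g001"], b_bins["g006"] = 2, 1
        a = nv.QuantileAssignment("rcfv", 4, a_bins, [5] * 4)
        b = nv.QuantileAssignment("nrcfv", 4, b_bins, [5] * 4)
        cmp = nv.compare_selections(a, b, tbl)
        assert cmp.table.pct_non_shared.tolist() == [40.0, 40.0, 0.0, 0.0]
        # hand-counted lengths: a-bin1 = genes 0..4 -> 10+20+30+40+50
        assert cmp.table.length_rcfv.tolist()[0] == 150
        # b-bin1 = {g002,g003,g004,g005,g006} -> 30+40+50+60+70
        assert cmp.table.length_nrcfv.tolist()[0] == 250
        # non-shared of b-bin1 (g005,g006) sit in a-bin2
        assert cmp.crosstab.loc["nrcfv_bin_1", "rcfv_bin_2"] == 2

    def test_equal_bin_sizes_make_non_shared_symmetric(self):
        rng = np.random.default_rng(4)
        tbl = metrics_table(rng.random(24).tolist())
        tbl["rcfv"] = rng.random(24)
        a = nv.assign_quantiles(tbl, "rcfv", k=6)
        b = nv.assign_quantiles(tbl, "nrcfv", k=6)
        ab = nv.compare_selections(a, b, tbl).table.non_shared
        ba = nv.compare_selections(b, a, tbl).table.non_shared
        assert ab.tolist() == ba.tolist()

    def test_mismatched_gene_sets_raise(self):
        tbl = metrics_table([1, 2])
        a = nv.QuantileAssignment("rcfv", 1, {"g000": 1, "g001": 1}, [2])
        b = nv.QuantileAssignment("nrcfv", 1, {"g000": 1, "gX": 1}, [2])
        with pytest.raises(ValueError):
            nv.compare_selections(a, b, tbl)


@pytest.fixture(scope="module")
def genes():
    return nv.simulate_graded_genes(
        12, n_taxa=8, lengths=[40 + 10 * i for i in range(12)], seed=5
    )


class TestCumulativeDataset:

    def test_full_concatenation_length(self, genes):
        tbl = nv.score_partitions(genes)
        a = nv.assign_quantiles(tbl, "nrcfv", k=6)
        sm, bounds = nv.cumulative_dataset(a, genes, upto=6)
        assert sm.n_columns == sum(aln.n_columns for _, aln in genes)
        assert len(bounds) == 12
        assert bounds.end.iloc[-1] == sm.n_columns

    def test_absent_taxon_padded_with_missing(self, genes):
        # drop one taxon from one gene entirely
        name0, g0 = genes[0]
        reduced = nv.Alignment(g0.taxa[1:], g0.codes[1:], g0.alphabet)
        modified = [(name0, reduced)] + list(genes[1:])
        tbl = nv.score_partitions(modified)
        a = nv.assign_quantiles(tbl, "nrcfv", k=3)
        sm, bounds = nv.cumulative_dataset(a, modified, upto=3)
        row = sm.taxa.index(g0.taxa[0])
        b = bounds[bounds.gene == name0].iloc[0]
        assert (sm.codes[row, b.start - 1:b.end] == MISSING).all()

    def test_per_taxon_nonmissing_counts_conserved(self, genes):
        tbl = nv.score_partitions(genes)
        a = nv.assign_quantiles(tbl, "nrcfv", k=4)
        sm, _ = nv.cumulative_dataset(a, genes, upto=2)
        members = {g for g, b in a.bins.items() if b <= 2}
        expected = sum(
            (aln.codes != MISSING).sum(axis=1)
            for name, aln in genes
            if name in members
        )
        got = (sm.codes != MISSING).sum(axis=1)
        np.testing.assert_array_equal(got, expected)

    def test_single_bin_case(self, genes):
        tbl = nv.score_partitions(genes)
        a = nv.assign_quantiles(tbl, "nrcfv", k=6)
        sm, bounds = nv.cumulative_dataset(a, genes, upto=1)
        assert set(bounds.gene) == a.members(1)


class TestPartitionFiles:
    def test_raxml_style_round_trip(self, tmp_path):
        f = tmp_path / "parts.txt"
        f.write_text("GENE1 = 1-6\nDNA, GENE2 = 7-10\nGENE3 = 11-12, 15-16\n")
        parts = nv.read_partition_file(f)
        assert parts == [
            ("GENE1", [(1, 6)]),
            ("GENE2", [(7, 10)]),
            ("GENE3", [(11, 12), (15, 16)]),
        ]

    def test_split_supermatrix_columns(self):
        aln = make_random_alignment(seed=12, n_taxa=4, n_columns=16)
        genes = nv.split_supermatrix(aln, [("a", [(1, 6)]), ("b", [(7, 16)])])
        assert genes[0][1].n_columns == 6
        assert genes[1][1].n_columns == 10
        np.testing.assert_array_equal(genes[0][1].codes, aln.codes[:, :6])

    def test_out_of_range_partition_raises(self):
        aln = make_random_alignment(seed=12, n_taxa=4, n_columns=16)
        with pytest.raises(nv.AlignmentError):
            nv.split_supermatrix(aln, [("a", [(1, 20)])])

    def test_bad_partition_line_raises(self, tmp_path):
        f = tmp_path / "parts.txt"
        f.write_text("GENE1 : 1-6\n")
        with pytest.raises(nv.AlignmentError):
            nv.read_partition_file(f)

    def test_gene_directory_roundtrip(self, tmp_path):
        genes = nv.simulate_graded_genes(4, n_taxa=5, lengths=30, seed=9)
        for name, aln in genes:
            nv.write_alignment(aln, tmp_path / f"{name}.fasta", "fasta")
        back = nv.read_gene_directory(tmp_path, alphabet=nv.DNA)
        assert [n for n, _ in back] == [n for n, _ in genes]
        for (_, a), (_, b) in zip(back, genes):
            assert (a.codes == b.codes).all()
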