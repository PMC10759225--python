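"""Dataset construction: loading, cleaning, dedup, splits, augmentation."""

import numpy as np
import pytest

import tcrbind as tb
from tcrbind.dataset_io import FormatError


def _ds(triplets, label=1):
    return tb.InteractionDataset(
        [tb.InteractionRecord(a, b, p, lab if (lab := label) is not None else 1)
         for a, b, p in triplets])


class TestLoad:
    def test_plain_tsv_identity_read(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("cdr3a\tcdr3b\tpeptide\tlabel\n"
                     "CAV\tCAS\tGIL\t1\nCAK\tCAT\tNLV\t0\nCAR\tCAW\tGLC\t1\n")
        ds = tb.load_interactions(p, "plain_tsv")
        assert len(ds) == 3
        assert ds[0].cdr3a == "CAV" and ds[2].label == 1

    def test_ergo_header_mapping(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("CDR3α,CDR3β,Peptide,Sign\nCAV,CAS,GIL,1\n")
        ds = tb.load_interactions(p, "ergo_csv")
        assert ds[0].cdr3b == "CAS" and ds[0].cdr3a == "CAV"

    def test_non_binary_label_is_an_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("cdr3a\tcdr3b\tpeptide\tlabel\nCAV\tCAS\tGIL\tyes\n")
        with pytest.raises(FormatError, match="label"):
            tb.load_interactions(p, "plain_tsv")

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("cdr3a\tpeptide\tlabel\nCAV\tGIL\t1\n")
        with pytest.raises(FormatError, match="cdr3b"):
            tb.load_interactions(p, "plain_tsv")


class TestClean:
    def test_drops_records_missing_chains(self):
        ds = tb.InteractionDataset([
            tb.InteractionRecord("", "CAS", "GIL", 1),
            tb.InteractionRecord("CAV", "CAS", "GIL", 1),
            tb.InteractionRecord("", "CAT", "NLV", 0),
            tb.InteractionRecord("CAK", "CAT", "NLV", 0),
            tb.InteractionRecord("CAR", "CAW", "GLC", 1),
        ])
        assert len(tb.clean(ds)) == 3

    def test_standard_peptide_kept_verbatim(self):
        ds = tb.InteractionDataset(
            [tb.InteractionRecord("CAV", "CAS", "GILGFVFTL", 1)])
        out = tb.clean(ds)
        assert out[0].peptide == "GILGFVFTL"

    @pytest.mark.parametrize("bad", ["GXL", "GBL", "GZL", "G L", "gil"])
    def test_nonstandard_residues_dropped(self, bad):
        ds = tb.InteractionDataset([tb.InteractionRecord("CAV", "CAS", bad, 1)])
        assert len(tb.clean(ds)) == 0


class TestDedup:
    def test_exact_duplicates_collapse(self):
        ds = _ds([("A", "B", "P"), ("A", "B", "P"), ("A", "B", "Q")])
        assert len(tb.dedup_triplets(ds)) == 2

    def test_conflicting_labels_keep_first_and_warn(self):
        ds = tb.InteractionDataset([tb.InteractionRecord("A", "B", "P", 1),
                                    tb.InteractionRecord("A", "B", "P", 0)])
        with pytest.warns(UserWarning, match="conflicting"):
            out = tb.dedup_triplets(ds)
        assert len(out) == 1 and out[0].label == 1

    def test_noop_on_unique_input_and_idempotent(self):
        rng = np.random.default_rng(0)
        trips = {tuple("".join(tb.AMINO_ACIDS[i] for i in rng.integers(0, 20, 5))
                       for _ in range(3)) for _ in range(120)}
        ds = _ds(sorted(trips)[:100])
        once = tb.dedup_triplets(ds)
        assert len(once) == len(ds)
        assert [r.triplet for r in tb.dedup_triplets(once)] == \
               [r.triplet for r in once]


class TestOverlapRemoval:
    def test_identical_triplet_removed_shared_peptide_retained(self):
        train = _ds([("A", "B", "P"), ("C", "D", "Q")])
        test = _ds([("A", "B", "P"), ("E", "F", "P"), ("A", "B", "R")])
        out = tb.remove_test_overlap(train, test)
        # full triplet (A,B,P) removed; peptide-only and CDR-only overlaps stay
        assert [r.triplet for r in out] == [("E", "F", "P"), ("A", "B", "R")]
        assert not (train.triplets() & out.triplets())

    def test_disjoint_sets_unchanged(self):
        train, test = _ds([("A", "B", "P")]), _ds([("C", "D", "Q")])
        assert len(tb.remove_test_overlap(train, test)) == 1


class TestSampleNegatives:
    def test_ratio_five_gives_one_sixth_positive_rate(self):
        ds = _ds([(f"A{i}", f"B{i}", f"P{i}") for i in range(6)])
        out = tb.sample_negatives(ds, ratio=5, seed=0)
        assert len(out) == 36
        assert out.positive_rate == pytest.approx(1 / 6)
        # no generated negative duplicates a positive or another negative
        assert len(out.triplets()) == 36

    def test_degenerate_space_errors(self):
        ds = _ds([("A", "B", "P")])
        with pytest.raises(ValueError, match="shortfall"):
            tb.sample_negatives(ds, ratio=5, seed=0)

    def test_deterministic_under_seed(self):
        ds = _ds([(f"A{i}", f"B{i}", f"P{i}") for i in range(6)])
        a = tb.sample_negatives(ds, 5, seed=42)
        b = tb.sample_negatives(ds, 5, seed=42)
        assert [r.triplet for r in a] == [r.triplet for r in b]

    @pytest.mark.parametrize("ratio", [1, 2, 5])
    def test_positive_fraction_exact(self, ratio):
        ds = _ds([(f"A{i}", f"B{i}", f"P{i}") for i in range(8)])
        out = tb.sample_negatives(ds, ratio, seed=1)
        assert out.positive_rate == pytest.approx(1 / (1 + ratio))

    def test_rejects_nonpositive_input(self):
        ds = tb.InteractionDataset([tb.InteractionRecord("A", "B", "P", 0)])
        with pytest.raises(ValueError, match="all-positive"):
            tb.sample_negatives(ds, 5, seed=0)


class TestOverlapReport:
    def test_unique_counts_by_hand(self):
        ds = _ds([("A", "B", "P"), ("A", "B", "Q"), ("C", "D", "P")])
        rep = tb.overlap_report(ds)
        assert (rep.unique_cdr3ab_count, rep.unique_peptide_count,
                rep.interaction_count) == (2, 2, 3)

    def test_disjoint_train_gives_zero_dups(self):
        ds = _ds([("A", "B", "P")])
        train = _ds([("C", "D", "Q")])
        rep = tb.overlap_report(ds, train)
        assert rep.dup_cdr3ab_with_train == 0
        assert rep.records_with_seen_peptide == 0

    def test_self_train_marks_all_records_seen(self):
        ds = _ds([("A", "B", "P"), ("C", "D", "Q")])
        rep = tb.overlap_report(ds, ds)
        assert rep.records_with_seen_peptide == len(ds)
        assert rep.records_with_seen_cdr3ab == len(ds)

    def test_seen_unseen_partition_sums(self):
        ds = _ds([("A", "B", "P"), ("C", "D", "Q"), ("E", "F", "P")])
        train = _ds([("A", "B", "Z"), ("X", "Y", "P")])
        rep = tb.overlap_report(ds, train)
        unseen_pep = sum(r.peptide not in {t.peptide for t in train.records}
                         for r in ds.records)
        assert rep.records_with_seen_peptide + unseen_pep == rep.interaction_count


class TestWindows:
    def test_window_counts(self):
        assert len(tb.window_peptides("A" * 10, k=9, stride=1)) == 2
        assert tb.window_peptides("GILGFVFTL", k=9) == ["GILGFVFTL"]

    def test_spike_length_window_count(self):
        # a 1,273-residue protein yields 1,265 nine-mers at stride 1
        protein = "".join(tb.AMINO_ACIDS[i % 20] for i in range(1273))
        assert len(tb.window_peptides(protein, k=9, stride=1)) == 1265

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            tb.window_peptides("GIL", k=9)


class TestAllVsAll:
    def test_small_product_with_one_positive(self):
        ds = tb.all_vs_all([("A", "B"), ("C", "D")], ["P", "Q", "R"],
                           positives={("A", "B", "P")})
        assert len(ds) == 6
        assert int(ds.labels.sum()) == 1

    def test_counts_without_materializing(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(1676)]
        peps = [f"P{i}" for i in range(1265)]
        c = tb.all_vs_all_counts(pairs, peps)
        assert c["total_records"] == 2_120_140

    def test_positive_element_negatives_arithmetic(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(10)]
        peps = [f"P{i}" for i in range(24)]
        positives = {(f"A{i % 10}", f"B{i % 10}", f"P{i % 24}") for i in range(40)}
        assert len(positives) == 40
        c = tb.all_vs_all_counts(pairs, peps, positives)
        assert c["n_negative"] == 200  # 10*24 - 40

    def test_absent_element_errors(self):
        with pytest.raises(ValueError, match="absent"):
            tb.all_vs_all([("A", "B")], ["P"], positives={("X", "Y", "P")})

    @pytest.mark.parametrize("n,m", [(1, 1), (3, 5), (7, 2)])
    def test_record_count_is_product(self, n, m):
        ds = tb.all_vs_all([(f"A{i}", f"B{i}") for i in range(n)],
                           [f"P{j}" for j in range(m)])
        assert len(ds) == n * m
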