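"""Alignment reading, haplotype collapsing and count reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapstruct.dataio import (
    Alignment,
    CountTable,
    DataError,
    FrequencyTable,
    HaplotypeCatalog,
    SampleRecord,
    collapse_haplotypes,
    counts_from_frequencies,
    expand_counts,
    polymorphic_site_table,
    read_alignment,
    read_count_table,
    read_frequency_table,
    read_haplotype_fasta,
    write_count_table,
    write_frequency_table,
    write_haplotype_fasta,
)
from hapstruct.synthetic import load_spinner_frequency_table, spinner_count_table


class TestReadAlignment:
    def test_round_trip(self, tmp_path, tiny_alignment):
        fasta = tmp_path / "a.fasta"
        popmap = tmp_path / "a.popmap"
        fasta.write_text(
            "".join(f">{r.sample_id}\n{r.sequence}\n" for r in tiny_alignment.records)
        )
        popmap.write_text(
            "".join(f"{r.sample_id}\t{r.population}\n" for r in tiny_alignment.records)
        )
        aln = read_alignment(fasta, popmap)
        assert aln.L == 10
        assert len(aln) == 4
        assert aln.populations == ["north", "south"]
        assert [r.sequence for r in aln.records] == [
            r.sequence for r in tiny_alignment.records
        ]

    def test_length_mismatch_names_offender(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        popmap = tmp_path / "a.popmap"
        fasta.write_text(">s1\nACGTACGTA\n>s2\nACGTACGTAC\n>s3\nACGTACGTAC\n")
        popmap.write_text("s1\tp\ns2\tp\ns3\tp\n")
        with pytest.raises(DataError, match="s2"):
            read_alignment(fasta, popmap)

    def test_missing_popmap_entry(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        popmap = tmp_path / "a.popmap"
        fasta.write_text(">s1\nACGT\n>s2\nACGT\n")
        popmap.write_text("s1\tp\n")
        with pytest.raises(DataError, match="s2"):
            read_alignment(fasta, popmap)

    def test_duplicate_id(self):
        with pytest.raises(DataError, match="duplicate"):
            Alignment(
                [SampleRecord("x", "p", "ACGT"), SampleRecord("x", "p", "ACGT")]
            )


class TestCollapse:
    def test_single_haplotype(self):
        aln = Alignment([SampleRecord(f"s{i}", "p", "ACGTT") for i in range(5)])
        cat, ct = collapse_haplotypes(aln)
        assert cat.ids == ["SP1"]
        assert ct.counts.tolist() == [[5]]

    def test_frequency_ordering(self):
        aln = Alignment(
            [
                SampleRecord("s1", "p", "AAAA"),
                SampleRecord("s2", "p", "AAAT"),
                SampleRecord("s3", "p", "AAAT"),
            ]
        )
        cat, ct = collapse_haplotypes(aln)
        assert cat.entries["SP1"] == "AAAT"  # more frequent wins SP1
        assert ct.to_frame()["p"].tolist() == [2, 1]

    def test_tie_broken_by_first_occurrence(self):
        aln = Alignment(
            [
                SampleRecord("s1", "p", "AAAT"),
                SampleRecord("s2", "p", "AAAA"),
            ]
        )
        cat, _ = collapse_haplotypes(aln)
        assert cat.entries["SP1"] == "AAAT"

    def test_strict_vs_pairwise_ignore(self):
        aln = Alignment(
            [
                SampleRecord("s1", "p", "ACGT"),
                SampleRecord("s2", "p", "ACGN"),
            ]
        )
        cat_strict, _ = collapse_haplotypes(aln, "strict")
        cat_merge, _ = collapse_haplotypes(aln, "pairwise_ignore")
        assert len(cat_strict.ids) == 2
        assert len(cat_merge.ids) == 1

    def test_collapse_expand_idempotent(self, spinner):
        cat, ct = spinner
        cat2, ct2 = collapse_haplotypes(expand_counts(cat, ct))
        assert sorted(cat2.entries.values()) == sorted(cat.entries.values())
        assert ct2.counts.sum() == ct.counts.sum()
        cat3, ct3 = collapse_haplotypes(expand_counts(cat2, ct2))
        assert cat3.entries == cat2.entries
        assert np.array_equal(ct3.counts, ct2.counts)

    def test_total_count_preserved(self, tiny_alignment):
        _, ct = collapse_haplotypes(tiny_alignment)
        assert ct.counts.sum() == len(tiny_alignment)


class TestPolymorphicSites:
    @pytest.mark.parametrize(
        "seqs, expect_class, expect_pos",
        [
            (["ACGT", "ACGC"], "transition", 4),
            (["ACGT", "ACGA"], "transversion", 4),
        ],
    )
    def test_two_state(self, seqs, expect_class, expect_pos):
        cat = HaplotypeCatalog(dict(zip("ab", seqs)))
        table = polymorphic_site_table(cat)
        assert len(table) == 1
        assert table.iloc[0]["position"] == expect_pos
        assert table.iloc[0]["class"] == expect_class

    def test_multistate_pairs(self):
        # brute force over state pairs: {A,G,C} -> A/G ts, A/C tv, G/C tv
        cat = HaplotypeCatalog({"a": "AAAA", "b": "AAAG", "c": "AAAC"})
        table = polymorphic_site_table(cat)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["class"] == "multi-state"
        assert row["transitions"] == 1
        assert row["transversions"] == 2

    def test_monomorphic_catalog_empty_table(self):
        cat = HaplotypeCatalog({"a": "ACGT"})
        assert polymorphic_site_table(cat).empty

    def test_fixture_site_summary(self, spinner):
        cat, _ = spinner
        table = polymorphic_site_table(cat)
        assert len(table) == 41
        assert table["transitions"].sum() == 40
        assert table["transversions"].sum() == 1


class TestCountsFromFrequencies:
    def test_half_up_cell(self):
        # 0.625 * 208 = 130 exactly
        ft = FrequencyTable(["p"], ["h1", "h2"], np.array([[0.625], [0.375]]))
        ct = counts_from_frequencies(ft, [208])
        assert ct.counts[0, 0] == 130

    def test_zero_frequency(self):
        ft = FrequencyTable(["p"], ["h1", "h2"], np.array([[1.0], [0.0]]))
        ct = counts_from_frequencies(ft, [57])
        assert ct.counts[1, 0] == 0

    def test_row_sum_mismatch_raises(self):
        ft = FrequencyTable(["p"], ["h1", "h2"], np.array([[0.5], [0.5]]))
        with pytest.raises(DataError, match="p"):
            counts_from_frequencies(ft, [7])  # 3.5 rounds to 4 twice -> 8 != 7

    def test_corrections_override(self):
        ft = FrequencyTable(["p"], ["h1", "h2"], np.array([[0.5], [0.5]]))
        ct = counts_from_frequencies(ft, [7], corrections={("p", "h1"): 3})
        assert ct.counts[:, 0].tolist() == [3, 4]

    def test_published_table_reconstructs_exactly(self):
        ct = spinner_count_table()
        assert ct.n_per_pop.tolist() == [208, 63, 97, 62]
        nsw = ct.pop_counts("NSW")
        assert int((nsw > 0).sum()) == 23
        assert nsw.sum() == 208

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_frequency_round_trip(self, data):
        # full-precision frequencies of a count table recover it exactly
        n_hap = data.draw(st.integers(2, 8))
        n_pop = data.draw(st.integers(1, 4))
        counts = np.array(
            [
                [data.draw(st.integers(0, 30)) for _ in range(n_pop)]
                for _ in range(n_hap)
            ]
        )
        counts[0] += 1  # keep every population non-empty
        ct = CountTable(
            [f"p{j}" for j in range(n_pop)], [f"h{i}" for i in range(n_hap)], counts
        )
        back = counts_from_frequencies(ct.frequencies(), ct.n_per_pop)
        assert np.array_equal(back.counts, ct.counts)


class TestRoundTrips:
    def test_count_table_tsv(self, tmp_path, spinner):
        _, ct = spinner
        path = tmp_path / "counts.tsv"
        write_count_table(ct, path)
        back = read_count_table(path)
        assert back.populations == ct.populations
        assert np.array_equal(back.counts, ct.counts)

    def test_frequency_table_tsv(self, tmp_path):
        ft, n, _ = load_spinner_frequency_table()
        path = tmp_path / "freqs.tsv"
        write_frequency_table(ft, path)
        back = read_frequency_table(path)
        assert np.allclose(back.freqs, ft.freqs)
        assert back.to_frame().shape == (37, 4)

    def test_haplotype_fasta(self, tmp_path):
        cat = HaplotypeCatalog({"SP1": "ACGT", "SP2": "ACGA"})
        path = tmp_path / "h.fasta"
        write_haplotype_fasta(cat, path)
        assert read_haplotype_fasta(path).entries == cat.entries
        assert path.read_text().count(">") == 2
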