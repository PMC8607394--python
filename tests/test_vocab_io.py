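"""Residue pooling, allele-frequency binning, consensus, and table I/O."""

from __future__ import annotations

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twodcg import (
    AMINO_ALPHABET,
    CodeVocabulary,
    DomainEntry,
    DomainVocabulary,
    VocabularyError,
    bin_allele_frequency,
    load_6ddp,
    load_vocabularies,
    pool_substitution,
    resolve_annotations,
    write_6ddp,
)
from twodcg.vocab_io import POOLED_CLASSES, SIXDDP_COLUMNS

from .oracles import oracle_majority


class TestPooling:
    @pytest.mark.parametrize(
        "ref,sub,expected",
        [
            ("Arg", "Gly", ("K", "G")),
            ("Gly", "Gly", ("G", "G")),
            ("Ala", "Trp", ("L", "L")),
            ("His", "Lys", ("K", "K")),
            ("Asp", "Glu", ("E", "E")),
            ("Ser", "Thr", ("T", "T")),
            ("Asn", "Gln", ("Q", "Q")),
            ("Val", "Ile", ("L", "L")),
            ("R", "G", ("K", "G")),  # one-letter input
            ("*", "C", ("*", "C")),  # stop symbol is its own class
        ],
    )
    def test_pooling_map(self, ref, sub, expected):
        pooled = pool_substitution(ref, sub)
        assert (pooled.ref_class, pooled.sub_class) == expected

    def test_unknown_letter_named_in_error(self):
        with pytest.raises(VocabularyError, match="Xyz"):
            pool_substitution("Xyz", "Gly")

    @given(
        ref=st.sampled_from(AMINO_ALPHABET), sub=st.sampled_from(AMINO_ALPHABET)
    )
    @settings(deadline=None, derandomize=True)
    def test_idempotent_and_closed(self, ref, sub):
        once = pool_substitution(ref, sub)
        twice = pool_substitution(once.ref_class, once.sub_class)
        assert once == twice
        assert once.ref_class in POOLED_CLASSES
        assert once.sub_class in POOLED_CLASSES

    def test_pooled_alphabet_has_ten_classes(self):
        assert len(POOLED_CLASSES) == 10


class TestAlleleFrequencyBinning:
    @pytest.mark.parametrize(
        "af,category",
        [(0.0, 0), (0.005, 0), (0.01, 0), (0.010001, 1), (0.5, 1), (1.0, 1)],
    )
    def test_binning(self, af, category):
        assert bin_allele_frequency(af) == category

    @pytest.mark.parametrize("af", [-0.1, 1.0001])
    def test_out_of_range(self, af):
        with pytest.raises(ValueError):
            bin_allele_frequency(af)


class TestConsensus:
    @pytest.mark.parametrize(
        "pa_list,expected",
        [
            (["pt", "pt", "be"], "pt"),  # strict majority
            (["pt", "be"], "uk"),  # tie -> unknown
            (["pt", "lp", "be"], "uk"),  # plurality without majority
            (["be"], "be"),  # single provider dominates
        ],
    )
    def test_pathogenicity_consensus(self, pa_list, expected):
        subs = [("FH", pa) for pa in pa_list]
        assert resolve_annotations(subs)[1] == expected

    def test_fields_resolve_independently(self):
        subs = [("FH", "pt"), ("FH", "be"), ("CM", "pt")]
        ph, pa = resolve_annotations(subs)
        assert ph == "FH"  # 2/3 majority
        assert pa == "pt"  # 2/3 majority

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_annotations([])

    @given(
        st.lists(st.sampled_from(["pt", "lp", "be", "lb"]), min_size=1, max_size=9)
    )
    @settings(deadline=None, derandomize=True)
    def test_matches_counting_oracle(self, pa_list):
        subs = [("FH", pa) for pa in pa_list]
        assert resolve_annotations(subs)[1] == oracle_majority(pa_list, "uk")


class TestDomainVocabulary:
    def test_block_boundary(self, small_domains):
        assert small_domains.block_boundary == 3
        assert small_domains.protein_block("MYBPC3") == (4, 5)

    def test_index_gap_rejected(self):
        with pytest.raises(VocabularyError, match="consecutive"):
            DomainVocabulary(
                (DomainEntry(1, "AA", "MAPT"), DomainEntry(3, "AB", "MAPT"))
            )

    def test_duplicate_code_rejected(self):
        with pytest.raises(VocabularyError, match="duplicate"):
            DomainVocabulary(
                (DomainEntry(1, "AA", "MAPT"), DomainEntry(2, "AA", "MAPT"))
            )

    def test_duplicate_population_code_rejected(self):
        with pytest.raises(VocabularyError):
            CodeVocabulary((("AFE", "a"), ("AFE", "b")), code_length=3)


class TestDatasetIO:
    def test_round_trip(self, tmp_path, toy_dataset_factory, small_domains,
                        small_populations, small_phenotypes):
        ds = toy_dataset_factory(seed=11, n=40)
        path = tmp_path / "toy.csv"
        write_6ddp(ds, path)
        back = load_6ddp(path, small_domains, small_populations, small_phenotypes)
        assert back.records == ds.records

    def test_fulfilled_partition(self, record_factory):
        from twodcg import SixDDPDataset

        ds = SixDDPDataset(
            [
                record_factory(pa="pt"),
                record_factory(pa="uk"),
                record_factory(ph="uk"),
            ]
        )
        assert ds.n_fulfilled == 1
        assert len(ds.fulfilled()) + len(ds.unfulfilled()) == len(ds)

    def test_three_row_fixture_counts(self, tmp_path, small_domains,
                                      small_populations, small_phenotypes):
        path = tmp_path / "mini.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(SIXDDP_COLUMNS)
            w.writerow(["CL", "K", "G", "AFE", 0, "FH", "pt"])
            w.writerow(["ML", "E", "T", "EUR", 1, "CM", "be"])
            w.writerow(["L8", "L", "L", "EAS", 0, "FH", "uk"])
        ds = load_6ddp(path, small_domains, small_populations, small_phenotypes)
        assert len(ds) == 3
        assert ds.n_fulfilled == 2

    def test_empty_body_valid_header(self, tmp_path, small_domains,
                                     small_populations, small_phenotypes):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(SIXDDP_COLUMNS) + "\n")
        ds = load_6ddp(path, small_domains, small_populations, small_phenotypes)
        assert len(ds) == 0

    @pytest.mark.parametrize(
        "column,bad",
        [("cd", "ZZ"), ("po", "XXX"), ("ph", "zz"), ("pa", "xx"),
         ("re_ref", "B"), ("af_cat", "7")],
    )
    def test_corrupted_row_named(self, tmp_path, small_domains, small_populations,
                                 small_phenotypes, column, bad):
        rows = [
            dict(zip(SIXDDP_COLUMNS, ["CL", "K", "G", "AFE", "0", "FH", "pt"])),
            dict(zip(SIXDDP_COLUMNS, ["ML", "E", "T", "EUR", "1", "CM", "be"])),
        ]
        rows[1][column] = bad
        path = tmp_path / "bad.csv"
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=SIXDDP_COLUMNS)
            w.writeheader()
            w.writerows(rows)
        with pytest.raises(VocabularyError, match="row 3"):
            load_6ddp(path, small_domains, small_populations, small_phenotypes)

    def test_missing_header_rejected(self, tmp_path, small_domains,
                                     small_populations, small_phenotypes):
        path = tmp_path / "headerless.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(VocabularyError, match="header"):
            load_6ddp(path, small_domains, small_populations, small_phenotypes)


class TestVocabularyLoading:
    def _write_vocabs(self, tmp_path, domain_rows):
        dpath = tmp_path / "domains.csv"
        with open(dpath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "code", "protein", "res_start", "res_end"])
            w.writerows(domain_rows)
        ppath = tmp_path / "populations.csv"
        ppath.write_text("code,name\nAFE,East Africa\nEUR,Europe\n")
        hpath = tmp_path / "phenotypes.csv"
        hpath.write_text("code,name\nFH,familial HCM\nCM,cardiomyopathy\n")
        return dpath, ppath, hpath

    def test_load(self, tmp_path):
        paths = self._write_vocabs(
            tmp_path,
            [[1, "CL", "MYH7-heavy-chain", 359, 377], [2, "L8", "MYBPC3", "", ""]],
        )
        domains, pops, phenos = load_vocabularies(*paths)
        assert len(domains) == 2
        assert domains.entries[0].residue_range == (359, 377)
        assert len(pops) == 2 and len(phenos) == 2
        assert domains.block_boundary == 1

    def test_duplicate_code_rejected(self, tmp_path):
        paths = self._write_vocabs(
            tmp_path,
            [[1, "CL", "MYH7-heavy-chain", "", ""], [2, "CL", "MYBPC3", "", ""]],
        )
        with pytest.raises(VocabularyError):
            load_vocabularies(*paths)
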