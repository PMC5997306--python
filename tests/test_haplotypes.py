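import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from bsaqtl.errors import ConfigurationError, DataError
from bsaqtl.haplotypes import (
    GeneModel,
    build_haplotypes,
    filter_variants,
    haplotype_anova,
    major_haplotypes,
    annotate_variant,
    relative_expression,
    synthetic_al_transporter_gene,
)


def geno_frame(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns, index=[f"acc{i}" for i in range(len(next(iter(columns.values()))))])


class TestFilterVariants:
    def test_low_maf_removed(self):
        # 25 accessions, 2 alt alleles of 50 -> MAF 0.04
        g = geno_frame({"s1": [2.0] + [0.0] * 24})
        assert filter_variants(g).shape[1] == 0

    def test_common_complete_snp_kept(self):
        g = geno_frame({"s1": [0.0, 2.0] * 10})
        assert filter_variants(g).shape[1] == 1

    def test_high_missingness_removed(self):
        g = geno_frame({"s1": [0.0, 2.0, np.nan] * 4})  # 25% missing
        assert filter_variants(g).shape[1] == 0

    def test_het_contributes_one_allele_of_each(self):
        # 10 accessions all het -> freq 0.5, MAF 0.5
        g = geno_frame({"s1": [1.0] * 10})
        assert filter_variants(g).shape[1] == 1

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(17)
        G = pd.DataFrame(
            np.select(
                [rng.random((40, 30)) < 0.1, rng.random((40, 30)) < 0.5],
                [np.nan, 0.0],
                default=2.0,
            )
        )
        strict = set(filter_variants(G, max_missing=0.1, min_maf=0.1).columns)
        loose = set(filter_variants(G, max_missing=0.3, min_maf=0.02).columns)
        assert strict <= loose


class TestBuildHaplotypes:
    def test_single_snp_partitions_homozygotes(self):
        g = geno_frame({"s1": [0.0, 0.0, 2.0, 2.0, 2.0]})
        groups = build_haplotypes(g)
        assert [g_.n for g_ in groups] == [3, 2]
        assert sum(g_.n for g_ in groups) == 5

    def test_two_snp_grouping(self):
        g = geno_frame({"s1": [0.0, 0.0, 0.0], "s2": [2.0, 2.0, 0.0]})
        groups = build_haplotypes(g)
        assert [g_.n for g_ in groups] == [2, 1]
        assert groups[0].haplotype == "02"

    def test_identical_accessions_form_one_group(self):
        g = geno_frame({"s1": [2.0] * 6, "s2": [0.0] * 6})
        groups = build_haplotypes(g)
        assert len(groups) == 1 and groups[0].n == 6

    def test_het_and_missing_excluded(self):
        g = geno_frame({"s1": [0.0, 1.0, np.nan, 2.0]})
        groups = build_haplotypes(g)
        assert sum(g_.n for g_ in groups) == 2

    def test_allele_spelling(self):
        g = geno_frame({"s1": [0.0, 2.0]})
        alleles = pd.DataFrame({"ref": ["G"], "alt": ["T"]}, index=["s1"])
        groups = build_haplotypes(g, alleles=alleles)
        assert {grp.haplotype for grp in groups} == {"G", "T"}

    def test_no_snps_is_an_error(self):
        with pytest.raises(ValueError):
            build_haplotypes(pd.DataFrame(index=["a"]))


class TestMajorHaplotypes:
    def test_strictly_more_than_threshold(self):
        g10 = geno_frame({"s1": [0.0] * 10})
        g11 = geno_frame({"s1": [0.0] * 11})
        assert major_haplotypes(build_haplotypes(g10)) == []
        assert len(major_haplotypes(build_haplotypes(g11))) == 1

    def test_empty_and_singleton_inputs(self):
        assert major_haplotypes([]) == []
        g = geno_frame({"s1": [0.0, 2.0]})
        assert major_haplotypes(build_haplotypes(g)) == []


class TestHaplotypeAnova:
    def _groups(self, values_by_hap):
        g = geno_frame(
            {"s1": [0.0] * len(values_by_hap["0"]) + [2.0] * len(values_by_hap["2"])}
        )
        groups = build_haplotypes(g)
        trait = pd.Series(
            values_by_hap["0"] + values_by_hap["2"], index=g.index, dtype=float
        )
        return groups, trait

    def test_matches_closed_form_oracle_on_six_values(self):
        groups, trait = self._groups({"0": [1.0, 2.0, 3.0], "2": [7.0, 8.0, 9.0]})
        res = haplotype_anova(groups, trait)
        # between/within mean-square oracle
        a, b = np.array([1.0, 2.0, 3.0]), np.array([7.0, 8.0, 9.0])
        grand = np.concatenate([a, b]).mean()
        msb = (3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2) / 1
        msw = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 4
        assert res.f == pytest.approx(msb / msw)
        assert res.p == pytest.approx(stats.f.sf(msb / msw, 1, 4))

    def test_label_permutation_invariance(self):
        groups, trait = self._groups({"0": [1.0, 2.0, 4.0], "2": [3.0, 5.0, 6.0]})
        res_a = haplotype_anova(groups, trait)
        res_b = haplotype_anova(list(reversed(groups)), trait)
        assert res_a.f == pytest.approx(res_b.f)
        assert res_a.p == pytest.approx(res_b.p)

    def test_zero_variance_is_degenerate(self):
        groups, trait = self._groups({"0": [2.0, 2.0], "2": [2.0, 2.0]})
        with pytest.raises(ValueError):
            haplotype_anova(groups, trait)

    def test_letters_separate_clearly_different_groups(self):
        groups, trait = self._groups({"0": [1.0, 1.1, 0.9, 1.0], "2": [9.0, 9.1, 8.9, 9.0]})
        res = haplotype_anova(groups, trait, alpha=0.01)
        letters = set(res.letters.values())
        assert len(letters) == 2 and not (res.letters["0"] == res.letters["2"])


class TestAnnotateVariant:
    def test_worked_missense_example_at_cds_311(self):
        model = synthetic_al_transporter_gene()
        eff = annotate_variant(model, 311, "C", "A", coords="cds")
        assert eff.codon_index == 104
        assert eff.codon_pos == 2
        assert (eff.ref_codon, eff.alt_codon) == ("GCC", "GAC")
        assert (eff.ref_aa, eff.alt_aa) == ("A", "D")
        assert eff.consequence == "missense"

    def test_minus_strand_genomic_coordinates_complemented(self):
        model = synthetic_al_transporter_gene()
        # locate the genomic base for CDS position 311 by inverting the map
        genomic = next(
            p
            for s, e in model.cds
            for p in range(s, e + 1)
            if model.genomic_to_cds(p) == 311
        )
        eff = annotate_variant(model, genomic, "G", "T", coords="genomic")
        assert (eff.ref_codon, eff.alt_codon) == ("GCC", "GAC")
        assert eff.consequence == "missense"

    def test_identity_substitution_synonymous(self):
        model = synthetic_al_transporter_gene()
        eff = annotate_variant(model, 1, "A", "A", coords="cds")
        assert eff.codon_index == 1 and eff.consequence == "synonymous"

    def test_third_position_wobble_synonymous(self):
        model = GeneModel(
            "toy", "chr1", "+", [(1, 9)], [(1, 9)], "ATGGGATAA"
        )
        eff = annotate_variant(model, 6, "A", "G", coords="cds")
        assert (eff.ref_codon, eff.alt_codon) == ("GGA", "GGG")
        assert eff.consequence == "synonymous"

    def test_nonsense_call(self):
        model = GeneModel("toy", "chr1", "+", [(1, 9)], [(1, 9)], "ATGTGGTAA")
        eff = annotate_variant(model, 6, "G", "A", coords="cds")  # TGG -> TGA
        assert eff.consequence == "nonsense"

    def test_position_outside_cds_is_non_coding(self):
        model = synthetic_al_transporter_gene()
        eff = annotate_variant(model, model.cds[0][0] - 100, "A", "C", coords="genomic")
        assert eff.consequence == "non_coding"

    def test_reference_mismatch_is_a_data_error(self):
        model = synthetic_al_transporter_gene()
        with pytest.raises(DataError):
            annotate_variant(model, 1, "C", "G", coords="cds")

    def test_missense_roundtrip_changes_exactly_one_residue(self):
        model = synthetic_al_transporter_gene()
        eff = annotate_variant(model, 311, "C", "A", coords="cds")
        seq = model.cds_seq
        mutated = seq[:310] + "A" + seq[311:]
        ref_prot = str(Seq(seq).translate())
        alt_prot = str(Seq(mutated).translate())
        diffs = [i for i, (r, a) in enumerate(zip(ref_prot, alt_prot), start=1) if r != a]
        assert diffs == [eff.codon_index]


class TestGeneModelValidation:
    def test_cds_must_start_with_atg(self):
        with pytest.raises(ConfigurationError):
            GeneModel("bad", "chr1", "+", [(1, 6)], [(1, 6)], "GTGTAA")

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(ConfigurationError):
            GeneModel("bad", "chr1", "+", [(1, 7)], [(1, 7)], "ATGTAAA")

    def test_synthetic_gene_structure(self):
        model = synthetic_al_transporter_gene()
        assert len(model.exons) == 13
        assert model.strand == "-"
        assert model.n_codons == 555  # 554 residues + stop
        span = model.exons[-1][1] - model.exons[0][0] + 1
        assert span == 4069

    def test_from_gff3_roundtrip_minus_strand(self, tmp_path):
        # two-exon minus-strand gene: coding seq ATG GGA TAA split 4+5
        coding = "ATGGGATAA"
        genomic_plus = str(Seq(coding).reverse_complement())  # 9 bp
        chrom_seq = "ACGT" + genomic_plus + "ACGT"
        fasta = tmp_path / "toy.fa"
        fasta.write_text(">chr9\n" + chrom_seq + "\n")
        gff = tmp_path / "toy.gff3"
        # exon1 genomic 5..9 (3' part of CDS), exon2 genomic 10..13
        gff.write_text(
            "##gff-version 3\n"
            "chr9\ttest\tgene\t5\t13\t.\t-\t.\tID=toygene\n"
            "chr9\ttest\tmRNA\t5\t13\t.\t-\t.\tID=toygene.1;Parent=toygene\n"
            "chr9\ttest\texon\t5\t9\t.\t-\t.\tParent=toygene.1\n"
            "chr9\ttest\texon\t10\t13\t.\t-\t.\tParent=toygene.1\n"
            "chr9\ttest\tCDS\t5\t9\t.\t-\t0\tParent=toygene.1\n"
            "chr9\ttest\tCDS\t10\t13\t.\t-\t0\tParent=toygene.1\n"
        )
        model = GeneModel.from_gff3(str(gff), str(fasta), "toygene")
        assert model.cds_seq == coding
        assert model.strand == "-"
        eff = annotate_variant(model, 6, "A", "G", coords="cds")
        assert eff.consequence == "synonymous"


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 15.0, 20.0, 15.0), 1.0),  # calibrator itself
            ((19.0, 15.0, 20.0, 15.0), 2.0),  # ddCt = -1
            ((22.0, 15.0, 20.0, 15.0), 0.25),  # ddCt = 2
        ],
    )
    def test_examples(self, cts, expected):
        assert relative_expression(*cts) == pytest.approx(expected)
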