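"""Genotype classification, encoding, loading, QC and PCA."""

import numpy as np
import pytest

from inbredfm import (
    NULL,
    GenotypeClass,
    StrainPanel,
    classify_genotype,
    genotype_pca,
    load_vcf,
    parse_consequences,
    parse_region,
    strain_qc_summary,
)
from inbredfm.genotype_store import GenotypeParseError, Region


class TestClassify:
    @pytest.mark.parametrize(
        "gt, confidence, expected",
        [
            ("0/0", 1, GenotypeClass.HOMOZYGOUS_REF),
            ("0/0", None, GenotypeClass.HOMOZYGOUS_REF),
            ("1/1", 1, GenotypeClass.HOMOZYGOUS_ALT),
            ("1/1", 0, GenotypeClass.LOW_CONFIDENCE),  # precedence over homozygous
            ("./.", 1, GenotypeClass.MISSING),
            ("./.", 0, GenotypeClass.LOW_CONFIDENCE),  # precedence over missing
            ("0/1", 1, GenotypeClass.HETEROZYGOUS),
            ("2/2", 1, GenotypeClass.MULTIALLELIC),  # allele 2 not retained
            ("1/2", 1, GenotypeClass.MULTIALLELIC),  # precedence over heterozygous
            ("./1", 1, GenotypeClass.MISSING),  # precedence over multiallelic
        ],
    )
    def test_precedence_and_classes(self, gt, confidence, expected):
        assert classify_genotype(gt, retained_alt_index=1, confidence=confidence) is expected

    def test_homozygous_for_retained_second_alt(self):
        assert classify_genotype("2/2", retained_alt_index=2) is GenotypeClass.HOMOZYGOUS_ALT
        assert classify_genotype("1/1", retained_alt_index=2) is GenotypeClass.MULTIALLELIC

    def test_encoded_values(self):
        assert GenotypeClass.HOMOZYGOUS_REF.encoded == 0
        assert GenotypeClass.HOMOZYGOUS_ALT.encoded == 1
        for cls in (GenotypeClass.LOW_CONFIDENCE, GenotypeClass.MISSING,
                    GenotypeClass.MULTIALLELIC, GenotypeClass.HETEROZYGOUS):
            assert cls.encoded == NULL

    def test_malformed_gt_names_variant_and_strain(self):
        with pytest.raises(GenotypeParseError, match=r"CAST/EiJ at 1:42"):
            classify_genotype("0/x", 1, variant="1:42", strain="CAST/EiJ")


def _write_vcf(path, lines, samples=("A", "B", "C"), fmt="GT:FI", extra_header=""):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=FI,Number=1,Type=Integer,Description="Confidence">\n'
        "##contig=<ID=1>\n##contig=<ID=7>\n##contig=<ID=X>\n"
        + extra_header
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    path.write_text(header + "".join(line + "\n" for line in lines))
    return path


class TestLoad:
    def test_retained_alt_is_most_frequent_and_others_null(self, tmp_path):
        # ALT1 hom in 1 strain, ALT2 hom in 2 strains -> retain ALT2
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC,G\t.\t.\t.\tGT:FI\t1/1:1\t2/2:1\t2/2:1"])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        rec = m.records[0]
        assert rec.alt_allele == "G"
        assert list(rec.genotypes) == [NULL, 1, 1]

    def test_retained_alt_tie_goes_to_first_listed(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC,G\t.\t.\t.\tGT:FI\t1/1:1\t2/2:1\t0/0:1"])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        assert m.records[0].alt_allele == "C"

    def test_all_null_records_dropped(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            "1\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t./.:1\t./.:1\t0/1:1",
            "1\t200\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        assert [r.pos for r in m.records] == [200]
        assert not any(np.all(r.genotypes == NULL) for r in m.records)

    def test_non_snv_skipped_and_counted(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            "1\t100\t.\tAT\tA\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
            "1\t200\t.\tA\tACC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
            "1\t300\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        assert len(m) == 1 and m.n_skipped_non_snv == 2

    def test_region_filter_closed_interval(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            f"7\t{pos}\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1"
            for pos in (99, 100, 150, 200, 201)
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")), regions=["7:100-200"])
        assert [r.pos for r in m.records] == [100, 150, 200]

    def test_autosome_filter(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            "7\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
            "X\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")), autosomes_only=True)
        assert [r.chrom for r in m.records] == ["7"]

    def test_missing_panel_strain_is_fatal(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1"])
        with pytest.raises(ValueError, match="ZZZ"):
            load_vcf(path, StrainPanel(("A", "B", "ZZZ")))

    def test_unsorted_input_is_fatal(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            "1\t200\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
            "1\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t1/1:1",
        ])
        with pytest.raises(ValueError, match="unsorted"):
            load_vcf(path, StrainPanel(("A", "B", "C")))

    def test_reference_strain_implicit_zeros(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t1/1:1\t1/1:1\t1/1:1"])
        panel = StrainPanel(("C57BL/6J", "A", "B", "C"), reference_strain="C57BL/6J")
        m = load_vcf(path, panel)
        assert list(m.records[0].genotypes) == [0, 1, 1, 1]

    def test_low_confidence_flag_marks_null(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC\t.\t.\t.\tGT:FI\t1/1:0\t1/1:1\t0/0:1"])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        assert list(m.records[0].genotypes) == [NULL, 1, 0]


class TestRoundTrip:
    def test_vcf_reexport_reproduces_encoding(self, noisy_fixture, tmp_path):
        path, spec, _ = noisy_fixture
        m = load_vcf(path, StrainPanel(spec.strains))
        out = tmp_path / "rt.vcf"
        m.to_vcf(out)
        m2 = load_vcf(out, StrainPanel(spec.strains))
        assert len(m2) == len(m)
        for a, b in zip(m.records, m2.records):
            assert (a.chrom, a.pos) == (b.chrom, b.pos)
            assert np.array_equal(a.genotypes, b.genotypes)


class TestConsequences:
    def test_known_terms_map_to_impacts(self):
        fmt = ["Allele", "Consequence", "Gene"]
        for term, impact in [("missense_variant", "MODERATE"),
                             ("stop_gained", "HIGH"),
                             ("synonymous_variant", "LOW"),
                             ("intron_variant", "MODIFIER")]:
            (ann,) = parse_consequences(f"C|{term}|G1", fmt)
            assert ann.impact == impact and ann.gene_id == "G1"

    def test_ampersand_terms_split_and_multiple_transcripts(self):
        anns = parse_consequences(
            "C|missense_variant&splice_region_variant|G1,C|intron_variant|G2",
            ["Allele", "Consequence", "Gene"],
        )
        assert [(a.consequence_term, a.impact) for a in anns] == [
            ("missense_variant", "MODERATE"),
            ("splice_region_variant", "LOW"),
            ("intron_variant", "MODIFIER"),
        ]

    def test_declared_impact_field_wins(self):
        (ann,) = parse_consequences("C|weird_term|HIGH|G1",
                                    ["Allele", "Consequence", "IMPACT", "Gene"])
        assert ann.impact == "HIGH"

    def test_unknown_term_falls_back_to_modifier(self):
        (ann,) = parse_consequences("C|made_up_term|G1", ["Allele", "Consequence", "Gene"])
        assert ann.impact == "MODIFIER"

    def test_empty_csq_gives_empty_list(self):
        assert parse_consequences("", ["Allele", "Consequence"]) == []

    def test_csq_parsed_from_file(self, tmp_path):
        hdr = ('##INFO=<ID=CSQ,Number=.,Type=String,Description="VEP. '
               'Format: Allele|Consequence|IMPACT|Gene">\n')
        path = _write_vcf(tmp_path / "t.vcf",
                          ["1\t100\t.\tA\tC\t.\t.\tCSQ=C|missense_variant|MODERATE|G9"
                           "\tGT:FI\t0/0:1\t1/1:1\t1/1:1"],
                          extra_header=hdr)
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        (ann,) = m.records[0].consequences
        assert (ann.consequence_term, ann.impact, ann.gene_id) == \
            ("missense_variant", "MODERATE", "G9")


class TestQC:
    def test_planted_class_counts_and_conservation(self, noisy_fixture):
        path, spec, truth = noisy_fixture
        m = load_vcf(path, StrainPanel(spec.strains))
        qc = strain_qc_summary(m)
        wide = qc.pivot(index="strain", columns="class", values="count")
        n_sites = len(truth.sites)
        # conservation: per strain the class counts sum to all scanned sites
        assert (wide.sum(axis=1) == n_sites).all()
        # exact match with the generator's planted tallies
        for strain in spec.strains:
            for cls, count in truth.qc_counts[strain].items():
                assert wide.loc[strain, cls] == count

    def test_clean_strain_is_all_homozygous(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            f"1\t{p}\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t./.:1" for p in (1, 2, 3)
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        wide = strain_qc_summary(m).pivot(index="strain", columns="class", values="count")
        assert wide.loc["A", "homozygous"] == 3
        assert wide.loc["C", "missing"] == 3


class TestPCA:
    def test_identical_strains_identical_coordinates(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = []
        for p in range(1, 41):
            g = rng.choice(["0/0", "1/1"], size=3)
            lines.append(f"1\t{p}\t.\tA\tC\t.\t.\t.\tGT:FI\t{g[0]}:1\t{g[0]}:1\t{g[1]}:1\t{g[2]}:1")
        path = _write_vcf(tmp_path / "t.vcf", lines, samples=("A", "Atwin", "B", "C"))
        coords = genotype_pca(load_vcf(path, StrainPanel(("A", "Atwin", "B", "C"))), 2)
        assert np.allclose(coords.loc["A"], coords.loc["Atwin"])

    def test_divergent_strain_is_pc1_outlier(self, tmp_path):
        rng = np.random.default_rng(1)
        lines = []
        for p in range(1, 201):
            base = rng.choice(["0/0", "1/1"])
            gts = [base] * 5
            # strain E carries a private allele at half the sites
            if rng.random() < 0.5:
                gts[4] = "1/1" if base == "0/0" else "0/0"
            # small shared noise so PCA has within-group variance
            if rng.random() < 0.2:
                gts[rng.integers(0, 4)] = "1/1" if base == "0/0" else "0/0"
            lines.append(f"1\t{p}\t.\tA\tC\t.\t.\t.\tGT:FI\t"
                         + "\t".join(f"{g}:1" for g in gts))
        samples = ("A", "B", "C", "D", "E")
        path = _write_vcf(tmp_path / "t.vcf", lines, samples=samples)
        coords = genotype_pca(load_vcf(path, StrainPanel(samples)), 2)
        dist = (coords - coords.mean()).pow(2).sum(axis=1)
        assert dist.idxmax() == "E"

    def test_shape_and_too_few_sites(self, tmp_path):
        path = _write_vcf(tmp_path / "t.vcf", [
            "1\t1\t.\tA\tC\t.\t.\t.\tGT:FI\t0/0:1\t1/1:1\t0/0:1",
            "1\t2\t.\tA\tC\t.\t.\t.\tGT:FI\t1/1:1\t0/0:1\t1/1:1",
        ])
        m = load_vcf(path, StrainPanel(("A", "B", "C")))
        assert genotype_pca(m, 2).shape == (3, 2)
        with pytest.raises(ValueError, match="complete sites"):
            genotype_pca(m, 3)


class TestRegions:
    def test_parse_region_with_commas(self):
        r = parse_region("7:83,244,464-95,801,713")
        assert r == Region("7", 83_244_464, 95_801_713)

    def test_bare_chromosome_and_bad_order(self):
        assert parse_region("7").contains("7", 10**9)
        with pytest.raises(ValueError):
            parse_region("7:100-50")
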