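import warnings

import numpy as np
import pandas as pd
import pytest

from rhoscan.formats_io import (CohortSelector, FormatError, HaplotypePanel,
                                default_snp_map, read_haplotypes,
                                read_metadata, read_snp_map, select_cohort,
                                write_haplotypes, write_snp_map)

from conftest import make_map, make_panel


class TestSnpMap:
    def test_default_map_matches_study_layout(self):
        m = default_snp_map()
        assert m.n_sites == 29
        assert m.length_bp == 3551
        assert m.segment_span == (160_689_203, 160_692_753)
        assert [e.label for e in m.entries[:5]] == [f"S{i}" for i in
                                                    range(1, 6)]
        assert all(e.subsegment == "PreAlu" for e in m.entries[:5])
        assert all(e.subsegment == "Alu" for e in m.entries[5:19])
        assert all(e.subsegment == "PostAlu" for e in m.entries[19:24])
        assert all(e.subsegment == "PostExon" for e in m.entries[24:])

    def test_round_trip_and_errors(self, tmp_path):
        m = default_snp_map()
        p = tmp_path / "map.tsv"
        write_snp_map(m, p)
        assert read_snp_map(p) == m
        # empty file
        (tmp_path / "empty.tsv").write_text("")
        with pytest.raises(FormatError):
            read_snp_map(tmp_path / "empty.tsv")
        # shuffled positions
        lines = p.read_text().splitlines()
        lines[2], lines[3] = lines[3], lines[2]
        (tmp_path / "shuffled.tsv").write_text("\n".join(lines))
        with pytest.raises(FormatError, match="non-monotone"):
            read_snp_map(tmp_path / "shuffled.tsv")
        # allele equal to itself
        bad = p.read_text().replace("rs6556547\t160689203\tC\tT",
                                    "rs6556547\t160689203\tC\tC")
        (tmp_path / "allele.tsv").write_text(bad)
        with pytest.raises(FormatError, match="ancestral"):
            read_snp_map(tmp_path / "allele.tsv")

    def test_duplicate_label_rejected(self, tmp_path):
        m = default_snp_map()
        p = tmp_path / "map.tsv"
        write_snp_map(m, p)
        dup = p.read_text().replace("S2\t", "S1\t", 1)
        (tmp_path / "dup.tsv").write_text(dup)
        with pytest.raises(FormatError, match="duplicate"):
            read_snp_map(tmp_path / "dup.tsv")


class TestHaplotypeIO:
    def test_tsv_round_trip_identical(self, tmp_path, rng):
        panel = make_panel(rng.integers(0, 2, size=(6, 5)),
                           population="JP", phenotype="CN", sex="M")
        p = tmp_path / "panel.tsv"
        write_haplotypes(panel, p)
        back = read_haplotypes(p, panel.snp_map)
        assert np.array_equal(back.matrix, panel.matrix)
        assert list(back.meta["population"]) == ["JP"] * 6
        # write -> read -> write is byte-identical
        p2 = tmp_path / "panel2.tsv"
        write_haplotypes(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_vcf_round_trip(self, tmp_path, rng):
        matrix = rng.integers(0, 2, size=(4, 5))
        panel = make_panel(matrix)
        panel.meta["individual"] = ["I1", "I1", "I2", "I2"]
        panel.meta["chromosome"] = [1, 2, 1, 2]
        p = tmp_path / "panel.vcf"
        write_haplotypes(panel, p)
        back = read_haplotypes(p, panel.snp_map)
        assert np.array_equal(back.matrix, panel.matrix)
        assert back.matrix.shape == (4, 5)

    def test_vcf_ref_equal_to_derived_inverts_codes(self, tmp_path):
        """A site whose VCF REF is the derived allele must be code-inverted
        relative to its raw genotype digits (hand-remapped 3-sample toy)."""
        m = make_map(2, length=100)
        e0, e1 = m.entries
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            "\tA\tB\tC\n"
            # REF = ancestral at site 1: raw digits match codes
            f"5\t{e0.position}\t.\t{e0.ancestral}\t{e0.derived}\t.\tPASS\t.\t"
            "GT\t0|1\t1|1\t0|0\n"
            # REF = derived at site 2: raw digits must be inverted
            f"5\t{e1.position}\t.\t{e1.derived}\t{e1.ancestral}\t.\tPASS\t.\t"
            "GT\t0|1\t1|1\t0|0\n")
        p = tmp_path / "t.vcf"
        p.write_text(vcf)
        panel = read_haplotypes(p, m)
        assert list(panel.matrix[:, 0]) == [0, 1, 1, 1, 0, 0]
        assert list(panel.matrix[:, 1]) == [1, 0, 0, 0, 1, 1]

    def test_vcf_unphased_and_foreign_allele_rejected(self, tmp_path):
        m = make_map(1, length=100)
        e = m.entries[0]
        head = ("##fileformat=VCFv4.2\n"
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n")
        (tmp_path / "u.vcf").write_text(
            head + f"5\t{e.position}\t.\t{e.ancestral}\t{e.derived}\t.\t"
            "PASS\t.\tGT\t0/1\n")
        with pytest.raises(FormatError, match="unphased"):
            read_haplotypes(tmp_path / "u.vcf", m)
        (tmp_path / "f.vcf").write_text(
            head + f"5\t{e.position}\t.\tT\t{e.derived}\t.\tPASS\t.\t"
            "GT\t0|0\n")
        with pytest.raises(FormatError, match="neither map allele"):
            read_haplotypes(tmp_path / "f.vcf", m)

    def test_metadata_merge_keeps_unknowns_as_missing(self, tmp_path, rng):
        panel = make_panel(rng.integers(0, 2, size=(2, 3)))
        p = tmp_path / "panel.tsv"
        write_haplotypes(panel, p)
        (tmp_path / "meta.tsv").write_text(
            "individual\tpopulation\tphenotype\tsex\nH1\tJP\tCN\tM\n")
        meta = read_metadata(tmp_path / "meta.tsv")
        back = read_haplotypes(p, panel.snp_map, meta)
        assert back.meta.loc[0, "population"] == "JP"
        assert pd.isna(back.meta.loc[1, "population"])
        assert back.n_chromosomes == 2  # unknown metadata is not dropped


class TestSelectCohort:
    def _study_panel(self, rng):
        """95 JP CN male subjects (190 chromosomes) plus others."""
        blocks = []
        for pop, phe, sex, n_subj in [("JP", "CN", "M", 95),
                                      ("JP", "CN", "F", 100),
                                      ("JP", "SZ", "M", 203)]:
            p = make_panel(rng.integers(0, 2, size=(2 * n_subj, 4)),
                           population=pop, phenotype=phe, sex=sex)
            blocks.append(p)
        matrix = np.vstack([b.matrix for b in blocks])
        meta = pd.concat([b.meta for b in blocks], ignore_index=True)
        return HaplotypePanel(blocks[0].snp_map, matrix, meta)

    def test_jp_cn_male_selection_has_190_chromosomes(self, rng):
        panel = self._study_panel(rng)
        sub = select_cohort(panel, CohortSelector("JP", "CN", "M"))
        assert sub.n_chromosomes == 190

    def test_empty_filters_return_everything(self, rng):
        panel = self._study_panel(rng)
        sub = select_cohort(panel, CohortSelector())
        assert sub.n_chromosomes == panel.n_chromosomes
        assert np.array_equal(sub.matrix, panel.matrix)

    def test_absent_population_warns_and_returns_empty(self, rng):
        panel = self._study_panel(rng)
        with pytest.warns(UserWarning, match="matched no chromosomes"):
            sub = select_cohort(panel, CohortSelector(population="AF"))
        assert sub.n_chromosomes == 0
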