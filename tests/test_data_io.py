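"""I/O contracts: VCF genotype counting, CDS validation, PDB parsing, round trips."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from lohfunnel import data_io
from lohfunnel.data_io import (
    CDSModel,
    DomainAnnotation,
    GenotypeCounts,
    Variant,
    VariantParseError,
)

SAMPLE_MAP = {"S1": "pop1", "S2": "pop1", "S3": "pop2", "S4": "pop2"}


def write_vcf(path, body: str, samples=("S1", "S2", "S3", "S4")) -> None:
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=10000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        """
    )
    columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(header + columns + "\n" + textwrap.dedent(body))


class TestReadVariants:
    def test_sample_conservation_two_records(self, tmp_path):
        """Per population, genotype counts sum to that population's size."""
        vcf = tmp_path / "v.vcf"
        write_vcf(
            vcf,
            """\
            chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/0
            chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t0/1
            """,
        )
        variants = data_io.read_variants(vcf, SAMPLE_MAP)
        assert len(variants) == 2
        for variant in variants:
            for pop in ("pop1", "pop2"):
                assert variant.pop_genotype_counts[pop].total == 2

    def test_indel_skipped(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(
            vcf,
            """\
            chr1\t100\trs1\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
            chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
            """,
        )
        variants = data_io.read_variants(vcf, SAMPLE_MAP)
        assert [v.pos for v in variants] == [200]

    def test_single_het_in_one_population(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\n")
        (variant,) = data_io.read_variants(vcf, SAMPLE_MAP)
        assert variant.pop_genotype_counts["pop1"] == GenotypeCounts(1, 1, 0, 0)
        assert variant.pop_genotype_counts["pop2"] == GenotypeCounts(2, 0, 0, 0)

    def test_missing_genotypes_tracked_not_counted(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0\n")
        (variant,) = data_io.read_variants(vcf, SAMPLE_MAP)
        counts = variant.pop_genotype_counts["pop1"]
        assert counts.missing == 1 and counts.called == 1

    def test_multiallelic_split_and_skip(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, "chr1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t2/2\n")
        split = data_io.read_variants(vcf, SAMPLE_MAP, multiallelic="split")
        assert sorted(v.alt_allele for v in split) == ["G", "T"]
        alt_t = next(v for v in split if v.alt_allele == "T")
        assert alt_t.pop_genotype_counts["pop1"].het == 1  # the 0/2 sample
        assert alt_t.pop_genotype_counts["pop2"].hom_alt == 1  # the 2/2 sample
        assert data_io.read_variants(vcf, SAMPLE_MAP, multiallelic="skip") == []

    def test_sample_missing_from_map_raises(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\n")
        with pytest.raises(VariantParseError, match="S4"):
            data_io.read_variants(vcf, {"S1": "p", "S2": "p", "S3": "p"})


class TestVariantRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ref_allele": "A", "alt_allele": "A"},
            {"ref_allele": "A", "alt_allele": "AT"},
            {"ref_allele": "N", "alt_allele": "G"},
            {"pos": 0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        base = dict(chrom="chr1", pos=10, ref_allele="A", alt_allele="G")
        base.update(kwargs)
        with pytest.raises(ValueError):
            Variant(**base)


class TestCDSModels:
    def test_single_exon_protein_length(self):
        model = CDSModel("G", "T", "chr1", "+", ((11, 19),), "P1")
        assert model.protein_length == 2

    def test_frame_violation_rejected_on_read(self, tmp_path, caplog):
        path = tmp_path / "cds.tsv"
        frame = pd.DataFrame(
            [
                {"gene": "G1", "transcript": "T1", "chrom": "chr1", "strand": "+",
                 "exons": "11-20", "protein_accession": "P1"},  # 10 nt, bad frame
                {"gene": "G2", "transcript": "T2", "chrom": "chr1", "strand": "+",
                 "exons": "11-19", "protein_accession": "P2"},
            ]
        )
        data_io.write_tsv(path, frame)
        with caplog.at_level("WARNING"):
            models = data_io.read_cds_models(path)
        assert [m.transcript_id for m in models] == ["T2"]
        assert "T1" in caplog.text

    def test_minus_strand_exons_sorted_by_genomic_start(self):
        model = CDSModel("G", "T", "chr1", "-", ((50, 55), (10, 15)), "P1")
        assert model.exons == ((10, 15), (50, 55))
        assert model.strand == "-"

    def test_overlapping_exons_raise(self):
        with pytest.raises(ValueError, match="overlapping"):
            CDSModel("G", "T", "chr1", "+", ((10, 20), (15, 24)), "P1")

    def test_round_trip(self, tmp_path, bundle):
        path = tmp_path / "cds.tsv"
        data_io.write_cds_models(path, bundle.models)
        assert data_io.read_cds_models(path) == bundle.models


PDB_THREE_RESIDUES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  CA AGLY A   2       3.000   1.000   0.000  0.40  0.00           C
ATOM      4  CA BGLY A   2       3.200   1.100   0.000  0.60  0.00           C
ATOM      5  CA  SER A   3       5.000   2.000   0.000  1.00  0.00           C
TER
HETATM    6  C1  COA A 500      10.000  10.000  10.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_chains_residues_and_ligands(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_THREE_RESIDUES)
        structure = data_io.read_structure(path)
        assert len(structure.chains) == 1
        chain = structure.chains[0]
        assert len(chain.residues) == 3
        assert [r.name for r in structure.ligands] == ["COA"]

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_THREE_RESIDUES)
        structure = data_io.read_structure(path)
        gly = structure.chains[0].residues[1]
        assert len(gly.atoms) == 1
        assert gly.atoms[0].coord[0] == pytest.approx(3.2)  # occupancy 0.60 wins

    def test_numbering_gap_preserves_author_labels(self, tmp_path):
        lines = []
        for i, num in enumerate((10, 11, 15), start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{num:4d}    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"  1.00  0.00           C"
            )
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        structure = data_io.read_structure(path)
        assert [r.label for r in structure.chains[0].residues] == ["10", "11", "15"]

    def test_no_atom_records_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError):
            data_io.read_structure(path)


class TestTableRoundTrips:
    def test_domains(self, tmp_path, bundle):
        path = tmp_path / "domains.tsv"
        data_io.write_domain_annotations(path, bundle.domains)
        assert data_io.read_domain_annotations(path) == bundle.domains

    def test_expression(self, tmp_path, bundle):
        path = tmp_path / "expr.tsv"
        data_io.write_expression(path, bundle.expression)
        pd.testing.assert_frame_equal(data_io.read_expression(path), bundle.expression)

    def test_loh_frequencies(self, tmp_path, bundle):
        path = tmp_path / "loh.tsv"
        data_io.write_loh_frequencies(path, bundle.loh_table)
        pd.testing.assert_frame_equal(
            data_io.read_loh_frequencies(path), bundle.loh_table
        )

    def test_sample_map(self, tmp_path, bundle):
        path = tmp_path / "samples.tsv"
        data_io.write_sample_map(path, bundle.sample_to_pop)
        assert data_io.read_sample_map(path) == bundle.sample_to_pop

    def test_cohort_validation(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        frame = pd.DataFrame(
            [{"patient": "P1", "locus": "rs1", "normal_ref": -5.0, "normal_alt": 10.0,
              "tumor_ref": 1.0, "tumor_alt": 1.0, "stage": "II"}]
        )
        data_io.write_cohort(path, frame)
        with pytest.raises(ValueError, match=">= 0"):
            data_io.read_cohort(path)

    def test_expression_negative_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        data_io.write_tsv(path, pd.DataFrame({"gene": ["G"], "colon": [-1.0]}))
        with pytest.raises(ValueError):
            data_io.read_expression(path)


class TestDomainAnnotation:
    def test_site_classes_validated(self):
        with pytest.raises(ValueError, match="site class"):
            DomainAnnotation("P1", "D1", 2, 10, ((5, "allosteric"),))

    def test_external_site_flagged(self):
        domain = DomainAnnotation("P1", "D1", 5, 10, ((3, "catalytic"), (7, "catalytic")))
        assert domain.external_sites() == (3,)
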