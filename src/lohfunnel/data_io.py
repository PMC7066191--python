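"""Readers, writers and core record types for the pipeline's external formats.

Formats handled: genotype-bearing VCF 4.x (via cyvcf2), CCDS-like tab-delimited
CDS/exon tables, protein FASTA, PDB structures (via gemmi), and TSV tables for
domain/site annotations, gene x tissue expression, locus x cancer-type LOH
frequencies, sample-to-population maps and paired tumor-normal cohorts.

Conventions: all on-disk coordinates are 1-based inclusive (VCF, CCDS, PDB);
interval arithmetic inside the package is done on these validated records.
TSV outputs carry a header line preceded by '#'-prefixed provenance comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structmap import Atom, Chain, Residue, StructureChainSet

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

__all__ = [
    "GenotypeCounts",
    "Variant",
    "CDSModel",
    "DomainAnnotation",
    "VariantParseError",
    "read_sample_map",
    "write_sample_map",
    "read_variants",
    "read_cds_models",
    "write_cds_models",
    "read_fasta",
    "write_fasta",
    "read_structure",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_expression",
    "write_expression",
    "read_loh_frequencies",
    "write_loh_frequencies",
    "read_cohort",
    "write_cohort",
    "write_tsv",
]


class VariantParseError(ValueError):
    """Malformed variant record; message names the offending site."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts for one variant in one population.

    Half-called or missing genotypes (e.g. ``./.``) are excluded from the
    three counts and tracked in ``missing`` so allele-frequency denominators
    reflect called alleles only.
    """

    hom_ref: int
    het: int
    hom_alt: int
    missing: int = 0

    def __post_init__(self):
        if min(self.hom_ref, self.het, self.hom_alt, self.missing) < 0:
            raise ValueError("genotype counts must be >= 0")

    @property
    def called(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    @property
    def total(self) -> int:
        return self.called + self.missing

    @property
    def alt_alleles(self) -> int:
        return self.het + 2 * self.hom_alt


@dataclass(frozen=True)
class Variant:
    """One biallelic SNV with per-population genotype counts."""

    chrom: str
    pos: int  # 1-based, reference strand
    ref_allele: str
    alt_allele: str
    rsid: Optional[str] = None
    pop_genotype_counts: Mapping[str, GenotypeCounts] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.key}: pos must be >= 1")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(f"{self.key}: alleles must be single bases in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.key}: ref and alt alleles are identical")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{getattr(self, 'ref_allele', '?')}>{getattr(self, 'alt_allele', '?')}"


@dataclass(frozen=True)
class CDSModel:
    """A transcript's coding exons: the genome-to-protein coordinate bridge.

    Exons are 1-based inclusive genomic intervals sorted by start, regardless
    of strand.  The coding sequence includes the stop codon, so the protein is
    one residue shorter than total_length/3.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_accession: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for start, end in exons:
            if start < 1 or end < start:
                raise ValueError(f"{self.transcript_id}: bad exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end
        object.__setattr__(self, "exons", exons)
        if self.total_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.total_length} not divisible by 3"
            )

    @property
    def total_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def protein_length(self) -> int:
        return self.total_length // 3 - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.exons)


@dataclass(frozen=True)
class DomainAnnotation:
    """A functional domain on a protein, with its annotated site residues.

    Site classes follow active-site annotation practice: ``catalytic``,
    ``substrate_binding``, ``cofactor_binding``.  A site residue outside the
    domain interval is accepted but flagged external.
    """

    protein_accession: str
    domain_id: str
    domain_start: int
    domain_end: int
    site_residues: tuple[tuple[int, str], ...] = ()

    SITE_CLASSES = ("catalytic", "substrate_binding", "cofactor_binding")

    def __post_init__(self):
        if not (1 <= self.domain_start <= self.domain_end):
            raise ValueError(f"{self.domain_id}: bad domain interval")
        for idx, cls in self.site_residues:
            if idx < 1:
                raise ValueError(f"{self.domain_id}: site residue index {idx} < 1")
            if cls not in self.SITE_CLASSES:
                raise ValueError(f"{self.domain_id}: unknown site class {cls!r}")

    def external_sites(self) -> tuple[int, ...]:
        return tuple(
            i for i, _ in self.site_residues if not self.domain_start <= i <= self.domain_end
        )

    def contains_residue(self, residue_index: int) -> bool:
        return self.domain_start <= residue_index <= self.domain_end


# ---------------------------------------------------------------------------
# generic TSV helpers


def write_tsv(path, frame: pd.DataFrame, provenance: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV with '#'-prefixed provenance comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# sample map


def read_sample_map(path) -> dict[str, str]:
    """TSV with columns ``sample`` and ``population``."""
    frame = _read_tsv(path)
    return dict(zip(frame["sample"].astype(str), frame["population"].astype(str)))


def write_sample_map(path, sample_to_pop: Mapping[str, str]) -> None:
    frame = pd.DataFrame(
        {"sample": list(sample_to_pop), "population": list(sample_to_pop.values())}
    )
    write_tsv(path, frame, ["sample-to-population assignment"])


# ---------------------------------------------------------------------------
# variants (VCF)


def read_variants(
    path,
    sample_to_pop: Mapping[str, str],
    multiallelic: str = "split",
) -> list[Variant]:
    """Read biallelic SNVs with per-population genotype counts from a VCF.

    Multiallelic sites are split into one biallelic record per alternate
    allele (``multiallelic="split"``, the default) or skipped entirely
    (``"skip"``).  Indels and symbolic alleles are skipped and logged.
    Missing genotypes are excluded from the counts but tracked.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("split", "skip"):
        raise ValueError("multiallelic must be 'split' or 'skip'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_to_pop]
    if unknown:
        raise VariantParseError(
            f"samples missing from population map: {', '.join(unknown[:5])}"
        )
    populations = sorted(set(sample_to_pop[s] for s in samples))
    pop_of = np.array([sample_to_pop[s] for s in samples])
    variants: list[Variant] = []
    for record in vcf:
        alts = record.ALT
        if len(alts) > 1 and multiallelic == "skip":
            logger.info("skipping multiallelic site %s:%s", record.CHROM, record.POS)
            continue
        genotypes = record.genotypes  # [allele1, allele2, phased] per sample
        for alt_index, alt in enumerate(alts, start=1):
            if len(record.REF) != 1 or len(alt) != 1 or alt not in VALID_BASES:
                logger.info(
                    "skipping non-SNV allele %s>%s at %s:%s",
                    record.REF, alt, record.CHROM, record.POS,
                )
                continue
            counts: dict[str, GenotypeCounts] = {}
            for pop in populations:
                mask = pop_of == pop
                tallies = {0: 0, 1: 0, 2: 0}
                missing = 0
                for gt, in_pop in zip(genotypes, mask):
                    if not in_pop:
                        continue
                    alleles = gt[:-1]
                    if len(alleles) != 2 or any(a < 0 for a in alleles):
                        missing += 1
                        continue
                    tallies[sum(1 for a in alleles if a == alt_index)] += 1
                counts[pop] = GenotypeCounts(
                    hom_ref=tallies[0], het=tallies[1], hom_alt=tallies[2], missing=missing
                )
            try:
                variants.append(
                    Variant(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref_allele=record.REF,
                        alt_allele=alt,
                        rsid=None if record.ID in (None, ".") else record.ID,
                        pop_genotype_counts=counts,
                    )
                )
            except ValueError as exc:
                raise VariantParseError(
                    f"malformed record at {record.CHROM}:{record.POS}: {exc}"
                ) from exc
    return variants


# ---------------------------------------------------------------------------
# CDS models


CDS_COLUMNS = ["gene", "transcript", "chrom", "strand", "exons", "protein_accession"]


def _format_exons(exons: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for token in str(text).split(","):
        start, _, end = token.partition("-")
        out.append((int(start), int(end)))
    return tuple(out)


def read_cds_models(path) -> list[CDSModel]:
    """Read a CCDS-like tab-delimited exon table.

    Models whose exon total is not divisible by 3 are rejected with a warning;
    overlapping exons raise a validation error.
    """
    frame = _read_tsv(path)
    models: list[CDSModel] = []
    for row in frame.itertuples(index=False):
        try:
            models.append(
                CDSModel(
                    gene_symbol=str(row.gene),
                    transcript_id=str(row.transcript),
                    chrom=str(row.chrom),
                    strand=str(row.strand),
                    exons=_parse_exons(row.exons),
                    protein_accession=str(row.protein_accession),
                )
            )
        except ValueError as exc:
            if "not divisible by 3" in str(exc):
                logger.warning("rejecting CDS model: %s", exc)
                continue
            raise
    return models


def write_cds_models(path, models: Sequence[CDSModel]) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene": m.gene_symbol,
                "transcript": m.transcript_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": _format_exons(m.exons),
                "protein_accession": m.protein_accession,
            }
            for m in models
        ],
        columns=CDS_COLUMNS,
    )
    write_tsv(path, frame, ["CDS models: 1-based inclusive exon intervals"])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# structures (PDB)


def read_structure(path) -> StructureChainSet:
    """Read a PDB file into per-chain ordered residues.

    Alternate locations are resolved to the highest-occupancy atom; hydrogens
    are retained on the record but ignored by downstream geometry.  Non-water
    HETATM groups (cofactors, ligands) are kept apart from the polymer chains.
    Author residue numbering (with insertion codes appended) is preserved.
    """
    import gemmi

    path = Path(path)
    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = structure[0]
    chains: list[Chain] = []
    ligands: list[Residue] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # resolve altlocs: keep highest occupancy per atom name
            best: dict[str, "gemmi.Atom"] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = tuple(
                Atom(
                    name=name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                )
                for name, a in best.items()
            )
            if not atoms:
                continue
            label = f"{res.seqid.num}{res.seqid.icode.strip()}"
            record = Residue(name=res.name, label=label, atoms=atoms)
            if res.het_flag == "H":
                if res.name != "HOH":
                    ligands.append(record)
            else:
                residues.append(record)
        if residues:
            chains.append(Chain(chain_id=chain.name, residues=tuple(residues)))
    if not chains and not ligands:
        raise ValueError(f"{path}: no ATOM records")
    return StructureChainSet(
        structure_id=path.stem, chains=tuple(chains), ligands=tuple(ligands)
    )


# ---------------------------------------------------------------------------
# domain / site annotations

DOMAIN_COLUMNS = ["protein_accession", "domain_id", "domain_start", "domain_end", "sites"]


def _format_sites(sites: Iterable[tuple[int, str]]) -> str:
    return ",".join(f"{i}:{cls}" for i, cls in sites)


def _parse_sites(text) -> tuple[tuple[int, str], ...]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text) == "":
        return ()
    out = []
    for token in str(text).split(","):
        idx, _, cls = token.partition(":")
        out.append((int(idx), cls))
    return tuple(out)


def read_domain_annotations(path) -> list[DomainAnnotation]:
    frame = _read_tsv(path)
    return [
        DomainAnnotation(
            protein_accession=str(row.protein_accession),
            domain_id=str(row.domain_id),
            domain_start=int(row.domain_start),
            domain_end=int(row.domain_end),
            site_residues=_parse_sites(row.sites),
        )
        for row in frame.itertuples(index=False)
    ]


def write_domain_annotations(path, domains: Sequence[DomainAnnotation]) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_accession": d.protein_accession,
                "domain_id": d.domain_id,
                "domain_start": d.domain_start,
                "domain_end": d.domain_end,
                "sites": _format_sites(d.site_residues),
            }
            for d in domains
        ],
        columns=DOMAIN_COLUMNS,
    )
    write_tsv(path, frame, ["functional domains with annotated site residues (1-based)"])


# ---------------------------------------------------------------------------
# expression, LOH frequency, cohort tables


def read_expression(path) -> pd.DataFrame:
    """Gene x tissue expression table; index = gene symbol, columns = tissues."""
    frame = _read_tsv(path).set_index("gene")
    if (frame.values < 0).any():
        raise ValueError("expression scores must be >= 0")
    return frame


def write_expression(path, table: pd.DataFrame) -> None:
    write_tsv(path, table.reset_index(), ["gene x tissue expression scores"])


def read_loh_frequencies(path) -> pd.DataFrame:
    """Long-format (gene, cancer_type, lf) LOH-frequency table."""
    frame = _read_tsv(path)
    if not frame["lf"].between(0, 1).all():
        raise ValueError("LOH frequencies must lie in [0, 1]")
    return frame


def write_loh_frequencies(path, table: pd.DataFrame) -> None:
    write_tsv(path, table, ["LOH frequency per locus/gene and cancer type"])


COHORT_COLUMNS = [
    "patient", "locus", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt", "stage",
]


def read_cohort(path) -> pd.DataFrame:
    """Paired tumor-normal allele-signal table (one row per patient x locus)."""
    frame = _read_tsv(path)
    missing = [c for c in COHORT_COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    signals = frame[["normal_ref", "normal_alt", "tumor_ref", "tumor_alt"]]
    if (signals.values < 0).any():
        raise ValueError("allele signals must be >= 0")
    return frame


def write_cohort(path, frame: pd.DataFrame) -> None:
    write_tsv(path, frame, ["paired tumor-normal allele signal intensities"])
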