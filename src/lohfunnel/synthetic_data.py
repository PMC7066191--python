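"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate, at desk scale, the study inputs: a multi-population
genotype panel (Hardy-Weinberg draws at configurable per-population allele
frequencies), CDS models on both strands, protein sequences, toy crystal
structures (ideal alpha-helical backbones with pseudo side chains and
designated catalytic residues), expression and LOH-frequency tables, and a
paired tumor-normal cohort with a planted LOH rate among heterozygotes.

Every generator is deterministic given (seed, config); each draws from its own
stream derived from the master seed by a fixed offset.  A truth table records
the funnel fate of every planted variant.  For the frequency-dependent stages
(allele-frequency prevalence, heterozygosity in all populations) the recorded
fate is computed from the realized genotype draws, so truth and pipeline agree
exactly under any seed; the planted frequencies keep wide margins from the
filter thresholds so the realized fate matches the intended one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import data_io
from .consequence import cds_to_genomic, extract_cds
from .data_io import CDSModel, DomainAnnotation
from .structmap import (
    Atom,
    Chain,
    Residue,
    StructureChainSet,
    min_distance_to_sites,
    relative_accessibility,
)

__all__ = [
    "PlantedVariantSpec",
    "CohortSpec",
    "SimulationConfig",
    "generate_reference",
    "generate_population_vcf",
    "generate_structure",
    "generate_cohort",
    "generate_all",
    "default_config",
]

# non-stop codons used as filler; translation-stable under the standard code
_FILLER_CODONS = (
    "GCT", "GTG", "CTG", "ATC", "TTC", "TCT", "ACC", "GAA", "GAT", "AAA",
    "AAC", "CAG", "CAC", "TGG", "TAC", "ATG", "CCG", "TGC",
)
_STOP = "TAA"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# three-letter names for PDB emission
_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class PlantedVariantSpec:
    """One gene and the single variant planted in it, with its intended fate."""

    gene: str
    variant_class: str = "missense"  # missense | synonymous
    residue_index: int = 8
    pop_afs: tuple[float, ...] = (0.4, 0.4, 0.4)
    has_domain_site: bool = True
    has_structure: bool = True
    near_site: bool = True
    buried: bool = False
    expression: float = 800.0
    loh_freq: float = 0.30


@dataclass(frozen=True)
class CohortSpec:
    """Paired tumor-normal cohort: exact planted counts or stochastic rates.

    When ``het_frequency`` (or ``loh_rate``) is set it overrides the exact
    count ``n_het`` (or ``n_loh``) with a per-patient Bernoulli draw.  Signals
    emulate Sanger peak intensities: a diploid allele contributes
    ``base_signal``; LOH collapses the lost allele to ``loh_minor_fraction``
    of the total; Gaussian noise (sd ``signal_sd``) is truncated at zero.
    """

    n_patients: int = 74
    n_het: int = 30
    n_loh: int = 2
    het_frequency: Optional[float] = None
    loh_rate: Optional[float] = None
    base_signal: float = 100.0
    signal_sd: float = 5.0
    loh_minor_fraction: float = 0.05
    locus: str = "rs1799930"  # emulated marker label; data are synthetic


def _default_planted() -> tuple[PlantedVariantSpec, ...]:
    """The default study conditions: one gene passing every funnel stage and
    one planted failure per stage."""
    return (
        PlantedVariantSpec(gene="GENE01"),  # passes everything
        PlantedVariantSpec(gene="GENE02", variant_class="synonymous"),
        PlantedVariantSpec(gene="GENE03", pop_afs=(0.001, 0.0, 0.0)),  # too rare
        PlantedVariantSpec(gene="GENE04", has_domain_site=False),
        PlantedVariantSpec(gene="GENE05", has_structure=False),
        PlantedVariantSpec(gene="GENE06", residue_index=18, near_site=False),
        PlantedVariantSpec(gene="GENE07", buried=True),
        PlantedVariantSpec(gene="GENE08", pop_afs=(0.5, 0.004, 0.004)),  # het fails
        PlantedVariantSpec(gene="GENE09", loh_freq=0.10),
        PlantedVariantSpec(gene="GENE10", expression=100.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_populations: int = 3
    samples_per_population: int = 100
    genome_length: int = 6000
    protein_length: int = 20  # residues, excluding the stop codon
    site_residue: int = 5  # catalytic residue planted in every structure
    planted: tuple[PlantedVariantSpec, ...] = field(default_factory=_default_planted)
    include_intergenic_variant: bool = True
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tissue: str = "colon"
    cancer_type: str = "colorectal"
    incidence: float = 1_400_000.0

    def __post_init__(self):
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("population counts must be >= 1")
        if self.protein_length < 10:
            raise ValueError("protein_length must be >= 10")
        for spec in self.planted:
            if len(spec.pop_afs) != self.n_populations:
                raise ValueError(f"{spec.gene}: need {self.n_populations} allele frequencies")
            if not all(0 <= p <= 1 for p in spec.pop_afs):
                raise ValueError(f"{spec.gene}: allele frequencies must lie in [0, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, offset]))


# ---------------------------------------------------------------------------
# reference: genome + CDS models + proteins


def _gene_slot(index: int, config: SimulationConfig) -> int:
    start = 200 + index * 500
    if start + 200 > config.genome_length:
        raise ValueError(
            f"gene {index} does not fit in genome of length {config.genome_length}"
        )
    return start


def _build_cds(spec: PlantedVariantSpec, config: SimulationConfig, rng) -> str:
    """Coding sequence with an ATG start, planted variant codon, catalytic and
    far-site codons fixed to arginine-free fillers, and a stop codon."""
    n = config.protein_length
    if not 2 <= spec.residue_index <= n:
        raise ValueError(f"{spec.gene}: variant residue outside protein")
    codons = ["ATG"]
    for residue in range(2, n + 1):
        codons.append(_FILLER_CODONS[rng.integers(len(_FILLER_CODONS))])
    # the planted codon: CGA (Arg); G>A at codon position 2 gives CAA (Gln,
    # missense -- the R197Q pattern), A>G at position 3 gives CGG (Arg,
    # synonymous)
    codons[spec.residue_index - 1] = "CGA"
    codons.append(_STOP)
    return "".join(codons)


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[CDSModel], dict[str, str]]:
    """Genome ({chrom: seq}), CDS models (alternating strands, 1-2 exons) and
    protein sequences keyed by accession.  Deterministic per seed."""
    rng = _rng(config, 1)
    genome = list("".join(rng.choice(list("ACGT"), size=config.genome_length)))
    models: list[CDSModel] = []
    proteins: dict[str, str] = {}
    for i, spec in enumerate(config.planted):
        cds = _build_cds(spec, config, rng)
        strand = "+" if i % 2 == 0 else "-"
        two_exons = i % 3 == 1
        slot = _gene_slot(i, config)
        if two_exons:
            split = 30
            intron = 50
            exons = (
                (slot, slot + split - 1),
                (slot + split + intron, slot + split + intron + len(cds) - split - 1),
            )
        else:
            exons = ((slot, slot + len(cds) - 1),)
        genomic_seq = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        offset = 0
        for start, end in exons:
            length = end - start + 1
            genome[start - 1 : end] = list(genomic_seq[offset : offset + length])
            offset += length
        accession = f"P{spec.gene[-2:]}000"
        model = CDSModel(
            gene_symbol=spec.gene,
            transcript_id=f"{spec.gene}.t1",
            chrom="chr1",
            strand=strand,
            exons=exons,
            protein_accession=accession,
        )
        models.append(model)
        from Bio.Seq import Seq

        protein = str(Seq(cds[:-3]).translate())
        if "*" in protein:
            raise AssertionError("premature stop in synthetic CDS")
        proteins[accession] = protein
    genome_map = {"chr1": "".join(genome)}
    # internal consistency: re-extraction must reproduce each CDS
    for model, spec in zip(models, config.planted):
        extracted = extract_cds(model, genome_map)
        from Bio.Seq import Seq

        if str(Seq(extracted[:-3]).translate()) != proteins[model.protein_accession]:
            raise AssertionError(f"{model.gene_symbol}: genome/protein inconsistency")
    return genome_map, models, proteins


# ---------------------------------------------------------------------------
# population VCF


def _planted_variant_site(
    spec: PlantedVariantSpec, model: CDSModel, genome: dict[str, str]
) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) of the planted SNV inside the CGA codon."""
    if spec.variant_class == "missense":
        cds_pos = 3 * (spec.residue_index - 1) + 2  # CGA -> CAA
        alt_tx = "A"
    elif spec.variant_class == "synonymous":
        cds_pos = 3 * (spec.residue_index - 1) + 3  # CGA -> CGG
        alt_tx = "G"
    else:
        raise ValueError(f"cannot plant coding variant of class {spec.variant_class!r}")
    pos = cds_to_genomic(cds_pos, model)
    ref = genome[model.chrom][pos - 1]
    alt = alt_tx if model.strand == "+" else alt_tx.translate(_COMPLEMENT)
    return pos, ref, alt


def _draw_genotypes(p: float, n: int, rng) -> np.ndarray:
    """Hardy-Weinberg diploid genotype codes (0/1/2 alt copies) for n samples."""
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    return rng.choice(3, size=n, p=probs)


def generate_population_vcf(
    config: SimulationConfig,
    genome: dict[str, str],
    models: Sequence[CDSModel],
    outdir: Path,
) -> tuple[Path, Path, pd.DataFrame]:
    """VCF with per-sample GT, a sample-to-population map, and the truth table.

    Genotypes are drawn under Hardy-Weinberg at the planted per-population
    allele frequencies; one intergenic variant is added when configured.  The
    truth table records each variant's funnel fate computed from the realized
    genotype counts (see module docstring).
    """
    rng = _rng(config, 2)
    outdir = Path(outdir)
    populations = [f"POP{k + 1}" for k in range(config.n_populations)]
    samples = [
        f"{pop}S{j + 1}" for pop in populations for j in range(config.samples_per_population)
    ]
    sample_to_pop = {s: s.split("S")[0] for s in samples}
    model_by_gene = {m.gene_symbol: m for m in models}

    records = []  # (pos, rsid, ref, alt, genotype codes per sample, spec or None)
    for i, spec in enumerate(config.planted):
        model = model_by_gene[spec.gene]
        pos, ref, alt = _planted_variant_site(spec, model, genome)
        codes = np.concatenate(
            [_draw_genotypes(p, config.samples_per_population, rng) for p in spec.pop_afs]
        )
        records.append((pos, f"rs9{i + 1:05d}", ref, alt, codes, spec))
    if config.include_intergenic_variant:
        pos = 50  # upstream of every gene slot
        ref = genome["chr1"][pos - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        codes = np.concatenate(
            [
                _draw_genotypes(0.3, config.samples_per_population, rng)
                for _ in range(config.n_populations)
            ]
        )
        records.append((pos, "rs900000", ref, alt, codes, None))
    records.sort(key=lambda r: r[0])

    vcf_path = outdir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={config.genome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for pos, rsid, ref, alt, codes, _ in records:
            gts = "\t".join(gt_strings[int(c)] for c in codes)
            fh.write(f"chr1\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")

    map_path = outdir / "samples.tsv"
    data_io.write_sample_map(map_path, sample_to_pop)

    truth_rows = []
    for pos, rsid, ref, alt, codes, spec in records:
        fate = _truth_fate(spec, codes, config)
        truth_rows.append(
            {
                "variant": f"chr1:{pos}:{ref}>{alt}",
                "rsid": rsid,
                "gene": spec.gene if spec else ".",
                "expected_stage": fate,
            }
        )
    truth = pd.DataFrame(truth_rows)
    data_io.write_tsv(outdir / "truth.tsv", truth, ["planted funnel fate per variant"])
    return vcf_path, map_path, truth


def _truth_fate(
    spec: Optional[PlantedVariantSpec], codes: np.ndarray, config: SimulationConfig
) -> str:
    """First funnel stage the planted variant fails, from realized genotypes."""
    if spec is None:
        return "coding"
    if spec.variant_class == "synonymous":
        return "nonsynonymous"
    n = config.samples_per_population
    per_pop = [codes[k * n : (k + 1) * n] for k in range(config.n_populations)]
    total_alt = int(codes.sum())
    global_af = total_alt / (2 * len(codes))
    if not 0.005 <= global_af <= 0.995:
        return "af_prevalence"
    if not spec.has_domain_site:
        return "domain_site"
    if not spec.has_structure:
        return "structure"
    if not spec.near_site or spec.buried:
        return "proximity_exposure"
    for pop_codes in per_pop:
        if (pop_codes == 1).mean() <= 0.05:
            return "het_all_pops"
    if not spec.loh_freq > 0.15:
        return "loh"
    if spec.expression < 300:
        return "expression"
    return "passed"


# ---------------------------------------------------------------------------
# structures


def _helix_coords(protein: str) -> list[Residue]:
    """Ideal alpha-helical backbone (rise 1.5 A, 100 deg/residue, CA radius
    2.3 A) with one pseudo side-chain atom (CB) 1.5 A radially out from CA."""
    residues = []
    for i, aa in enumerate(protein):
        theta = math.radians(100.0 * i)
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        ca = 2.3 * radial + np.array([0.0, 0.0, 1.5 * i])
        atoms = [
            Atom("N", "N", ca - 0.7 * tangent + np.array([0, 0, -0.8])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 0.7 * tangent + np.array([0, 0, 0.8])),
            Atom("O", "O", ca + 1.2 * tangent + np.array([0, 0, 1.4])),
            Atom("CB", "C", ca + 1.5 * radial),
        ]
        residues.append(Residue(name=_AA3.get(aa, "UNK"), label=str(i + 1), atoms=tuple(atoms)))
    return residues


def _shell_atoms(center: np.ndarray, radius: float, n: int) -> list[np.ndarray]:
    """Deterministic golden-spiral shell of n points at the given radius."""
    coords = []
    for i in range(n):
        t = (i + 0.5) / n
        phi = math.acos(1 - 2 * t)
        theta = math.pi * (1 + 5**0.5) * (i + 0.5)
        coords.append(
            center
            + radius
            * np.array(
                [math.sin(phi) * math.cos(theta), math.sin(phi) * math.sin(theta), math.cos(phi)]
            )
        )
    return coords


def generate_structure(
    config: SimulationConfig,
    spec: PlantedVariantSpec,
    protein: str,
    verify: bool = True,
) -> StructureChainSet:
    """Toy structure for one gene: helix chain A; chain X shell when buried.

    The planted variant residue is the spec's ``residue_index`` (chosen close
    to the catalytic residue when ``near_site`` else well beyond the proximity
    threshold); geometry (near/far distance, burial) is verified internally
    against brute-force measures.
    """
    residues = _helix_coords(protein)
    chains = [Chain(chain_id="A", residues=tuple(residues))]
    variant_index = spec.residue_index
    if spec.buried:
        target = residues[variant_index - 1]
        center = np.mean([a.coord for a in target.atoms], axis=0)
        shell_residues = []
        label = 1001
        for radius, n in ((6.0, 200), (8.5, 400)):
            for coord in _shell_atoms(center, radius, n):
                shell_residues.append(
                    Residue(name="UNK", label=str(label), atoms=(Atom("C", "C", coord),))
                )
                label += 1
        chains.append(Chain(chain_id="X", residues=tuple(shell_residues)))
    structure = StructureChainSet(
        structure_id=f"synth_{spec.gene}", chains=tuple(chains), ligands=()
    )
    if verify:
        chain_a = structure.chains[0]
        site = chain_a.residues[config.site_residue - 1]
        variant = chain_a.residues[variant_index - 1]
        dist, _ = min_distance_to_sites(variant, [site], "side_chain_heavy")
        if spec.near_site and dist > 10.0:
            raise AssertionError(f"{spec.gene}: planted near residue at {dist:.1f} A")
        if not spec.near_site and dist <= 12.0:
            raise AssertionError(f"{spec.gene}: planted far residue at {dist:.1f} A")
        rsa = relative_accessibility(chain_a, variant, environment=structure.all_atoms())
        if spec.buried and rsa >= 0.05:
            raise AssertionError(f"{spec.gene}: planted buried residue has rsa {rsa:.3f}")
        if not spec.buried and rsa < 0.2:
            raise AssertionError(f"{spec.gene}: planted exposed residue has rsa {rsa:.3f}")
    return structure


def write_pdb(structure: StructureChainSet, path) -> None:
    """Emit ATOM records (PDB fixed columns) for every chain."""
    serial = 1
    with open(path, "w") as fh:
        for chain in structure.chains:
            for residue in chain.residues:
                resnum = int(residue.label) if residue.label.isdigit() else 0
                for atom in residue.atoms:
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                    x, y, z = atom.coord
                    fh.write(
                        f"ATOM  {serial:5d} {name}{'':1s}{residue.name:>3s} "
                        f"{chain.chain_id:1s}{resnum:4d}{'':1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    spec: CohortSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-signal cohort table and its per-patient truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    n = spec.n_patients
    if spec.het_frequency is not None:
        is_het = rng.random(n) < spec.het_frequency
    else:
        if spec.n_het > n:
            raise ValueError("n_het cannot exceed n_patients")
        is_het = np.zeros(n, dtype=bool)
        is_het[rng.choice(n, size=spec.n_het, replace=False)] = True
    # non-heterozygotes split between the two homozygote classes
    hom_alt = (~is_het) & (rng.random(n) < 0.5)
    het_index = np.flatnonzero(is_het)
    loh = np.zeros(n, dtype=bool)
    if spec.loh_rate is not None:
        loh[het_index] = rng.random(len(het_index)) < spec.loh_rate
    else:
        if spec.n_loh > len(het_index):
            raise ValueError("n_loh cannot exceed the number of heterozygotes")
        loh[rng.choice(het_index, size=spec.n_loh, replace=False)] = True
    retains_ref = rng.random(n) < 0.5  # both alleles equally likely to be lost

    b = spec.base_signal
    normal_ref = np.where(is_het, b, np.where(hom_alt, 0.0, 2 * b))
    normal_alt = np.where(is_het, b, np.where(hom_alt, 2 * b, 0.0))
    tumor_ref = normal_ref.copy()
    tumor_alt = normal_alt.copy()
    major = 2 * b * (1 - spec.loh_minor_fraction)
    minor = 2 * b * spec.loh_minor_fraction
    tumor_ref[loh] = np.where(retains_ref[loh], major, minor)
    tumor_alt[loh] = np.where(retains_ref[loh], minor, major)
    if spec.signal_sd > 0:
        noise = rng.normal(0.0, spec.signal_sd, size=(4, n))
        normal_ref = np.clip(normal_ref + noise[0], 0, None)
        normal_alt = np.clip(normal_alt + noise[1], 0, None)
        tumor_ref = np.clip(tumor_ref + noise[2], 0, None)
        tumor_alt = np.clip(tumor_alt + noise[3], 0, None)
    stages = rng.choice(["II", "III", "IV"], size=n)

    patients = [f"PT{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "patient": patients,
            "locus": spec.locus,
            "normal_ref": normal_ref,
            "normal_alt": normal_alt,
            "tumor_ref": tumor_ref,
            "tumor_alt": tumor_alt,
            "stage": stages,
        }
    )
    truth = pd.DataFrame(
        {
            "patient": patients,
            "genotype": np.where(is_het, "het", np.where(hom_alt, "hom_alt", "hom_ref")),
            "loh": loh,
            "retained_allele": np.where(loh, np.where(retains_ref, "ref", "alt"), "."),
        }
    )
    return frame, truth


# ---------------------------------------------------------------------------
# everything together


def generate_all(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write the full fixture set consumed by the funnel and cohort analysis.

    Emits genome.fa, proteins.fa, cds.tsv, variants.vcf, samples.tsv,
    structure_<gene>.pdb, domains.tsv, expression.tsv, loh_freq.tsv,
    cohort.tsv, truth.tsv and cohort_truth.tsv under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models, proteins = generate_reference(config)
    data_io.write_fasta(outdir / "genome.fa", genome)
    data_io.write_fasta(outdir / "proteins.fa", proteins)
    data_io.write_cds_models(outdir / "cds.tsv", models)
    vcf_path, map_path, truth = generate_population_vcf(config, genome, models, outdir)

    domains = []
    structure_paths: dict[str, Path] = {}
    model_by_gene = {m.gene_symbol: m for m in models}
    for spec in config.planted:
        accession = model_by_gene[spec.gene].protein_accession
        sites = (
            ((config.site_residue, "catalytic"),) if spec.has_domain_site else ()
        )
        domains.append(
            DomainAnnotation(
                protein_accession=accession,
                domain_id=f"DOM_{spec.gene}",
                domain_start=2,
                domain_end=config.protein_length - 1,
                site_residues=sites,
            )
        )
        if spec.has_structure:
            structure = generate_structure(config, spec, proteins[accession])
            path = outdir / f"structure_{spec.gene}.pdb"
            write_pdb(structure, path)
            structure_paths[accession] = path
    data_io.write_domain_annotations(outdir / "domains.tsv", domains)

    expression = pd.DataFrame(
        {
            "gene": [s.gene for s in config.planted],
            config.tissue: [s.expression for s in config.planted],
            "liver": [400.0] * len(config.planted),
        }
    ).set_index("gene")
    data_io.write_expression(outdir / "expression.tsv", expression)
    loh_table = pd.DataFrame(
        {
            "gene": [s.gene for s in config.planted],
            "cancer_type": [config.cancer_type] * len(config.planted),
            "lf": [s.loh_freq for s in config.planted],
        }
    )
    data_io.write_loh_frequencies(outdir / "loh_freq.tsv", loh_table)

    cohort, cohort_truth = generate_cohort(config.cohort, seed=config.seed)
    data_io.write_cohort(outdir / "cohort.tsv", cohort)
    data_io.write_tsv(outdir / "cohort_truth.tsv", cohort_truth, ["planted cohort truth"])

    paths = {
        "genome": outdir / "genome.fa",
        "proteins": outdir / "proteins.fa",
        "cds": outdir / "cds.tsv",
        "variants": vcf_path,
        "samples": map_path,
        "domains": outdir / "domains.tsv",
        "expression": outdir / "expression.tsv",
        "loh_freq": outdir / "loh_freq.tsv",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.tsv",
        "cohort_truth": outdir / "cohort_truth.tsv",
    }
    paths.update({f"structure_{acc}": p for acc, p in structure_paths.items()})
    return paths
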