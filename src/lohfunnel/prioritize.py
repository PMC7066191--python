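"""The target-discovery funnel: from population SNVs to eligible-patient counts.

Stages, applied in order, each recording the first failure per variant:

1. ``coding``              variant falls in a coding exon of some transcript
2. ``nonsynonymous``       the substitution changes the encoded amino acid
3. ``af_prevalence``       pooled allele frequency within [af_low, af_high]
4. ``domain_site``         residue inside a functional domain with annotated sites
5. ``structure``           a crystal structure of the protein is available
6. ``proximity_exposure``  surface-exposed residue close to a functional site
7. ``het_all_pops``        heterozygosity > threshold in every population
8. ``loh``                 locus lost in > min_loh of tumors of the cancer type
9. ``expression``          gene expressed (>= min_expression) in the tissue of origin

Surviving variants are aggregated per gene; each candidate gene carries the
eligible-patient estimate EP = 0.5 * HF * LF * I, where HF is the heterozygote
frequency of the variant in the reference panel, LF the LOH frequency of the
locus in the cancer type, I the yearly incidence, and the factor 0.5 reflects
that only one of the two alleles is an exploitable target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import popgen
from .data_io import CDSModel, DomainAnnotation, Variant
from .consequence import annotate_all
from .structmap import ProximityResult, StructureChainSet, evaluate_variant_on_structures

logger = logging.getLogger(__name__)

STAGES = (
    "coding",
    "nonsynonymous",
    "af_prevalence",
    "domain_site",
    "structure",
    "proximity_exposure",
    "het_all_pops",
    "loh",
    "expression",
)

__all__ = [
    "STAGES",
    "FunnelConfig",
    "CandidateTarget",
    "FunnelResult",
    "eligible_patients",
    "expression_filter",
    "loh_filter",
    "run_funnel",
]


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds and cohort constants of one funnel run.

    Boundary conventions mirror the filter definitions: the allele-frequency
    prevalence band is inclusive at both ends; the per-population
    heterozygosity and the LOH-frequency filters are strict (>); the
    expression filter keeps scores at or above ``min_expression``.
    """

    af_low: float = 0.005
    af_high: float = 0.995
    min_het_all_pops: float = 0.05
    het_metric: str = "observed"
    d_max: float = 10.0  # Angstrom
    rsa_min: float = 0.2
    atom_set: str = "side_chain_heavy"
    min_expression: float = 300.0
    min_loh: float = 0.15
    cancer_type: str = "colorectal"
    tissue: str = "colon"
    incidence: float = 1_400_000.0  # cases / year
    hf_pooling: str = "pooled"  # or "max_population"
    sasa_points: int = 960

    def __post_init__(self):
        if not 0 <= self.af_low <= self.af_high <= 1:
            raise ValueError("AF band must satisfy 0 <= af_low <= af_high <= 1")
        if self.incidence < 0:
            raise ValueError("incidence must be >= 0")
        if self.hf_pooling not in ("pooled", "max_population"):
            raise ValueError("hf_pooling must be 'pooled' or 'max_population'")


@dataclass
class CandidateTarget:
    """A gene surviving every funnel stage, with its eligible-patient estimate."""

    gene_symbol: str
    variants: list[dict] = field(default_factory=list)  # all passing variant rows
    hf: float = 0.0
    lf: float = 0.0
    ep: float = 0.0
    best_distance: float = float("inf")
    best_variant_key: str = ""


@dataclass
class FunnelResult:
    candidates: list[CandidateTarget]
    report: pd.DataFrame  # stage, n_in, n_out
    trace: pd.DataFrame  # one row per variant: terminal state

    def candidate_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": c.gene_symbol,
                "n_passing_variants": len(c.variants),
                "best_variant": c.best_variant_key,
                "min_site_distance": c.best_distance,
                "hf": c.hf,
                "lf": c.lf,
                "ep": c.ep,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "n_passing_variants", "best_variant",
                "min_site_distance", "hf", "lf", "ep",
            ],
        )


def eligible_patients(hf: float, lf: float, incidence: float) -> float:
    """EP = 0.5 * HF * LF * I eligible patients per year.

    The 0.5 factor assumes only one of the two alleles is an exploitable
    therapeutic target, so half of the LOH events lose the wrong allele.
    """
    if not 0 <= hf <= 1:
        raise ValueError(f"HF must lie in [0, 1], got {hf}")
    if not 0 <= lf <= 1:
        raise ValueError(f"LF must lie in [0, 1], got {lf}")
    if incidence < 0:
        raise ValueError(f"incidence must be >= 0, got {incidence}")
    return 0.5 * hf * lf * incidence


def expression_filter(
    gene: str,
    tissue: str,
    expression: pd.DataFrame,
    min_expression: float = 300.0,
) -> tuple[bool, str]:
    """Keep iff the gene's expression in the tissue is >= min_expression.

    Genes absent from the table (or without the tissue column) are dropped
    with a ``no data`` status: an unexpressed target cannot be validated.
    """
    if tissue not in expression.columns:
        raise KeyError(f"tissue column {tissue!r} not in expression table")
    if gene not in expression.index:
        return False, "no data"
    value = float(expression.loc[gene, tissue])
    return (value >= min_expression), f"expression={value:g}"


def loh_filter(
    gene: str,
    cancer_type: str,
    loh_table: pd.DataFrame,
    min_loh: float = 0.15,
) -> tuple[bool, float]:
    """Keep iff LOH frequency strictly exceeds min_loh for the cancer type."""
    rows = loh_table[(loh_table["gene"] == gene) & (loh_table["cancer_type"] == cancer_type)]
    if rows.empty:
        return False, float("nan")
    lf = float(rows["lf"].iloc[0])
    return (lf > min_loh), lf


def _variant_hf(stats: popgen.PopulationStats, config: FunnelConfig) -> float:
    if config.hf_pooling == "pooled":
        return stats.global_hf
    return max(f.hf_obs for f in stats.per_population.values())


def run_funnel(
    variants: Sequence[Variant],
    models: Sequence[CDSModel],
    cds_sequences: Mapping[str, str],
    protein_sequences: Mapping[str, str],
    domains: Sequence[DomainAnnotation],
    structures: Mapping[str, Sequence[StructureChainSet]],
    expression: pd.DataFrame,
    loh_table: pd.DataFrame,
    config: FunnelConfig = FunnelConfig(),
) -> FunnelResult:
    """Run every funnel stage and assemble candidates, report and trace.

    ``structures`` maps protein accession to the available structure chain
    sets.  Every input variant ends in exactly one terminal state: ``passed``
    or the name of the single stage where it first failed.
    """
    for name, table in (("expression", expression), ("loh", loh_table)):
        if table is None:
            raise ValueError(f"missing required input table for stage {name!r}")

    consequences = annotate_all(variants, models, cds_sequences)
    domains_by_protein: dict[str, list[DomainAnnotation]] = {}
    for domain in domains:
        domains_by_protein.setdefault(domain.protein_accession, []).append(domain)

    trace_rows = []
    # (gene, variant) contexts surviving to gene-level aggregation
    survivors: list[dict] = []
    for variant in variants:
        vkey = variant.key
        rows = consequences[
            (consequences["chrom"] == variant.chrom)
            & (consequences["pos"] == variant.pos)
            & (consequences["alt"] == variant.alt_allele)
        ]
        record = {
            "variant": vkey,
            "rsid": variant.rsid or ".",
            "gene": rows["gene"].iloc[0] if len(rows) else ".",
            "stage_failed": "",
            "status": "",
        }

        def fail(stage: str, status: str = "") -> None:
            record["stage_failed"] = stage
            record["status"] = status
            trace_rows.append(record)

        if rows.empty:
            fail("coding", "no overlapping coding exon")
            continue
        missense = rows[rows["consequence"] == "missense"]
        if missense.empty:
            fail("nonsynonymous", f"classes: {','.join(sorted(set(rows['consequence'])))}")
            continue
        stats = popgen.compute_stats(variant)
        if not popgen.af_prevalence_filter(stats, config.af_low, config.af_high):
            fail("af_prevalence", f"global_af={stats.global_af:.4g}")
            continue
        # evidence is preserved per transcript; the variant proceeds when any
        # transcript context passes the structural stages
        contexts = []
        domain_hit = structure_hit = proximity_hit = False
        best_prox: Optional[ProximityResult] = None
        best_ctx = None
        for row in missense.itertuples(index=False):
            accession = row.protein_accession
            residue_index = int(row.residue_index)
            sites = [
                i
                for dom in domains_by_protein.get(accession, [])
                if dom.site_residues and dom.contains_residue(residue_index)
                for i, _ in dom.site_residues
            ]
            if not sites:
                continue
            domain_hit = True
            available = structures.get(accession, ())
            if not available:
                continue
            structure_hit = True
            prox = evaluate_variant_on_structures(
                accession,
                protein_sequences[accession],
                residue_index,
                sorted(set(sites)),
                available,
                atom_set=config.atom_set,
                d_max=config.d_max,
                rsa_min=config.rsa_min,
                n_points=config.sasa_points,
            )
            if prox is None:
                continue
            if prox.selected:
                proximity_hit = True
                if best_prox is None or prox.min_site_distance < best_prox.min_site_distance:
                    best_prox, best_ctx = prox, row
            contexts.append((row, prox))
        if not domain_hit:
            fail("domain_site", "no domain with annotated sites at residue")
            continue
        if not structure_hit:
            fail("structure", "no structure for protein")
            continue
        if not proximity_hit:
            detail = (
                f"d={contexts[-1][1].min_site_distance:.1f}A rsa={contexts[-1][1].rsa:.2f}"
                if contexts
                else "variant residue not resolved in any chain"
            )
            fail("proximity_exposure", detail)
            continue
        if not popgen.het_all_populations_filter(
            stats, config.min_het_all_pops, config.het_metric
        ):
            fail("het_all_pops", "heterozygosity <= threshold in some population")
            continue
        gene = best_ctx.gene
        loh_keep, lf = loh_filter(gene, config.cancer_type, loh_table, config.min_loh)
        if not loh_keep:
            fail("loh", f"lf={lf:.3g}")
            continue
        expr_keep, expr_status = expression_filter(
            gene, config.tissue, expression, config.min_expression
        )
        if not expr_keep:
            fail("expression", expr_status)
            continue
        record["stage_failed"] = "passed"
        record["gene"] = gene
        trace_rows.append(record)
        survivors.append(
            {
                "gene": gene,
                "variant": vkey,
                "rsid": variant.rsid or ".",
                "hf": _variant_hf(stats, config),
                "lf": lf,
                "distance": best_prox.min_site_distance,
                "rsa": best_prox.rsa,
                "structure": best_prox.structure_id,
                "chain": best_prox.chain_id,
                "residue_index": best_prox.residue_index,
            }
        )

    trace = pd.DataFrame(
        trace_rows, columns=["variant", "rsid", "gene", "stage_failed", "status"]
    )

    # stage report: survivors entering/leaving each stage
    n_in = len(variants)
    report_rows = []
    for stage in STAGES:
        n_failed = int((trace["stage_failed"] == stage).sum()) if len(trace) else 0
        n_out = n_in - n_failed
        report_rows.append({"stage": stage, "n_in": n_in, "n_out": n_out})
        logger.info("funnel stage %-18s %6d -> %6d", stage, n_in, n_out)
        n_in = n_out
    report = pd.DataFrame(report_rows, columns=["stage", "n_in", "n_out"])

    # gene-level aggregation: rank by the best (minimum-distance) variant
    by_gene: dict[str, CandidateTarget] = {}
    for row in survivors:
        candidate = by_gene.setdefault(row["gene"], CandidateTarget(gene_symbol=row["gene"]))
        candidate.variants.append(row)
        if row["distance"] < candidate.best_distance:
            candidate.best_distance = row["distance"]
            candidate.best_variant_key = row["variant"]
            candidate.hf = row["hf"]
            candidate.lf = row["lf"]
    for candidate in by_gene.values():
        candidate.ep = eligible_patients(candidate.hf, candidate.lf, config.incidence)
    candidates = sorted(by_gene.values(), key=lambda c: (-c.ep, c.gene_symbol))
    return FunnelResult(candidates=candidates, report=report, trace=trace)
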