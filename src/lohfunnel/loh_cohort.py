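"""Paired tumor-normal LOH analysis from allele-signal intensities.

Sanger chromatogram peaks are abstracted to two non-negative intensities per
sample (reference and alternate allele).  The normal tissue gives the
constitutional genotype; only constitutional heterozygotes are informative for
loss of heterozygosity, and a tumor is called LOH when its minor-allele signal
fraction collapses below a loss threshold.  Contaminating normal tissue in the
tumor sample biases the minor-allele fraction upward (tumor purity is not
modelled), so the default threshold is deliberately permissive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PairedSample",
    "LOHCall",
    "CohortSummary",
    "call_constitutional_genotype",
    "call_loh",
    "cohort_summary",
    "calls_from_frame",
    "calls_to_frame",
]

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class PairedSample:
    """One patient x locus pair of normal and tumor allele signals."""

    patient_id: str
    locus: str
    normal_signals: tuple[float, float]  # (ref, alt) intensities
    tumor_signals: tuple[float, float]
    stage: Optional[str] = None

    def __post_init__(self):
        for label, signals in (("normal", self.normal_signals), ("tumor", self.tumor_signals)):
            if min(signals) < 0:
                raise ValueError(f"{self.patient_id}/{self.locus}: negative {label} signal")
        if max(self.normal_signals) <= 0 and max(self.tumor_signals) <= 0:
            raise ValueError(f"{self.patient_id}/{self.locus}: all signals zero")


@dataclass(frozen=True)
class LOHCall:
    patient_id: str
    locus: str
    normal_genotype: str  # hom_ref | het | hom_alt | no_call
    verdict: str  # LOH | no_LOH | non_informative
    retained_allele: Optional[str] = None  # 'ref' / 'alt', set only for LOH
    lost_allele: Optional[str] = None
    stage: Optional[str] = None
    status: str = ""

    def __post_init__(self):
        if self.normal_genotype != "het" and self.verdict == "LOH":
            raise ValueError("LOH verdict requires a heterozygous normal genotype")
        if self.verdict == "LOH" and self.retained_allele == self.lost_allele:
            raise ValueError("retained and lost allele must differ")


def call_constitutional_genotype(
    signals: tuple[float, float], het_band: tuple[float, float] = (0.3, 0.7)
) -> str:
    """Genotype from normal-tissue allele signals.

    Heterozygous when the alternate-allele signal fraction lies inside the het
    band (inclusive); otherwise the homozygote of the dominant allele.  Both
    signals zero -> ``no_call``.
    """
    s_ref, s_alt = signals
    total = s_ref + s_alt
    if total <= 0:
        return "no_call"
    alt_fraction = s_alt / total
    if het_band[0] <= alt_fraction <= het_band[1]:
        return "het"
    return "hom_alt" if alt_fraction > het_band[1] else "hom_ref"


def call_loh(
    pair: PairedSample,
    het_band: tuple[float, float] = (0.3, 0.7),
    loss_threshold: float = 0.15,
) -> LOHCall:
    """LOH verdict for one paired sample.

    Only constitutional heterozygotes are informative.  LOH is called when the
    tumor minor-allele signal fraction is <= ``loss_threshold``; the retained
    allele is the tumor's dominant allele.
    """
    normal_gt = call_constitutional_genotype(pair.normal_signals, het_band)
    if normal_gt != "het":
        return LOHCall(
            patient_id=pair.patient_id,
            locus=pair.locus,
            normal_genotype=normal_gt,
            verdict="non_informative",
            stage=pair.stage,
            status="normal not heterozygous" if normal_gt != "no_call" else "normal no-call",
        )
    t_ref, t_alt = pair.tumor_signals
    total = t_ref + t_alt
    if total <= 0:
        return LOHCall(
            patient_id=pair.patient_id,
            locus=pair.locus,
            normal_genotype=normal_gt,
            verdict="non_informative",
            stage=pair.stage,
            status="tumor no-call",
        )
    minor_fraction = min(t_ref, t_alt) / total
    if minor_fraction <= loss_threshold:
        retained = "ref" if t_ref >= t_alt else "alt"
        return LOHCall(
            patient_id=pair.patient_id,
            locus=pair.locus,
            normal_genotype=normal_gt,
            verdict="LOH",
            retained_allele=retained,
            lost_allele="alt" if retained == "ref" else "ref",
            stage=pair.stage,
        )
    return LOHCall(
        patient_id=pair.patient_id,
        locus=pair.locus,
        normal_genotype=normal_gt,
        verdict="no_LOH",
        stage=pair.stage,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level LOH frequency with genotype and retained-allele bookkeeping.

    ``lf`` is the LOH frequency among informative (constitutionally
    heterozygous) patients with its Wilson 95% binomial interval;
    ``lf_all_patients`` uses all genotyped patients as denominator, since
    published "percent LOH" figures are sometimes quoted either way.
    """

    n_patients: int
    genotype_distribution: dict[str, int]
    n_het: int
    n_loh: int
    lf: Optional[float]
    lf_ci: Optional[tuple[float, float]]
    lf_all_patients: float
    retained_allele_counts: dict[str, int]
    per_stage: dict[str, dict[str, int]]

    @property
    def retained_allele_fractions(self) -> dict[str, float]:
        total = sum(self.retained_allele_counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.retained_allele_counts.items()}


def cohort_summary(calls: Sequence[LOHCall]) -> CohortSummary:
    """Summarise per-patient LOH calls into cohort-level statistics."""
    if not calls:
        raise ValueError("no LOH calls to summarise")
    genotype_distribution = {g: 0 for g in (*GENOTYPES, "no_call")}
    retained = {"ref": 0, "alt": 0}
    per_stage: dict[str, dict[str, int]] = {}
    n_het = n_loh = 0
    for call in calls:
        genotype_distribution[call.normal_genotype] += 1
        if call.normal_genotype == "het" and call.status != "tumor no-call":
            n_het += 1
            if call.verdict == "LOH":
                n_loh += 1
                retained[call.retained_allele] += 1
        if call.stage is not None:
            bucket = per_stage.setdefault(
                str(call.stage), {"n": 0, "n_het": 0, "n_loh": 0}
            )
            bucket["n"] += 1
            if call.normal_genotype == "het":
                bucket["n_het"] += 1
                if call.verdict == "LOH":
                    bucket["n_loh"] += 1
    if n_het > 0:
        lf = n_loh / n_het
        low, high = proportion_confint(n_loh, n_het, alpha=0.05, method="wilson")
        lf_ci = (float(low), float(high))
    else:
        lf, lf_ci = None, None
    return CohortSummary(
        n_patients=len(calls),
        genotype_distribution=genotype_distribution,
        n_het=n_het,
        n_loh=n_loh,
        lf=lf,
        lf_ci=lf_ci,
        lf_all_patients=n_loh / len(calls),
        retained_allele_counts=retained,
        per_stage=per_stage,
    )


def calls_from_frame(
    frame: pd.DataFrame,
    het_band: tuple[float, float] = (0.3, 0.7),
    loss_threshold: float = 0.15,
) -> list[LOHCall]:
    """Apply :func:`call_loh` to every row of a cohort table."""
    calls = []
    for row in frame.itertuples(index=False):
        stage = getattr(row, "stage", None)
        pair = PairedSample(
            patient_id=str(row.patient),
            locus=str(row.locus),
            normal_signals=(float(row.normal_ref), float(row.normal_alt)),
            tumor_signals=(float(row.tumor_ref), float(row.tumor_alt)),
            stage=None if stage is None or pd.isna(stage) else str(stage),
        )
        calls.append(call_loh(pair, het_band=het_band, loss_threshold=loss_threshold))
    return calls


def calls_to_frame(calls: Sequence[LOHCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient": c.patient_id,
                "locus": c.locus,
                "normal_genotype": c.normal_genotype,
                "verdict": c.verdict,
                "retained_allele": c.retained_allele or ".",
                "lost_allele": c.lost_allele or ".",
                "stage": c.stage or ".",
                "status": c.status,
            }
            for c in calls
        ]
    )
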