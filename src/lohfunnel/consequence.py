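"""Genomic SNVs to protein-level consequences through CDS models.

Coding positions are translated with the standard nuclear genetic code; for
minus-strand transcripts the variant allele is reverse-complemented before the
codon substitution.  A substitution inside the stop codon that yields a
different stop is synonymous (the amino-acid sequence is unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .data_io import CDSModel, Variant

__all__ = [
    "ProteinConsequence",
    "ReferenceMismatchError",
    "genomic_to_cds",
    "cds_to_genomic",
    "extract_cds",
    "call_consequence",
    "annotate_all",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONSEQUENCE_CLASSES = ("synonymous", "missense", "stop_gain", "stop_loss", "non_coding")


class ReferenceMismatchError(ValueError):
    """The VCF reference allele disagrees with the coding sequence: the
    genome build, CDS model and variant call set are inconsistent."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class ProteinConsequence:
    variant: Variant
    transcript_id: str
    protein_accession: str
    cds_position: int  # 1-based coding-nucleotide offset
    residue_index: int  # 1-based
    ref_codon: str
    alt_codon: str
    ref_aa: str  # one-letter, '*' for stop
    alt_aa: str
    consequence_class: str

    def __post_init__(self):
        if self.residue_index != math.ceil(self.cds_position / 3):
            raise ValueError("residue_index inconsistent with cds_position")
        diffs = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
        if diffs != 1:
            raise ValueError("codons must differ at exactly one position")


def genomic_to_cds(pos: int, model: CDSModel) -> Optional[int]:
    """1-based coding-nucleotide offset of a genomic position, or None when
    the position is not exonic (non-coding is a value, not an error).

    On the + strand coding positions count exonic bases left to right; on the
    - strand, right to left.
    """
    if pos < 1:
        raise ValueError("pos must be >= 1")
    forward = 0
    found = False
    for start, end in model.exons:
        if pos > end:
            forward += end - start + 1
        elif pos >= start:
            forward += pos - start + 1
            found = True
            break
        else:
            break
    if not found:
        return None
    if model.strand == "+":
        return forward
    return model.total_length - forward + 1


def cds_to_genomic(cds_position: int, model: CDSModel) -> int:
    """Inverse of :func:`genomic_to_cds` for exonic coding positions."""
    if not 1 <= cds_position <= model.total_length:
        raise ValueError(f"cds_position {cds_position} outside CDS of length {model.total_length}")
    forward = (
        cds_position if model.strand == "+" else model.total_length - cds_position + 1
    )
    remaining = forward
    for start, end in model.exons:
        length = end - start + 1
        if remaining <= length:
            return start + remaining - 1
        remaining -= length
    raise AssertionError("unreachable: forward offset inside total_length")


def extract_cds(model: CDSModel, genome: Mapping[str, str] | str) -> str:
    """Spliced coding sequence (sense strand, stop codon included) of a model
    from a genome given as {chrom: sequence} or a single chromosome string."""
    chrom_seq = genome if isinstance(genome, str) else genome[model.chrom]
    parts = [chrom_seq[start - 1 : end] for start, end in model.exons]
    seq = "".join(parts)
    return _revcomp(seq) if model.strand == "-" else seq


def call_consequence(
    variant: Variant, model: CDSModel, coding_sequence: str
) -> Optional[ProteinConsequence]:
    """Protein consequence of an SNV on one transcript; None if non-coding.

    Raises :class:`ReferenceMismatchError` when the variant's reference allele
    does not match the coding sequence at the mapped position (corrupt inputs).
    """
    if len(coding_sequence) != model.total_length:
        raise ValueError(
            f"{model.transcript_id}: coding sequence length {len(coding_sequence)} "
            f"!= model length {model.total_length}"
        )
    if variant.chrom != model.chrom:
        return None
    cds_pos = genomic_to_cds(variant.pos, model)
    if cds_pos is None:
        return None
    coding_sequence = coding_sequence.upper()
    if model.strand == "+":
        ref_tx, alt_tx = variant.ref_allele, variant.alt_allele
    else:
        ref_tx = variant.ref_allele.translate(_COMPLEMENT)
        alt_tx = variant.alt_allele.translate(_COMPLEMENT)
    if coding_sequence[cds_pos - 1] != ref_tx:
        raise ReferenceMismatchError(
            f"{variant.key} on {model.transcript_id}: expected {ref_tx} at CDS "
            f"position {cds_pos}, found {coding_sequence[cds_pos - 1]}"
        )
    residue_index = math.ceil(cds_pos / 3)
    codon_start = 3 * (residue_index - 1)
    ref_codon = coding_sequence[codon_start : codon_start + 3]
    offset = cds_pos - 1 - codon_start
    alt_codon = ref_codon[:offset] + alt_tx + ref_codon[offset + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if ref_aa == alt_aa:
        cls = "synonymous"
    elif ref_aa == "*":
        cls = "stop_loss"
    elif alt_aa == "*":
        cls = "stop_gain"
    else:
        cls = "missense"
    return ProteinConsequence(
        variant=variant,
        transcript_id=model.transcript_id,
        protein_accession=model.protein_accession,
        cds_position=cds_pos,
        residue_index=residue_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence_class=cls,
    )


def annotate_all(
    variants: Iterable[Variant],
    models: Sequence[CDSModel],
    cds_sequences: Mapping[str, str],
) -> pd.DataFrame:
    """One row per (variant, overlapping transcript) protein consequence.

    Variants hitting no model (or only non-exonic positions) are absent; rows
    are ordered deterministically by (chrom, pos, alt, transcript).
    """
    rows = []
    for variant in variants:
        for model in models:
            if model.chrom != variant.chrom or not model.contains(variant.pos):
                continue
            result = call_consequence(variant, model, cds_sequences[model.transcript_id])
            if result is None:
                continue
            rows.append(
                {
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref_allele,
                    "alt": variant.alt_allele,
                    "rsid": variant.rsid or ".",
                    "gene": model.gene_symbol,
                    "transcript": model.transcript_id,
                    "protein_accession": model.protein_accession,
                    "cds_position": result.cds_position,
                    "residue_index": result.residue_index,
                    "ref_codon": result.ref_codon,
                    "alt_codon": result.alt_codon,
                    "ref_aa": result.ref_aa,
                    "alt_aa": result.alt_aa,
                    "consequence": result.consequence_class,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "rsid", "gene", "transcript",
            "protein_accession", "cds_position", "residue_index",
            "ref_codon", "alt_codon", "ref_aa", "alt_aa", "consequence",
        ],
    )
    return frame.sort_values(["chrom", "pos", "alt", "transcript"]).reset_index(drop=True)
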