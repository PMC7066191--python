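# lohfunnel

Tumors frequently lose one parental copy of whole chromosome arms (loss of
heterozygosity, LOH). When the lost allele encoded an enzyme activity that the
patient's normal cells retain, a cytotoxic substrate of that enzyme kills the
tumor selectively — the normal tissue detoxifies the drug, the tumor cannot.
`lohfunnel` implements the computational discovery side of that strategy for
structural bioinformaticians and cancer genomicists: a filtering funnel that
walks from population variant calls down to a ranked list of candidate enzyme
targets, plus the paired tumor–normal analysis used to validate a candidate's
LOH frequency in a patient cohort.

## The funnel

Starting from biallelic SNVs with per-population genotypes, the pipeline keeps
a variant only if, in order:

1. it falls in a coding exon (CCDS-like transcript models, both strands);
2. it changes the encoded amino acid (standard genetic code; on minus-strand
   transcripts the allele is reverse-complemented before codon substitution);
3. its pooled allele frequency lies in [0.005, 0.995];
4. the substituted residue lies in a functional domain with annotated
   catalytic / substrate-binding / cofactor-binding residues;
5. a crystal structure of the protein is available;
6. on that structure the residue is surface-exposed (relative solvent
   accessibility ≥ 0.2 by Shrake–Rupley sampling) and within 10 Å of a
   functional-site residue (minimum over all atom pairs, side-chain heavy
   atoms);
7. heterozygote frequency exceeds 5% in **every** population;
8. the locus shows > 15% LOH frequency in the configured cancer type;
9. the gene is expressed (score ≥ 300) in the tissue of origin.

Each surviving gene gets an eligible-patient estimate

```
EP = 0.5 × HF × LF × I
```

with HF the heterozygote frequency in the reference panel, LF the LOH
frequency in the cancer type, I the yearly incidence of that cancer, and the
factor 0.5 because only one of the two alleles is an exploitable target.

## LOH calling in paired tumor–normal cohorts

`lohfunnel.loh_cohort` abstracts Sanger peaks as two allele-signal
intensities per sample. Normal tissue gives the constitutional genotype
(heterozygous when the alternate-allele fraction is within [0.3, 0.7]); only
heterozygotes are informative. A tumor is called LOH when its minor-allele
fraction collapses to ≤ 0.15, with retained/lost allele bookkeeping. The
cohort summary reports the LOH frequency among heterozygotes with a Wilson
95% interval, the retained-allele split, and per-stage breakdowns.

## Worked example

Everything runs from synthetic fixtures with planted ground truth — no
downloads. The generator plants one gene that passes every stage and one
single-stage failure per filter:

```sh
lohfunnel simulate --seed 1 --out fixture
lohfunnel funnel --config funnel.yaml --out run     # paths + thresholds in YAML
lohfunnel loh --input fixture/cohort.tsv --out lohrun
```

`run/candidates.tsv` (the planted passing gene, ranked by EP):

```
gene    n_passing_variants  best_variant  min_site_distance  hf    lf   ep
GENE01  1                   chr1:222:G>A  5.890301265639985  0.46  0.3  96600.0
```

Read: the missense variant at chr1:222 substitutes a surface residue 5.9 Å
from the planted catalytic residue; 46% of panel individuals are heterozygous,
the locus is lost in 30% of tumors of the configured cancer type, so at an
incidence of 1.4 M cases/year about 96,600 patients/year would carry a
targetable somatic loss. `run/funnel_report.tsv` lists survivors per stage and
`run/trace.tsv` the single stage at which every other variant fell out.

`lohrun/summary.tsv` for the default 74-patient cohort (30 constitutional
heterozygotes, 2 somatic LOH events):

```
n_patients  74
n_het       30
n_loh       2
lf          0.066667        # ≈7% of informative heterozygotes
lf_ci_low   0.018477
lf_ci_high  0.213235
```

## Scope

The package operates on desk-scale synthetic or user-supplied tables; it does
not fetch 1000 Genomes, CCDS, UniProt, Pfam or PDB releases, does not model
splice/UTR/indel consequences, homology models, ΔΔG stability or tumor
purity, and does not attempt druggability or essentiality scoring. See
`docs/methods.md` for the model details and design decisions.
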