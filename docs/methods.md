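# Methods

## Problem setting

A tumor that has lost one parental allele of a drug-metabolizing enzyme, while
the patient's normal cells retain it, exposes an allele-selective therapeutic
window. Finding such targets is a screening problem over population genetics
(the variant must be common enough that many patients are heterozygous),
protein structure (the substitution must plausibly alter catalysis, i.e. sit
exposed near the active site), and tumor biology (the locus must actually be
lost often, and the gene expressed in the tissue of origin). `lohfunnel`
formalizes that screen as a sequence of pure filters with an auditable
per-variant trace, plus the paired tumor–normal analysis that validates a
candidate's LOH frequency in a real cohort.

## Coordinate and consequence model

Transcripts are CCDS-like exon interval lists (1-based inclusive, sorted by
genomic start regardless of strand) with total length divisible by three; the
protein is one residue shorter than length/3 because the stop codon is
included. Coding positions count exonic bases left-to-right on the plus
strand and right-to-left on the minus strand; `cds_to_genomic` is the exact
inverse on every exonic position (property-tested exhaustively).

Consequences use the standard nuclear genetic code only — every intended
target is a nuclear enzyme. A substitution inside the stop codon that yields a
different stop codon is classified synonymous because the amino-acid sequence
is unchanged. Variants are evaluated once per overlapping transcript; gene
level deduplication happens at prioritization so transcript-level evidence is
never discarded. The implementation substitutes a single codon; the unit and
acceptance tests compare every possible SNV on multi-exon fixtures of both
strands against an independent oracle that re-translates the entire mutated
CDS.

The funnel's "non-synonymous" stage keeps **missense** variants only.
Stop-gain/stop-loss changes are classified and reported, but a truncation is
not an active-site substitution amenable to allele-selective inhibition, so
they do not proceed to the structural stages.

## Population-genetic quantities

All frequencies are computed on called diploid genotypes; missing calls
(`./.`) are tracked but excluded from denominators. For each population:
AF = (het + 2·hom_alt)/(2·called), observed heterozygote frequency
HF = het/called, expected heterozygosity 2·AF·(1−AF). The prevalence band
[0.005, 0.995] is inclusive at both ends; the per-population heterozygosity
filter is strict (> 0.05 in every population) and fails when any population
has no called genotypes. "Heterozygosity" is not further specified in common
usage, so the filter defaults to the observed heterozygote genotype fraction —
the quantity actually available from genotype data — with a switch to expected
2p(1−p). Population presence means AF > 0 (allele observed at all); a
frequency floor is deliberately not applied by default because any floor is
arbitrary, and the presence rule is reported rather than claimed to reproduce
external single-population statistics. The HF used for the eligible-patient
estimate pools heterozygotes across populations (total het / total called),
with a per-population maximum available as a config switch.

## Structural scoring

The historical selection step here was a human looking at structures; the
package replaces it with two measurements and two thresholds, both surfaced
in the report and configurable:

* **Proximity**: minimum Euclidean distance between the variant residue and
  any annotated functional-site residue, minimized over all atom pairs of the
  chosen atom sets (`side_chain_heavy` default; glycine falls back to Cα).
  Default `d_max` = 10 Å — a common structural-biology working definition of
  "close to the active site", roughly two side-chain lengths.
* **Exposure**: relative solvent accessibility (RSA) = residue ASA divided by
  its theoretical Gly-X-Gly maximum (Tien et al. 2013 table, shipped as a
  data file). Default `rsa_min` = 0.2, the conventional buried/exposed
  boundary. ASA uses Shrake–Rupley sampling: 960 deterministic golden-spiral
  points per atom, probe 1.4 Å, Bondi heavy-atom radii. The estimator is
  deterministic for a fixed point count; doubling the points moves fixtures
  by < 0.02 RSA. Values slightly above 1 are possible for exposed termini and
  are left uncapped since only the ≥ rsa_min comparison matters. An
  independent Shrake–Rupley implementation (biotite) serves as a cross-check
  oracle in the test suite.

Sequence-to-structure residue mapping never trusts author numbering: the
protein sequence is globally aligned to the chain's observed residues
(match +1, mismatch −1, gap open −5, extend −0.5 — affine gaps so crystal
gaps cost little while scattered substitutions are punished), and a mapping
below 90% identity over aligned columns is rejected as the wrong chain.
Insertion codes are carried as opaque labels. When several chains or
structures are available, all are evaluated and the minimum distance is kept
(the most permissive reading: any structure showing proximity counts).
Non-water HETATM groups (cofactors such as coenzyme A) are kept apart from
polymer chains; they occlude solvent in RSA but are not distance targets
unless annotated as cofactor-binding sites.

## Funnel assembly

Stages run in the order listed in the README; each variant terminates in
exactly one state — `passed` or the first failing stage — so survivor counts
are non-increasing by construction and the trace partitions the input. The
LOH filter is strict (LF > 0.15) and the expression filter inclusive
(score ≥ 300), matching each criterion's wording; genes absent from either
table are dropped with a `no data` status rather than silently passed.
Candidates are ranked by EP descending, gene symbol as the tie-break, with
each gene represented by its minimum-distance passing variant (all passing
variants are retained in the record). EP = 0.5 × HF × LF × I is an identity,
not an estimate: its linearity in I and its exactness are asserted in tests.

## Paired tumor–normal LOH model

Sanger traces are abstracted to two non-negative intensities per sample.
Constitutional heterozygosity is an alternate-allele fraction inside
[0.3, 0.7] (inclusive); outside the band the sample is the dominant-allele
homozygote. Only heterozygotes are informative. LOH is a tumor minor-allele
fraction ≤ 0.15; the retained allele is the tumor's dominant allele. Both
thresholds are configuration with these stated defaults, because visual peak
scoring has no published numeric rule; raising the loss threshold can only
add LOH calls (tested monotonicity). Tumor purity is not modelled —
contaminating normal tissue biases the tumor minor-allele fraction upward,
making the caller conservative; the summary output carries that note. The
cohort LOH frequency LF = n_LOH/n_het gets a Wilson 95% binomial interval;
because published "percent LOH" figures are quoted against either
denominator, the all-patients fraction is reported alongside.

## Synthetic data: what it emulates and what it does not

The generator produces every input from a single seed, with per-generator
streams derived from the master seed by fixed offsets:

* **Reference**: a random genome (default 6 kb) carrying 10 compact genes
  (20 residues + stop), alternating strands, a mix of single- and two-exon
  models; proteins are emitted from the same codons, and re-extraction plus
  re-translation is verified internally.
* **Panel**: 3 populations × 100 diploid samples, Hardy–Weinberg genotypes at
  planted per-population allele frequencies. The planted set contains one
  gene passing every stage (AF 0.4 in all populations, near + exposed,
  LF 0.30, expression 800) and one failure per stage: a synonymous change, a
  too-rare allele (AF 0.001), a domain without sites, a missing structure, a
  far residue (Δ13 along the helix ≈ 20 Å), a shell-buried residue, a
  single-population allele (0.5/0.004/0.004 — fails the all-populations
  heterozygosity rule), LF 0.10, expression 100, plus one intergenic variant.
  Truth fates for the frequency-dependent stages are recorded from the
  realized draws, and planted frequencies sit far from the thresholds, so the
  truth table is exact under any seed.
* **Structures**: ideal α-helical backbones (rise 1.5 Å, 100°/residue, Cα
  radius 2.3 Å) with one pseudo side-chain atom per residue (CB, 1.5 Å
  radially out from Cα) — sufficient for distance and accessibility logic
  without rotamer modelling. Burial is planted with a two-layer golden-spiral
  carbon shell (radii 6 and 8.5 Å) written as a separate chain so it occludes
  solvent without entering the sequence mapping. All planted geometry is
  verified by brute force at generation time.
* **Cohort**: 74 patients with exactly 30 constitutional heterozygotes and 2
  LOH events by default (rate-based Bernoulli modes available), retained
  allele fair-coin, diploid base signal 100 per allele, Gaussian noise
  sd 5 truncated at zero; LOH collapses the lost allele to 5% of total
  signal. The default sizes mirror a realistic single-marker genotyping
  study; the 3000-heterozygote rate-mode cohort drives the Wilson-coverage
  check.

What passing tests on these fixtures show: the coordinate arithmetic, codon
logic, frequency algebra, geometry, filter ordering and bookkeeping are
correct, and planted signals are recovered exactly or within binomial error.
What they do not show: performance on real data with alignment artifacts,
multi-mapping transcripts, incomplete structures with non-trivial
conformations, population stratification, or impure tumors. The helix
fixtures have no realistic fold, so RSA magnitudes (with single pseudo side
chains) are meaningful only relative to the thresholds, not as predictions
for real proteins.

## Numerical choices and degenerate inputs

* Distances are exact all-pairs minima (no cutoffs); ties broken by the first
  site in residue-index order.
* Shrake–Rupley points are deterministic (golden spiral), so results are
  bit-reproducible; rotation changes RSA by < 0.02 on fixtures (sampling
  anisotropy), far inside the classification margin.
* Alternate locations in PDB input resolve to the highest-occupancy atom;
  residues without heavy atoms are errors for RSA.
* Multiallelic VCF sites split into biallelic records by default (skip mode
  available); genotype counts conserve sample number per population.
* Zero called genotypes across all populations, an empty site list, an empty
  cohort, and a monomorphic site in the population-presence test are errors,
  not silent values; intronic positions are the value `non_coding`, not an
  error.
* The all-heterozygote acceptance check uses 200 seeds × 3000 heterozygotes
  and the default funnel fixture is 11 variants over 10 genes — sizes chosen
  so the full suite and the acceptance script each complete in seconds while
  binomial checks retain power.

## Known limitations

Splice-site, UTR and indel consequences are out of scope; one variant per
gene is planted by the default generator (the pipeline itself handles many);
LOH calling assumes a single informative marker per patient and no copy-number
context; EP treats HF and LF as independent, which overestimates eligibility
if the variant allele and the lost haplotype are correlated.
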