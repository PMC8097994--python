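# Methods

This note records the models, conventions and design choices behind
`mirvar`, in the order the pipeline runs.

## Coordinates and formats

Internal coordinates are 0-based half-open; GFF3 and VCF (1-based
inclusive) are converted at the I/O boundary and emitted tables use
1-based inclusive positions so they can be read next to published miRNA
annotation tables. RNA (U) and DNA (T) alphabets are normalised to DNA
internally, with the original alphabet recorded on read. Multiallelic
VCF records are split and only single-base substitutions are kept —
the analysis is defined for SNPs, and InDels are out of scope. Mature
arms shorter than 8 nt are rejected at parse time because no seed is
definable. The miRNA GFF3 dialect is the miRBase/miRCarta one
(`miRNA_primary_transcript` + `miRNA` with `Derives_from`); arms are
kept in 5′→3′ order of the hairpin, which makes locus round-trips
byte-exact. The annotated hairpin interval is treated as the entire
"precursor" universe; whether an annotation includes flanking pri-miRNA
sequence is a property of the input, not of the pipeline.

## Target-site model

Only 7mer-m8 and 8mer canonical sites are modelled; 6mer, 7mer-A1 and
3′-compensatory site classes are deliberately excluded as weaker
determinants of repression. The scanner works on the spliced 3′UTR
sequence and projects hits to the genome through the block structure, so
a site may span an exon junction. Classification is strict: a match is
an 8mer iff target position 1 (the base 3′ of the match on the mRNA)
exists and is `A`; a match ending at the last UTR base is a 7mer-m8.
Some published pipelines label 8mer-with-mismatch sites as 7mer-m8; this
scanner classifies by the t1 base only and emits both labels, so either
convention can be recovered downstream. Overlapping occurrences are all
reported and counted as occurrences, not merged intervals. Matching is
case-insensitive; windows containing an ambiguous base never match, and
an occurrence whose t1 base is ambiguous is dropped entirely rather than
guessed into a class.

## Hairpin sub-region classification

Mature position p (1-based from the miRNA 5′ end; on the minus strand
the 5′ end is the highest genomic coordinate) determines the five-way
class: p=1 anchor, 2–8 seed, 13–18 supplemental pairing, otherwise
other-mature; hairpin positions outside both arms are precursor. The
supplemental-pairing bounds follow the 13–18 definition (a 13–16 variant
exists in the literature; the wider window is used here). The three-way
labels used in most summaries collapse anchor/supplementary/other into
"mature". A variant covered by two overlapping hairpin annotations is
annotated once per locus with a warning, and sharing summaries
de-duplicate by variant id. Presence of a variant in a population means
the alternative allele was observed in at least one individual of that
group. Percentages are available in both half-up-rounded and truncated
two-decimal renderings because published tables mix the two conventions.

## Density statistics

Region lengths partition exactly: seed (7 bp × number of arms) + mature
(arm length minus seed) + precursor (hairpin minus arms) = total hairpin
length. The density statistic D = N_r × 100 / L_r is exact rational
arithmetic before display rounding (densities to 2 decimals, folds to
1–2). Per-position densities divide by the number of arms of length ≥ p
so short arms do not dilute distal positions. Flanking profiles use 10
bins of 100 bp on each side; bin −1 abuts the hairpin 5′ end in
transcriptional orientation by default (a `genomic` switch uses
left/right instead), and bins overlapping a neighbouring hairpin are
kept. The Mann–Whitney U test uses exact null enumeration when
n₁+n₂ ≤ 20 without ties, otherwise the normal approximation with
mid-ranks, tie correction and 0.5 continuity correction. The sampling
unit for the seed-vs-mature contrast is the per-arm density pair (one
seed and one mature density per arm, compared unpaired); this
construction is a documented package choice, as the original analyses of
this kind rarely state theirs.

## Mixed-model association

The univariate model y = Wα + xδ + u + ε with u ~ MVN(0, λτ⁻¹K) is
fitted by maximum likelihood: K is eigendecomposed once per
missing-data pattern, all vectors are rotated, and for any trial λ the
model is weighted least squares with weights 1/(λdᵢ+1). The ML search
runs over log₁₀λ ∈ [−5, 5] with a 0.1-step grid followed by bounded
Brent refinement to 10⁻⁶. ML (not REML) is used throughout so the
likelihood-ratio test of H₁: δ≠0 vs H₀: δ=0 (χ², 1 df, statistic floored
at 0) is a valid nested comparison. The standard error of δ̂ is taken
from the ML information at the optimum. Kinship is the centered
construction K = XcXcᵀ/p over mean-imputed, mean-centered dosage
columns; for the tested SNP itself, individuals with missing genotype
are excluded from that test and the null is refitted on the same subset.
Fixed-effect factors are reference-coded with the first observed level
as baseline and rank-deficient columns dropped with a warning. The FDR
family defaults to all phenotypes tested for one SNP (a `global` family
is available). Candidate-target filtering requires a 7mer-m8/8mer site
for the SNP's miRNA in the gene's 3′UTR, a validated (miRNA, gene)
interaction in the supplied table, and survival of the expression
presence filter (probe detected in ≥ 50% of samples; a probe at exactly
50% is retained because only probes below threshold in *more than* half
the samples are discarded). Switching both filters off gives the
condition-free whole-transcriptome scan. Probe→gene mapping and
validated interactions are plain input tables; no live database lookups.
Pathway enrichment is a one-sided hypergeometric upper-tail test with BH
correction across pathways, on gene sets supplied as input.

For qPCR, per-sample ΔCt subtracts the arithmetic mean of the control
genes' mean Cts (equivalent to a geometric mean on the expression
scale — the multi-control combination is a package choice), ΔΔCt
subtracts the calibrator-group mean ΔCt, Rq = 2^−ΔΔCt, and groups are
compared by Welch's t-test on log₂Rq.

## Synthetic-data generators

The generators emulate the study conditions rather than generic data:
370 hairpin loci (39 with two arms, giving 409 mature arms and a seed
total of exactly 7 × 409 = 2,863 bp), arm lengths 20–24 nt, hairpins
60–110 bp, strands ~50/50; per-region SNP rates 0.0042 / 0.0086 / 0.0099
per bp (seed / mature / precursor — i.e. the 0.42 / 0.86 / ~1.0 per
100 bp gradient) and a flanking rate of 0.0238 per bp (~2.6-fold above
the hairpin average); four populations with a 15% all-shared fraction
and otherwise random proper subsets; alternative-allele frequencies from
rare-skewed Beta distributions with mean 0.12 (mature/seed) and 0.15
(precursor). 3′UTRs carry planted seed-match sites for a small set of
designated scan arms with distinct seeds, one third of them 8mers;
background sequence is cleaned of accidental motif occurrences by
targeted mutation, so planted-site recovery is exact rather than
probabilistic and scanner tests cannot flake. Half of the planted sites
also receive a SNP so the variant–site intersection is exercised.

The cohort generator gene-drops genotypes from five sires (half-sib
families) plus population-frequency dam alleles, builds K from the
background SNPs, and draws phenotypes from the association model itself
with h² = 0.3 and δ = 0.45 per alternative allele; target-probe
expression decreases with the causal dosage (homozygous-alternative
lowest) and the Ct table encodes a 1.9-fold difference between
homozygous groups with 0.15-cycle technical replicate noise. All
generators are deterministic given the seed; identical seeds give
byte-identical bundles.

What the generators do **not** emulate: linkage disequilibrium beyond
family structure, demographic history, sequencing or genotyping error,
microarray normalisation artefacts, and hairpin secondary structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed model, not robustness to the messiness of
real population data.

## Numerical choices and test scales

The λ search tolerance is 10⁻⁶ on log₁₀λ; kinship matrices are accepted
as PSD down to a −10⁻⁸ relative eigenvalue tolerance, with negative
eigenvalues clipped to zero. A constant SNP vector yields NaN effect
estimates with a warning rather than an error, so scans over many SNPs
do not abort. Simulation-based checks run at the study scale where the
claim demands it (370 loci for density properties; n = 300, 1000
null replicates for LRT calibration; n = 300, 200 replicates for effect
recovery) and at a reduced scale (40 loci, n = 100) for the fast unit
loop, where only rank-of-association and nominal significance are
asserted because power at q < 0.1 requires the larger cohort.

## Known limitations

- Standard errors of δ̂ are plug-in Wald errors conditional on the
  estimated λ. Like all plug-in mixed-model intervals they are slightly
  anti-conservative at finite n: simulations at n = 300 under kinship
  structure put the true coverage of δ̂ ± 2·se at ≈94.8–95.0% instead of
  the nominal 95.45% (the Kackar–Harville effect); a REML refit does not
  remove it. No Kenward–Roger-style correction is implemented.
- The per-replicate density ordering precursor > mature > seed is only
  ~83% probable at single-study scale because the precursor-vs-mature
  margin is about one standard deviation at the configured rates; the
  ordering is asserted strictly only on pooled replicates.
- The Mann–Whitney exact mode is limited to n₁+n₂ ≤ 20 without ties.
- No secondary-structure modelling of hairpin variants, no target
  gain/loss scoring for seed SNPs, and no permutation-based eQTL FDR.
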