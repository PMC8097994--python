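# mirvar

Variability analysis of microRNA genes: canonical seed-match target
prediction in 3′UTRs, classification of SNPs into miRNA hairpin
sub-regions, SNP-density statistics that expose purifying selection, and
kinship mixed-model association of miRNA SNP genotypes with gene
expression and quantitative phenotypes.

The package targets the analysis design used in livestock population
genomics of regulatory variation — e.g. porcine miRNA genes annotated on
Sscrofa11.1, SNPs called per population (European/Asian domestic pigs and
wild boars), and a half-sib cohort genotyped for candidate miRNA SNPs —
but every stage runs on synthetic data generated by the package itself,
so the whole pipeline is testable end to end without any download.

## What it computes

**Target sites.** For a mature miRNA, the seed is nucleotides 2–8 from
the 5′ end. The seed is reverse-complemented and every exact occurrence
in a spliced 3′UTR is reported as a site: an **8mer** when the base
immediately 3′ of the match on the mRNA (target position 1) is an
adenine, otherwise a **7mer-m8**. Sites are projected back to genomic
coordinates through the UTR block structure and intersected with SNPs.

**Hairpin sub-regions.** A SNP inside a hairpin falls in exactly one of:
anchor (mature position 1), seed (2–8), supplemental pairing (13–18),
other mature positions, or the precursor (hairpin outside the mature
arms). The three-way labelling seed / mature / precursor is derived from
this partition.

**SNP density.** For a region class with `N_r` SNPs over `L_r` bp across
all loci, the windowed density is

    D = N_r × 100 / L_r        (SNPs per 100 bp)

computed per region, per mature position, and in ±1 kb flanking bins of
100 bp; region contrasts use the Mann–Whitney U test.

**Association.** Each SNP dosage vector x is tested against each
phenotype y (expression probe or quantitative trait) under the
univariate mixed model

    y = Wα + xδ + u + ε,   u ~ MVN(0, λτ⁻¹K),   ε ~ MVN(0, τ⁻¹I)

with K the centered genomic relatedness matrix. The model is fitted by
maximum likelihood via a single eigendecomposition of K and a 1-D search
over λ; significance of the allele substitution effect δ comes from a
likelihood-ratio test (χ², 1 df) with Benjamini–Hochberg FDR control.
Candidate-target filtering (seed-match site present **and** interaction
validated), one-sided hypergeometric pathway enrichment, Welch's t-test
and 2^−ΔΔCt qPCR quantification complete the downstream analysis.

## Worked example

Simulate a study-scale dataset (370 hairpin loci with 409 mature arms,
four populations, a 350-individual five-family half-sib cohort) and run
the density and association stages:

```bash
mirvar simulate --seed 42 --out run/data
mirvar density  --data run/data --out run/density
mirvar assoc    --data run/data --out run/assoc
mirvar ddct     --data run/data --out run/ddct
```

`run/density/region_density.tsv` (seed 42):

```
region     n_snps  length_bp  density
seed           18       2863  0.6287111421585749
mature         41       6110  0.6710310965630114
precursor     220      21891  1.0049792152025947
total         279      30864  0.9039657853810265
```

The planted per-region SNP rates fall with functional constraint, and
the estimated densities recover the ordering precursor > mature > seed:
about 1.0 SNPs per 100 bp in precursors versus 0.63 in seeds here (the
seed/mature margin fluctuates at single-study scale; it is ~0.42 vs 0.86
in expectation). The association stage reports, per SNP × probe,
the allele substitution effect, its standard error, the LRT P-value and
the BH q-value; with the default generator the causal SNP is the top
association:

```
snp   probe     delta     se      p          q
rs0   probe_t0  -0.3783   0.0858  2.089e-05  2.089e-05
```

i.e. each alternative allele of rs0 lowers target-probe expression by
≈0.38 units (truth −0.45), detected at q ≪ 0.1. The qPCR stage recovers
the planted 1.9-fold expression difference between homozygous genotype
groups (`mean Rq ≈ 1.86` for AA with GG as calibrator in this run).

The library API mirrors the CLI: see `mirvar.targets.scan_utr`,
`mirvar.annotate.classify_variant`, `mirvar.density.snp_density` and
`mirvar.assoc.fit_lmm`.

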