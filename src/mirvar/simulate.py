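"""Seeded generators for synthetic study inputs.

Every analysis stage in this package can be exercised end to end without
any external download: these generators emit a genome, a miRNA hairpin
annotation, spliced 3'UTR models with planted seed-match sites, VCF
variants with a region-dependent density gradient, and a half-sib cohort
(genotypes with kinship structure, expression and lipid phenotypes drawn
from the association mixed model, and qPCR Ct tables) — together with a
truth record so tests can check exact recovery.

Defaults emulate the porcine study design this pipeline targets: 370
hairpin loci carrying 409 mature arms, per-region SNP rates ordered
precursor > mature > seed (0.0099 / 0.0086 / 0.0042 per bp, i.e. ~1 /
0.86 / 0.42 SNPs per 100 bp in expectation), flanking SNP rates ~2.6-fold
above the hairpin average, four populations with a 15% all-shared
fraction, rare-skewed allele frequencies (Beta with mean 0.12 in mature
and seed regions, 0.15 in precursors), a five-sire half-sib cohort of 350
offspring, heritability 0.3, an allele substitution effect of 0.45 and a
1.9-fold expression difference between homozygous genotype groups.

Planted seed-match sites are guaranteed to be the only occurrences of the
scanned motifs: UTR background sequence is cleaned of accidental matches
by targeted mutation, which makes site recovery exact rather than
probabilistic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .assoc import centered_kinship
from .targets import map_site_to_genome
from .model import (
    GenomicInterval,
    MatureArm,
    MiRNALocus,
    UTRModel,
    Variant,
    genomic_to_mature_position,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "Reference",
    "Cohort",
    "simulate_reference",
    "simulate_variants",
    "simulate_cohort",
    "write_bundle",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generators, with study-scale defaults."""

    seed: int = 0
    # reference geometry
    n_loci: int = 370
    n_two_arm_loci: int = 39  # 370 loci + 39 second arms = 409 mature arms
    arm_length_range: tuple[int, int] = (20, 24)
    hairpin_length_range: tuple[int, int] = (60, 110)
    locus_spacing_bp: int = 2300  # leaves the +-1 kb flanks disjoint
    n_utrs: int = 12
    utr_length_range: tuple[int, int] = (300, 600)
    sites_per_utr: int = 2
    frac_8mer_sites: float = 1 / 3
    n_scan_arms: int = 4  # arms whose seeds are planted in UTRs
    # variant rates (per bp)
    r_seed: float = 0.0042
    r_mature: float = 0.0086
    r_precursor: float = 0.0099
    r_flank: float = 0.0238
    frac_site_variants: float = 0.5  # fraction of planted sites carrying a SNP
    populations: tuple[str, ...] = ("EDM", "ADM", "EWB", "AWB")
    sharing_prob: float = 0.15
    af_beta_a: float = 0.5
    af_beta_b_mature: float = 11 / 3  # Beta mean 0.12 for mature and seed SNPs
    af_beta_b_precursor: float = 17 / 6  # Beta mean 0.15 for precursor SNPs
    # cohort
    n_individuals: int = 350
    n_families: int = 5
    n_background_snps: int = 400
    n_mirna_snps: int = 12
    h2: float = 0.3
    delta_true: float = 0.45
    fold_effect: float = 1.9
    ct_sd: float = 0.15
    n_null_probes: int = 20
    n_target_probes: int = 3
    n_qpcr_per_group: int = 9

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Reference:
    genome: dict[str, str]
    loci: list[MiRNALocus]
    utrs: list[UTRModel]
    truth: dict


@dataclass
class Cohort:
    genotypes: pd.DataFrame  # individuals x SNPs, miRNA SNPs first
    covariates: pd.DataFrame  # batch, farm
    kinship: np.ndarray  # from background SNPs
    phenotypes: pd.DataFrame  # lipid-like traits
    expression: pd.DataFrame  # probes x individuals
    presence: pd.DataFrame  # boolean probes x individuals
    probe_gene: pd.DataFrame
    ct_table: pd.DataFrame
    ct_groups: dict[str, str]
    truth: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _clean_motifs(seq: list[str], motifs: list[str], rng: np.random.Generator) -> None:
    """Mutate the sequence in place until no motif occurs anywhere."""
    for _ in range(2000):
        s = "".join(seq)
        hit = -1
        for m in motifs:
            i = s.find(m)
            if i != -1:
                hit = i
                width = len(m)
                break
        if hit == -1:
            return
        j = hit + int(rng.integers(width))
        seq[j] = str(rng.choice([b for b in "ACGT" if b != seq[j]]))
    raise RuntimeError("could not clean UTR background of motif occurrences")


def _place_arms(
    rng: np.random.Generator,
    hp_start: int,
    hp_len: int,
    two_arms: bool,
    arm_range: tuple[int, int],
) -> list[tuple[int, int]]:
    lo, hi = arm_range
    l1 = int(rng.integers(lo, hi + 1))
    if two_arms:
        l2 = int(rng.integers(lo, hi + 1))
        off1 = int(rng.integers(0, 4))
        off2 = int(rng.integers(0, 4))
        a1 = (hp_start + off1, hp_start + off1 + l1)
        a2 = (hp_start + hp_len - off2 - l2, hp_start + hp_len - off2)
        if a1[1] >= a2[0]:
            raise ValueError("hairpin too short for two arms")
        return [a1, a2]
    if rng.random() < 0.5:
        off = int(rng.integers(0, 4))
        return [(hp_start + off, hp_start + off + l1)]
    off = int(rng.integers(0, 4))
    return [(hp_start + hp_len - off - l1, hp_start + hp_len - off)]


def simulate_reference(config: SimulationConfig | None = None) -> Reference:
    """Generate genome + miRNA annotation + UTR models with planted sites.

    Hairpins are laid out on chromosome ``chrM`` with disjoint +-1 kb
    flanks, strands drawn ~50/50.  UTRs live on ``chrU``; each carries the
    configured number of exact seed-match sites for one of the designated
    scan arms, with the target-position-1 base set to A for the configured
    8mer fraction.  The truth record lists the planted sites and the
    (arm, gene) pairs, which double as the validated-interaction table.
    """
    cfg = config or SimulationConfig()
    rng = cfg.rng()
    if cfg.n_two_arm_loci > cfg.n_loci:
        raise ValueError("n_two_arm_loci cannot exceed n_loci")

    chrom_len = 2000 + cfg.n_loci * cfg.locus_spacing_bp
    genome_m = list(_random_seq(rng, chrom_len))
    loci: list[MiRNALocus] = []
    for i in range(cfg.n_loci):
        hp_len = int(rng.integers(*cfg.hairpin_length_range))
        hp_start = 1100 + i * cfg.locus_spacing_bp
        strand = "+" if rng.random() < 0.5 else "-"
        hp = GenomicInterval("chrM", hp_start, hp_start + hp_len, strand)
        spans = _place_arms(
            rng, hp_start, hp_len, i < cfg.n_two_arm_loci, cfg.arm_length_range
        )
        arms = []
        for j, (a0, a1) in enumerate(spans):
            sub = "".join(genome_m[a0:a1])
            seq = reverse_complement(sub) if strand == "-" else sub
            suffix = ("5p", "3p")[j] if len(spans) == 2 else "m"
            arms.append(
                MatureArm(f"mir{i}-{suffix}", GenomicInterval("chrM", a0, a1, strand), seq)
            )
        if strand == "-":
            arms = arms[::-1]  # 5p arm of a minus-strand hairpin sits at high coords
        loci.append(MiRNALocus(f"mir{i}", hp, tuple(arms)))

    # scan arms: distinct seeds so planted-site recovery is unambiguous
    all_arms = [arm for locus in loci for arm in locus.arms]
    scan_arms: list[MatureArm] = []
    seen_seeds: set[str] = set()
    for arm in all_arms:
        if arm.seed not in seen_seeds:
            scan_arms.append(arm)
            seen_seeds.add(arm.seed)
        if len(scan_arms) == cfg.n_scan_arms:
            break
    motifs = [reverse_complement(a.seed) for a in scan_arms]

    utrs: list[UTRModel] = []
    planted_sites: list[dict] = []
    genome_u: list[str] = []
    cursor = 0
    for u in range(cfg.n_utrs):
        arm = scan_arms[u % len(scan_arms)]
        motif = motifs[u % len(scan_arms)]
        length = int(rng.integers(*cfg.utr_length_range))
        if length < cfg.sites_per_utr * 10 + 10:
            raise ValueError(f"UTR length {length} too short to plant sites")
        strand = "+" if rng.random() < 0.5 else "-"
        for _attempt in range(50):
            spliced = list(_random_seq(rng, length))
            _clean_motifs(spliced, motifs, rng)
            # non-overlapping planting positions, keeping the t1 base inside
            positions: list[int] = []
            while len(positions) < cfg.sites_per_utr:
                p = int(rng.integers(0, length - 8))
                if all(abs(p - q) >= 9 for q in positions):
                    positions.append(p)
            positions.sort()
            planned = []
            for p in positions:
                eightmer = rng.random() < cfg.frac_8mer_sites
                spliced[p : p + 7] = list(motif)
                spliced[p + 7] = "A" if eightmer else str(rng.choice(list("CGT")))
                planned.append((p, "8mer" if eightmer else "7mer-m8"))
            s = "".join(spliced)
            ok = all(
                [i for i in range(length - 6) if s[i : i + 7] == m]
                == ([p for p, _ in planned] if m == motif else [])
                for m in motifs
            )
            if ok:
                break
        else:
            raise RuntimeError("could not plant sites without collisions")

        # split into 1-2 genomic blocks and write into chrU
        n_blocks = 1 if rng.random() < 0.5 else 2
        if n_blocks == 2:
            cut = int(rng.integers(50, length - 50))
            sizes = [cut, length - cut]
        else:
            sizes = [length]
        plus_seq = s if strand == "+" else reverse_complement(s)
        # transcript blocks map to genomic blocks: for '-', transcript order
        # reversed relative to genomic order
        genomic_sizes = sizes if strand == "+" else sizes[::-1]
        blocks_fwd = []
        pos = cursor + 100  # gap before each UTR
        genome_u.append(_random_seq(rng, pos - cursor))
        offset = 0
        for k, size in enumerate(genomic_sizes):
            if k > 0:
                intron = int(rng.integers(50, 200))
                genome_u.append(_random_seq(rng, intron))
                pos += intron
            blocks_fwd.append(GenomicInterval("chrU", pos, pos + size, strand))
            genome_u.append(plus_seq[offset : offset + size])
            offset += size
            pos += size
        cursor = pos
        tx_blocks = tuple(blocks_fwd if strand == "+" else reversed(blocks_fwd))
        tx_id, gene_id = f"tx{u}", f"gene{u}"
        utrs.append(UTRModel(tx_id, gene_id, strand, tx_blocks, s))
        for p, stype in planned:
            planted_sites.append(
                {
                    "arm_id": arm.arm_id,
                    "transcript_id": tx_id,
                    "gene_id": gene_id,
                    "utr_start": p,
                    "utr_end": p + (8 if stype == "8mer" else 7),
                    "site_type": stype,
                }
            )
    genome_u.append(_random_seq(rng, 100))

    truth = {
        "scan_arms": [a.arm_id for a in scan_arms],
        "planted_sites": planted_sites,
        "validated_pairs": sorted(
            {(site["arm_id"], site["gene_id"]) for site in planted_sites}
        ),
    }
    genome = {"chrM": "".join(genome_m), "chrU": "".join(genome_u)}
    return Reference(genome, loci, utrs, truth)


def _draw_presence(
    rng: np.random.Generator, pops: tuple[str, ...], sharing_prob: float
) -> dict[str, bool]:
    if rng.random() < sharing_prob:
        return {p: True for p in pops}
    while True:
        flags = rng.random(len(pops)) < 0.5
        if flags.any() and not flags.all():
            return {p: bool(f) for p, f in zip(pops, flags)}


def simulate_variants(
    reference: Reference, config: SimulationConfig | None = None
) -> tuple[list[Variant], dict]:
    """Plant SNPs with region-dependent Bernoulli rates.

    Each hairpin bp carries an independent SNP with the rate of its
    three-way region (seed / mature / precursor); each flanking bp (+-1 kb,
    outside any hairpin) with the flanking rate.  Presence across the four
    populations is all-shared with the configured probability, otherwise a
    random proper subset; alternative-allele frequencies are drawn from
    rare-skewed Beta distributions.  A configured fraction of the planted
    UTR seed-match sites also receives a SNP.  Returns the variants and a
    truth record with the planted region label per miRNA SNP and the ids
    of in-site UTR SNPs.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    genome = reference.genome
    variants: list[Variant] = []
    truth: dict = {"regions": {}, "site_variant_ids": []}

    hairpin_spans = [(l.hairpin.start, l.hairpin.end) for l in reference.loci]

    def add_variant(chrom: str, pos: int, vid: str, region3: str | None) -> None:
        ref = genome[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        presence = _draw_presence(rng, cfg.populations, cfg.sharing_prob)
        b = cfg.af_beta_b_precursor if region3 in (None, "precursor") else cfg.af_beta_b_mature
        freqs = {
            p: float(rng.beta(cfg.af_beta_a, b)) if presence[p] else 0.0
            for p in cfg.populations
        }
        variants.append(Variant(chrom, pos, vid, ref, alt, presence, freqs))
        if region3 is not None:
            truth["regions"][vid] = region3

    for locus in reference.loci:
        hp = locus.hairpin
        for pos in range(hp.start, hp.end):
            arm = locus.arm_at(pos)
            if arm is None:
                region3, rate = "precursor", cfg.r_precursor
            else:
                p = genomic_to_mature_position(arm, pos)
                region3 = "seed" if 2 <= p <= 8 else "mature"
                rate = cfg.r_seed if region3 == "seed" else cfg.r_mature
            if rng.random() < rate:
                add_variant(hp.chrom, pos, f"mv_{locus.locus_id}_{pos}", region3)
        if cfg.r_flank > 0:
            lo = max(0, hp.start - 1000)
            hi = min(len(genome[hp.chrom]), hp.end + 1000)
            offs = np.nonzero(rng.random(hi - lo) < cfg.r_flank)[0] + lo
            for pos in offs:
                pos = int(pos)
                if hp.start <= pos < hp.end:
                    continue
                if any(s <= pos < e for s, e in hairpin_spans):
                    continue
                add_variant(hp.chrom, pos, f"fv_{locus.locus_id}_{pos}", None)

    # SNPs inside planted UTR seed-match sites
    utr_by_id = {u.transcript_id: u for u in reference.utrs}
    site_variant_ids = []
    for k, site in enumerate(reference.truth.get("planted_sites", ())):
        if rng.random() >= cfg.frac_site_variants:
            continue
        utr = utr_by_id[site["transcript_id"]]
        offset = int(rng.integers(site["utr_start"], site["utr_end"]))
        blocks = map_site_to_genome(utr, offset, offset + 1)
        pos = blocks[0].start
        vid = f"sv_{site['transcript_id']}_{k}"
        add_variant(blocks[0].chrom, pos, vid, None)
        site_variant_ids.append(vid)
    truth["site_variant_ids"] = site_variant_ids
    return variants, truth


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a half-sib cohort under the association mixed model.

    Genotypes are gene-dropped from a small number of sires (half-sib
    families) plus population-frequency dam alleles, which induces the
    block kinship structure the LMM must absorb.  The first miRNA SNP is
    causal: it shifts each lipid-like trait by ``delta_true`` per
    alternative allele and lowers target-probe expression (homozygous
    alternative lowest).  Polygenic values are drawn MVN(0, h2 * K) with
    residual variance 1 - h2.  A Ct table for one target miRNA and two
    endogenous controls encodes a ``fold_effect`` expression ratio between
    homozygous genotype groups.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_individuals
    n_snps = cfg.n_mirna_snps + cfg.n_background_snps
    freqs = np.concatenate(
        [
            rng.uniform(0.15, 0.6, size=cfg.n_mirna_snps),
            rng.uniform(0.1, 0.9, size=cfg.n_background_snps),
        ]
    )
    sire_haps = rng.random((cfg.n_families, 2, n_snps)) < freqs
    family = np.arange(n) % cfg.n_families
    # gene dropping: per individual and SNP, pick one sire haplotype
    pick = rng.integers(0, 2, size=(n, n_snps))
    sire_allele = sire_haps[family[:, None], pick, np.arange(n_snps)[None, :]]
    dam_allele = rng.random((n, n_snps)) < freqs
    dosages = sire_allele.astype(int) + dam_allele.astype(int)

    snp_names = [f"rs{i}" for i in range(cfg.n_mirna_snps)] + [
        f"bg{i}" for i in range(cfg.n_background_snps)
    ]
    genotypes = pd.DataFrame(
        dosages, columns=snp_names, index=[f"ind{i}" for i in range(n)]
    )
    K = centered_kinship(genotypes[[f"bg{i}" for i in range(cfg.n_background_snps)]])

    batch = rng.integers(0, 4, size=n)
    farm = rng.integers(0, 3, size=n)
    covariates = pd.DataFrame(
        {"batch": [f"b{b}" for b in batch], "farm": [f"f{f}" for f in farm]},
        index=genotypes.index,
    )
    batch_eff = rng.normal(0, 0.3, size=4)
    farm_eff = rng.normal(0, 0.3, size=3)
    fixed = batch_eff[batch] + farm_eff[farm]

    # polygenic values: u ~ MVN(0, h2 * K)
    evals, evecs = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    root = evecs * np.sqrt(evals)

    def draw_u() -> np.ndarray:
        return np.sqrt(cfg.h2) * (root @ rng.standard_normal(n))

    x_causal = dosages[:, 0].astype(float)
    sigma_e = np.sqrt(1.0 - cfg.h2)
    phen = {}
    for trait in ("trait_causal", "trait_null"):
        delta = cfg.delta_true if trait == "trait_causal" else 0.0
        phen[trait] = (
            fixed + delta * x_causal + draw_u() + sigma_e * rng.standard_normal(n)
        )
    phenotypes = pd.DataFrame(phen, index=genotypes.index)

    # expression: target probes respond to the causal genotype (alt lowers
    # expression), null probes do not
    probes = {}
    presence = {}
    probe_gene_rows = []
    expr_effect = -cfg.delta_true
    for t in range(cfg.n_target_probes):
        pid = f"probe_t{t}"
        probes[pid] = (
            10.0
            + expr_effect * x_causal
            + draw_u()
            + sigma_e * rng.standard_normal(n)
        )
        presence[pid] = np.ones(n, dtype=bool)
        probe_gene_rows.append({"probe": pid, "gene": f"gene{t}"})
    for t in range(cfg.n_null_probes):
        pid = f"probe_n{t}"
        probes[pid] = 8.0 + rng.standard_normal(n)
        det = rng.random() > 0.25  # a quarter of null probes fall below detection
        presence[pid] = (
            np.ones(n, dtype=bool)
            if det
            else rng.random(n) < 0.3
        )
        probe_gene_rows.append({"probe": pid, "gene": f"ngene{t}"})
    expression = pd.DataFrame(probes, index=genotypes.index).T
    presence_df = pd.DataFrame(presence, index=genotypes.index).T
    probe_gene = pd.DataFrame(probe_gene_rows)

    # qPCR Ct table: fold_effect between homozygous groups on the target
    ct_rows = []
    groups: dict[str, str] = {}
    dct_shift = float(np.log2(cfg.fold_effect))
    for g, grp in enumerate(("GG", "AA")):
        for i in range(cfg.n_qpcr_per_group):
            sample = f"{grp}_{i}"
            groups[sample] = grp
            target_ct = 25.0 - (dct_shift if grp == "AA" else 0.0)
            for gene, base_ct in (
                ("mir_target", target_ct),
                ("ctrl_let7a", 20.0),
                ("ctrl_mir26a", 21.0),
            ):
                for _rep in range(3):
                    ct_rows.append(
                        {
                            "sample": sample,
                            "gene": gene,
                            "ct": base_ct + rng.normal(0, cfg.ct_sd),
                        }
                    )
    ct_table = pd.DataFrame(ct_rows)

    truth = {
        "causal_snp": "rs0",
        "delta_true": cfg.delta_true,
        "expr_effect": expr_effect,
        "h2": cfg.h2,
        "fold_effect": cfg.fold_effect,
        "family": family.tolist(),
    }
    return Cohort(
        genotypes=genotypes,
        covariates=covariates,
        kinship=K,
        phenotypes=phenotypes,
        expression=expression,
        presence=presence_df,
        probe_gene=probe_gene,
        ct_table=ct_table,
        ct_groups=groups,
        truth=truth,
    )


def write_bundle(
    outdir: str | Path,
    reference: Reference,
    variants: list[Variant] | None = None,
    variant_truth: Mapping | None = None,
    cohort: Cohort | None = None,
) -> Path:
    """Write a simulated dataset as the plain-text formats the CLI reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(outdir / "genome.fa", reference.genome)
    mio.write_mirna_gff3(outdir / "mirna.gff3", reference.loci)
    mio.write_bed12(outdir / "utrs.bed", reference.utrs)
    truth = {"reference": reference.truth}
    if variants is not None:
        contigs = {name: len(seq) for name, seq in reference.genome.items()}
        mio.write_vcf(outdir / "snps.vcf", variants, contigs)
        truth["variants"] = dict(variant_truth or {})
    if cohort is not None:
        cohort.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
        cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
        cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
        cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
        cohort.presence.to_csv(outdir / "presence.tsv", sep="\t")
        cohort.probe_gene.to_csv(outdir / "probe_gene.tsv", sep="\t", index=False)
        cohort.ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"sample": s, "group": g} for s, g in cohort.ct_groups.items()]
        ).to_csv(outdir / "ct_groups.tsv", sep="\t", index=False)
        truth["cohort"] = cohort.truth
    pd.DataFrame(
        reference.truth["validated_pairs"], columns=["mirna_arm_id", "gene_id"]
    ).to_csv(outdir / "validated_interactions.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return outdir
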