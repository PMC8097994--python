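"""SNP-density statistics over miRNA hairpin sub-regions.

The central statistic is the windowed density D = Nr * 100 / Lr: the
number of SNPs observed in a region class, scaled to a 100-bp window by
the total length of that class across all loci.  Purifying selection on
mature miRNAs — strongest on the seed — shows up as the characteristic
ordering precursor > mature > seed, and as a density dip at functionally
constrained mature positions (anchor, seed, supplemental pairing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotate import AnnotatedVariant
from .model import MiRNALocus, RegionClass, Variant

__all__ = [
    "RegionLengths",
    "DensityResult",
    "RankSumResult",
    "region_lengths",
    "snp_density",
    "density_fold",
    "region_density_table",
    "per_position_density",
    "flanking_density",
    "mann_whitney_u",
    "per_arm_densities",
]

SEED_BP_PER_ARM = 7


@dataclass(frozen=True)
class RegionLengths:
    """Total bp per region class across a locus set.

    seed + mature (mature arms excluding seeds) + precursor (hairpin
    excluding arms) partition the total hairpin length.
    """

    seed_bp: int
    mature_bp: int
    precursor_bp: int

    @property
    def total_bp(self) -> int:
        return self.seed_bp + self.mature_bp + self.precursor_bp


@dataclass(frozen=True)
class DensityResult:
    region: str
    n_snps: int
    length_bp: int
    density: float  # SNPs per 100 bp


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"


def region_lengths(loci: Iterable[MiRNALocus]) -> RegionLengths:
    """Seed / mature / precursor total lengths for a locus set."""
    n_arms = 0
    arm_bp = 0
    hairpin_bp = 0
    for locus in loci:
        hairpin_bp += locus.hairpin.length
        for arm in locus.arms:
            n_arms += 1
            arm_bp += arm.length
    seed_bp = SEED_BP_PER_ARM * n_arms
    return RegionLengths(
        seed_bp=seed_bp,
        mature_bp=arm_bp - seed_bp,
        precursor_bp=hairpin_bp - arm_bp,
    )


def snp_density(n_snps: int, length_bp: int) -> float:
    """Windowed SNP density D = Nr * 100 / Lr (SNPs per 100 bp)."""
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if n_snps < 0:
        raise ValueError("SNP count must be non-negative")
    return n_snps * 100 / length_bp


def density_fold(d_num: float, d_den: float) -> float:
    if d_den <= 0:
        raise ValueError("denominator density must be positive")
    return d_num / d_den


def region_density_table(
    annotated: Iterable[AnnotatedVariant], loci: Iterable[MiRNALocus]
) -> list[DensityResult]:
    """Three-way (seed / mature / precursor) density table plus the total."""
    lengths = region_lengths(loci)
    counts = {"seed": 0, "mature": 0, "precursor": 0}
    total = 0
    for av in annotated:
        counts[av.region.paper_label] += 1
        total += 1
    entries = [
        ("seed", counts["seed"], lengths.seed_bp),
        ("mature", counts["mature"], lengths.mature_bp),
        ("precursor", counts["precursor"], lengths.precursor_bp),
        ("total", total, lengths.total_bp),
    ]
    return [
        DensityResult(name, n, l, snp_density(n, l) if l else 0.0)
        for name, n, l in entries
    ]


def per_position_density(
    annotated: Iterable[AnnotatedVariant], loci: Iterable[MiRNALocus]
) -> pd.DataFrame:
    """SNP density at each mature position p across all arms.

    For position p the denominator is the number of arms of length >= p,
    so positions beyond a short arm's end do not dilute its density.
    """
    arm_lengths = [arm.length for locus in loci for arm in locus.arms]
    if not arm_lengths:
        return pd.DataFrame(columns=["p", "n_snps", "n_arms", "density"])
    max_len = max(arm_lengths)
    n_arms_at = [sum(1 for L in arm_lengths if L >= p) for p in range(1, max_len + 1)]
    n_snps_at = [0] * max_len
    for av in annotated:
        if av.mature_position is not None:
            n_snps_at[av.mature_position - 1] += 1
    rows = [
        {
            "p": p,
            "n_snps": n_snps_at[p - 1],
            "n_arms": n_arms_at[p - 1],
            "density": snp_density(n_snps_at[p - 1], n_arms_at[p - 1]),
        }
        for p in range(1, max_len + 1)
        if n_arms_at[p - 1] > 0
    ]
    return pd.DataFrame(rows, columns=["p", "n_snps", "n_arms", "density"])


def flanking_density(
    loci: Sequence[MiRNALocus],
    all_variants: Iterable[Variant],
    n_bins: int = 10,
    bin_bp: int = 100,
    orientation: str = "strand",
) -> pd.DataFrame:
    """SNP density in the hairpin body (bin 0) and in ``n_bins`` flanking
    bins of ``bin_bp`` bp on each side.

    With ``orientation="strand"`` (default) bin -1 abuts the hairpin's 5'
    end in transcriptional orientation, i.e. it lies genomically left of a
    plus-strand hairpin and right of a minus-strand one.  With
    ``orientation="genomic"`` negative bins are always genomically left.
    Pooled density per flanking bin is count * 100 / (bin_bp * n_loci).
    """
    if orientation not in ("strand", "genomic"):
        raise ValueError(f"unknown orientation {orientation!r}")
    variants = list(all_variants)
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    bins = list(range(-n_bins, 0)) + [0] + list(range(1, n_bins + 1))
    counts = {b: 0 for b in bins}
    body_bp = 0
    n_loci = len(loci)
    for locus in loci:
        hp = locus.hairpin
        body_bp += hp.length
        flip = orientation == "strand" and hp.strand == "-"
        for v in by_chrom.get(hp.chrom, ()):
            if hp.contains(v.pos):
                counts[0] += 1
            elif v.pos < hp.start and hp.start - v.pos <= n_bins * bin_bp:
                k = (hp.start - 1 - v.pos) // bin_bp + 1  # 1..n_bins left of hairpin
                counts[k if flip else -k] += 1
            elif v.pos >= hp.end and v.pos - hp.end < n_bins * bin_bp:
                k = (v.pos - hp.end) // bin_bp + 1  # 1..n_bins right of hairpin
                counts[-k if flip else k] += 1
    rows = []
    for b in bins:
        bp = body_bp if b == 0 else bin_bp * n_loci
        rows.append(
            {
                "bin": b,
                "bp": bp,
                "n_snps": counts[b],
                "density": snp_density(counts[b], bp) if bp else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["bin", "bp", "n_snps", "density"])


def per_arm_densities(
    annotated: Iterable[AnnotatedVariant], loci: Iterable[MiRNALocus]
) -> pd.DataFrame:
    """Per-arm seed and mature (non-seed) densities, one row per arm.

    These per-arm values are the sampling units for the non-parametric
    seed-vs-mature comparison; how the original analysis defined its
    sampling unit is not recorded, so this construction is the package's
    documented choice.
    """
    per_arm: dict[str, dict[str, int]] = {}
    arm_len: dict[str, int] = {}
    for locus in loci:
        for arm in locus.arms:
            arm_len[arm.arm_id] = arm.length
            per_arm[arm.arm_id] = {"seed": 0, "mature": 0}
    for av in annotated:
        if av.arm_id is not None:
            key = "seed" if av.region is RegionClass.SEED else "mature"
            per_arm[av.arm_id][key] += 1
    rows = [
        {
            "arm_id": arm_id,
            "seed_density": snp_density(c["seed"], SEED_BP_PER_ARM),
            "mature_density": snp_density(
                c["mature"], arm_len[arm_id] - SEED_BP_PER_ARM
            ),
        }
        for arm_id, c in per_arm.items()
    ]
    return pd.DataFrame(rows, columns=["arm_id", "seed_density", "mature_density"])


def mann_whitney_u(
    xs: Sequence[float], ys: Sequence[float], alternative: str = "two-sided"
) -> RankSumResult:
    """Mann-Whitney U rank-sum test.

    Exact null enumeration when n1 + n2 <= 20 and there are no ties;
    otherwise the normal approximation with mid-ranks for ties, tie
    correction, and a 0.5 continuity correction.
    """
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(xs) + list(ys)
    has_ties = len(set(pooled)) < len(pooled)
    exact = (len(xs) + len(ys) <= 20) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        xs, ys, alternative=alternative, method=method, use_continuity=True
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "normal-approximation",
    )
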