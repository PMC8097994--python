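"""Assignment of SNPs to miRNA hairpin sub-regions and summary statistics.

Every variant inside a hairpin falls in exactly one of five sub-regions:
anchor (mature position 1), seed (2-8), supplemental pairing (13-18),
other mature positions, or the precursor (hairpin outside any mature
arm).  The coarser three-way labelling used in most reports collapses
anchor/supplementary/other-mature into "mature".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    SEED_END,
    SEED_START,
    SUPP_END,
    SUPP_START,
    MiRNALocus,
    RegionClass,
    Variant,
    genomic_to_mature_position,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedVariant",
    "SharingSummary",
    "classify_variant",
    "annotate_all",
    "per_mirna_snp_histogram",
    "sharing_summary",
    "percent",
    "frequency_spectrum",
    "annotated_to_table",
]


@dataclass(frozen=True)
class AnnotatedVariant:
    """A SNP placed in exactly one hairpin sub-region.

    ``arm_id`` and the 1-based mature position ``p`` are set iff the
    variant falls inside a mature arm (any region but PRECURSOR).
    """

    variant: Variant
    locus_id: str
    region: RegionClass
    arm_id: str | None = None
    mature_position: int | None = None

    def __post_init__(self) -> None:
        in_arm = self.region is not RegionClass.PRECURSOR
        if in_arm != (self.arm_id is not None) or in_arm != (
            self.mature_position is not None
        ):
            raise ValueError(
                "arm_id and mature_position must be set exactly for mature-arm regions"
            )


def classify_variant(locus: MiRNALocus, variant: Variant) -> AnnotatedVariant:
    """Classify a variant inside a hairpin into its sub-region.

    Inside a mature arm, the mature position p determines the class:
    p=1 anchor, p in 2-8 seed, p in 13-18 supplemental pairing, otherwise
    other-mature.  Inside the hairpin but outside both arms: precursor.
    """
    if not locus.hairpin.contains(variant.pos) or locus.hairpin.chrom != variant.chrom:
        raise ValueError(
            f"variant {variant.vid} at {variant.chrom}:{variant.pos} outside "
            f"hairpin of locus {locus.locus_id}"
        )
    arm = locus.arm_at(variant.pos)
    if arm is None:
        return AnnotatedVariant(variant, locus.locus_id, RegionClass.PRECURSOR)
    p = genomic_to_mature_position(arm, variant.pos)
    if p == 1:
        region = RegionClass.ANCHOR
    elif SEED_START <= p <= SEED_END:
        region = RegionClass.SEED
    elif SUPP_START <= p <= SUPP_END:
        region = RegionClass.SUPPLEMENTARY
    else:
        region = RegionClass.MATURE_OTHER
    return AnnotatedVariant(variant, locus.locus_id, region, arm.arm_id, p)


def annotate_all(
    loci: Sequence[MiRNALocus], variants: Iterable[Variant]
) -> list[AnnotatedVariant]:
    """Annotate every variant that falls inside some hairpin.

    A variant covered by two overlapping loci is emitted once per locus
    with a warning logged; variants outside all hairpins are dropped.
    """
    by_chrom: dict[str, list[MiRNALocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.hairpin.chrom, []).append(locus)
    out: list[AnnotatedVariant] = []
    for v in variants:
        hits = [
            loc for loc in by_chrom.get(v.chrom, ()) if loc.hairpin.contains(v.pos)
        ]
        if len(hits) > 1:
            logger.warning(
                "variant %s overlaps %d loci: %s",
                v.vid, len(hits), ",".join(l.locus_id for l in hits),
            )
        for locus in hits:
            out.append(classify_variant(locus, v))
    return out


def per_mirna_snp_histogram(annotated: Iterable[AnnotatedVariant]) -> dict[int, int]:
    """Map k -> number of polymorphic miRNA loci carrying exactly k SNPs."""
    per_locus: dict[str, int] = {}
    for av in annotated:
        per_locus[av.locus_id] = per_locus.get(av.locus_id, 0) + 1
    hist: dict[int, int] = {}
    for k in per_locus.values():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


@dataclass
class SharingSummary:
    """Cross-population sharing of miRNA SNPs."""

    populations: tuple[str, ...]
    total: int
    shared_all: int
    exclusive: dict[str, int]
    subset_counts: dict[frozenset, int] = field(default_factory=dict)

    @property
    def shared_all_pct(self) -> float:
        return percent(self.shared_all, self.total) if self.total else 0.0


def sharing_summary(
    annotated: Iterable[AnnotatedVariant], population_labels: Sequence[str]
) -> SharingSummary:
    """Summarise in how many and which populations each SNP segregates.

    Presence of a variant in a population means the alternative allele was
    observed in at least one individual of that group.  Variants annotated
    in several loci are counted once (by variant id).
    """
    pops = tuple(population_labels)
    seen: dict[str, frozenset] = {}
    for av in annotated:
        v = av.variant
        unknown = set(v.pop_presence) - set(pops)
        if unknown:
            raise ValueError(f"unknown population label(s): {sorted(unknown)}")
        present = frozenset(p for p in pops if v.pop_presence.get(p, False))
        seen.setdefault(v.vid, present)
    subset_counts: dict[frozenset, int] = {}
    for present in seen.values():
        subset_counts[present] = subset_counts.get(present, 0) + 1
    total = len(seen)
    shared_all = subset_counts.get(frozenset(pops), 0)
    exclusive = {
        p: subset_counts.get(frozenset({p}), 0) for p in pops
    }
    return SharingSummary(pops, total, shared_all, exclusive, subset_counts)


def percent(k: int, n: int, mode: str = "round") -> float:
    """Render 100*k/n with two decimals, either half-up rounded or
    truncated.  Both conventions appear in published percentage tables, so
    both are provided."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    value = Fraction(100 * k, n)
    dec = Decimal(value.numerator) / Decimal(value.denominator)
    if mode == "round":
        q = dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    elif mode == "truncate":
        q = dec.quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(q)


def frequency_spectrum(
    annotated: Iterable[AnnotatedVariant],
    population: str,
    bin_width: float = 0.1,
):
    """Histogram of alternative-allele frequencies for one population.

    Bins are [0,w), [w,2w), ..., [1-w,1]; the last bin is closed so a
    frequency of exactly 1 is counted.  Returns (bin_edges, counts,
    fraction_at_most_0.1).
    """
    freqs = np.array(
        [
            av.variant.alt_freq[population]
            for av in annotated
            if population in av.variant.alt_freq
        ]
    )
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    frac_rare = float(np.mean(freqs <= 0.1)) if freqs.size else 0.0
    return edges, counts, frac_rare


def annotated_to_table(annotated: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """AnnotatedVariant records as a TSV-ready table (1-based positions)."""
    rows = []
    for av in annotated:
        v = av.variant
        row = {
            "vid": v.vid,
            "chrom": v.chrom,
            "pos_1based": v.pos + 1,
            "ref": v.ref,
            "alt": v.alt,
            "locus_id": av.locus_id,
            "arm_id": av.arm_id or "",
            "mature_position": av.mature_position if av.mature_position else "",
            "region": av.region.value,
            "region_3way": av.region.paper_label,
        }
        for pop in sorted(v.alt_freq):
            row[f"af_{pop}"] = v.alt_freq[pop]
        rows.append(row)
    return pd.DataFrame(rows)
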