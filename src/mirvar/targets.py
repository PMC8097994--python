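"""Canonical miRNA seed-match prediction in 3'UTRs.

Only the two site classes with the strongest functional support are
modelled: 7mer-m8 (exact Watson-Crick complementarity of the target to
miRNA positions 2-8) and 8mer (a 7mer-m8 match whose target position 1 —
the base immediately 3' of the match on the mRNA — is an adenine).
Scanning happens on the spliced UTR sequence; sites are projected back to
genomic coordinates through the UTR block structure, so a site can span an
exon junction and occupy two or more genomic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    GenomicInterval,
    MatureArm,
    MiRNALocus,
    UTRModel,
    Variant,
    reverse_complement,
)

__all__ = [
    "SeedMatchSite",
    "extract_seed",
    "scan_utr",
    "map_site_to_genome",
    "scan_all",
    "build_target_pairs",
    "intersect_variants_with_sites",
    "sites_to_bed",
]

_DNA = frozenset("ACGT")

SITE_7MER_M8 = "7mer-m8"
SITE_8MER = "8mer"


@dataclass(frozen=True)
class SeedMatchSite:
    """A seed-complementary site in a spliced 3'UTR.

    ``utr_start``/``utr_end`` are 0-based half-open positions in the
    spliced sequence; the span is 7 nt for a 7mer-m8 site and 8 nt for an
    8mer (the extra base being the target-position-1 adenine).
    """

    mirna_arm_id: str
    transcript_id: str
    utr_start: int
    utr_end: int
    site_type: str
    genomic_blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        width = self.utr_end - self.utr_start
        expected = 8 if self.site_type == SITE_8MER else 7
        if self.site_type not in (SITE_7MER_M8, SITE_8MER):
            raise ValueError(f"unknown site type {self.site_type!r}")
        if width != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {width}"
            )
        if sum(b.length for b in self.genomic_blocks) != width:
            raise ValueError("genomic block lengths do not sum to site width")


def extract_seed(arm: MatureArm) -> str:
    """Seed of a mature arm: positions 2-8 from the 5' end, 7 nt."""
    if arm.length < 8:
        raise ValueError(f"arm {arm.arm_id} too short for a seed")
    return arm.seed


def map_site_to_genome(
    utr: UTRModel, utr_start: int, utr_end: int
) -> tuple[GenomicInterval, ...]:
    """Project a spliced-UTR interval onto the genome through the UTR blocks.

    Returns genomic intervals in transcript 5'->3' order; an interval that
    crosses a block junction yields one genomic interval per block touched.
    """
    if not (0 <= utr_start < utr_end <= utr.spliced_length):
        raise ValueError(
            f"site {utr_start}-{utr_end} outside spliced UTR "
            f"{utr.transcript_id} (length {utr.spliced_length})"
        )
    out: list[GenomicInterval] = []
    offset = 0
    for block in utr.blocks:
        lo = max(utr_start, offset)
        hi = min(utr_end, offset + block.length)
        if lo < hi:
            if utr.strand == "+":
                g0 = block.start + (lo - offset)
                g1 = block.start + (hi - offset)
            else:
                # transcript position offset maps to block.end - 1 - within-block offset
                g1 = block.end - (lo - offset)
                g0 = block.end - (hi - offset)
            out.append(GenomicInterval(block.chrom, g0, g1, utr.strand))
        offset += block.length
    return tuple(out)


def scan_utr(utr: UTRModel, seed: str, arm_id: str = "") -> list[SeedMatchSite]:
    """Find every canonical seed-match site for ``seed`` in a spliced UTR.

    The 7-nt seed is reverse-complemented and every exact occurrence of the
    resulting match motif is reported, overlapping occurrences included.
    An occurrence is an 8mer when the base immediately 3' of the match on
    the mRNA exists and is ``A`` (the site then extends by that base);
    otherwise it is a 7mer-m8.  Windows containing an ambiguous base never
    match, and an occurrence whose 3'-adjacent base is ambiguous is dropped.
    Matching is case-insensitive.
    """
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    if set(seed.upper()) - _DNA:
        raise ValueError(f"seed contains non-ACGT characters: {seed!r}")
    motif = reverse_complement(seed)
    seq = utr.spliced_sequence.upper()
    sites: list[SeedMatchSite] = []
    start = seq.find(motif)
    while start != -1:
        t1_pos = start + 7
        if t1_pos < len(seq) and seq[t1_pos] not in _DNA:
            pass  # ambiguous base adjacent to the match: no site
        elif t1_pos < len(seq) and seq[t1_pos] == "A":
            sites.append(
                SeedMatchSite(
                    arm_id, utr.transcript_id, start, start + 8, SITE_8MER,
                    map_site_to_genome(utr, start, start + 8),
                )
            )
        else:
            sites.append(
                SeedMatchSite(
                    arm_id, utr.transcript_id, start, start + 7, SITE_7MER_M8,
                    map_site_to_genome(utr, start, start + 7),
                )
            )
        start = seq.find(motif, start + 1)
    return sites


def scan_all(
    loci: Iterable[MiRNALocus], utrs: Sequence[UTRModel]
) -> list[SeedMatchSite]:
    """Scan every mature arm of every locus against every UTR."""
    sites: list[SeedMatchSite] = []
    for locus in loci:
        for arm in locus.arms:
            seed = extract_seed(arm)
            for utr in utrs:
                sites.extend(scan_utr(utr, seed, arm_id=arm.arm_id))
    return sites


def build_target_pairs(
    loci: Iterable[MiRNALocus], utrs: Sequence[UTRModel]
) -> pd.DataFrame:
    """Tabulate putative miRNA-mRNA target pairs: one row per (arm,
    transcript) with at least one site, with per-type site counts."""
    gene_of = {u.transcript_id: u.gene_id for u in utrs}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for site in scan_all(loci, utrs):
        key = (site.mirna_arm_id, site.transcript_id)
        entry = counts.setdefault(key, {SITE_7MER_M8: 0, SITE_8MER: 0})
        entry[site.site_type] += 1
    rows = [
        {
            "mirna_arm_id": arm_id,
            "gene_id": gene_of[tx],
            "transcript_id": tx,
            "n_7mer_m8": c[SITE_7MER_M8],
            "n_8mer": c[SITE_8MER],
        }
        for (arm_id, tx), c in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["mirna_arm_id", "gene_id", "transcript_id", "n_7mer_m8", "n_8mer"]
    )
    return df.sort_values(["mirna_arm_id", "transcript_id"]).reset_index(drop=True)


def _offset_in_site(site: SeedMatchSite, chrom: str, pos: int) -> int | None:
    """Offset of a genomic position within a site, in target 5'->3'
    orientation, or None if outside all blocks."""
    acc = 0
    for block in site.genomic_blocks:
        if block.chrom == chrom and block.contains(pos):
            if block.strand == "-":
                return acc + (block.end - 1 - pos)
            return acc + (pos - block.start)
        acc += block.length
    return None


def intersect_variants_with_sites(
    variants: Iterable[Variant], sites: Sequence[SeedMatchSite]
) -> pd.DataFrame:
    """Report every (variant, site) pair where the variant falls inside a
    genomic block of the site, with the variant's offset in target
    5'->3' orientation (0 = first base of the match)."""
    rows = []
    for v in variants:
        for site in sites:
            off = _offset_in_site(site, v.chrom, v.pos)
            if off is not None:
                rows.append(
                    {
                        "vid": v.vid,
                        "chrom": v.chrom,
                        "pos_1based": v.pos + 1,
                        "mirna_arm_id": site.mirna_arm_id,
                        "transcript_id": site.transcript_id,
                        "utr_start": site.utr_start,
                        "utr_end": site.utr_end,
                        "site_type": site.site_type,
                        "offset": off,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "vid", "chrom", "pos_1based", "mirna_arm_id", "transcript_id",
            "utr_start", "utr_end", "site_type", "offset",
        ],
    )


def sites_to_bed(sites: Iterable[SeedMatchSite]) -> pd.DataFrame:
    """Sites as BED6-shaped rows, one row per genomic block."""
    rows = []
    for site in sites:
        for block in site.genomic_blocks:
            rows.append(
                {
                    "chrom": block.chrom,
                    "start": block.start,
                    "end": block.end,
                    "name": f"{site.mirna_arm_id}|{site.transcript_id}|{site.site_type}",
                    "score": 0,
                    "strand": block.strand,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
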