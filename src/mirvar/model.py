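"""Core domain types and coordinate conventions.

All internal coordinates are 0-based half-open (``start`` inclusive,
``end`` exclusive).  GFF3 and VCF use 1-based inclusive coordinates and are
converted at the I/O boundary; emitted tables use 1-based inclusive
coordinates again so they can be compared side by side with published
miRNA annotation tables.

Sequences are stored as DNA (A/C/G/T, uppercase).  RNA input (U) is
normalised to T on read and the original alphabet is recorded so output
can be re-emitted in the alphabet it arrived in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "GenomicInterval",
    "MatureArm",
    "MiRNALocus",
    "Variant",
    "UTRModel",
    "RegionClass",
    "reverse_complement",
    "genomic_to_mature_position",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_DNA = frozenset("ACGT")

SEED_START = 2  #: first mature position of the seed (1-based, inclusive)
SEED_END = 8  #: last mature position of the seed (1-based, inclusive)
SUPP_START = 13  #: first position of the supplemental-pairing region
SUPP_END = 18  #: last position of the supplemental-pairing region
SEED_LENGTH = SEED_END - SEED_START + 1


class RegionClass(Enum):
    """Sub-region of a miRNA hairpin, exhaustive for any hairpin position.

    The five-way classification refines the three-way labelling commonly
    used in the literature ("seed" / "mature" / "precursor"): ``ANCHOR``,
    ``SUPPLEMENTARY`` and ``MATURE_OTHER`` are all "mature" at the
    three-way level.
    """

    SEED = "seed"
    ANCHOR = "anchor"
    SUPPLEMENTARY = "supplementary"
    MATURE_OTHER = "mature_other"
    PRECURSOR = "precursor"

    @property
    def paper_label(self) -> str:
        """Three-way label: seed, mature or precursor."""
        if self is RegionClass.SEED:
            return "seed"
        if self is RegionClass.PRECURSOR:
            return "precursor"
        return "mature"


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA arm: interval plus sequence written 5'->3'.

    The sequence is in miRNA orientation, i.e. for a minus-strand arm it is
    the reverse complement of the plus-strand genomic substring.  Mature
    position ``p`` (1-based from the 5' end) indexes this sequence directly.
    """

    arm_id: str
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) != self.interval.length:
            raise ValueError(
                f"arm {self.arm_id}: sequence length {len(seq)} != "
                f"interval length {self.interval.length}"
            )
        if len(seq) < 8:
            raise ValueError(
                f"arm {self.arm_id}: length {len(seq)} < 8, no seed definable"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def seed(self) -> str:
        """Seed region: mature positions 2-8 (1-based), 7 nt."""
        return self.sequence[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class MiRNALocus:
    """A miRNA hairpin (pre-miRNA) with one or two mature arms."""

    locus_id: str
    hairpin: GenomicInterval
    arms: tuple[MatureArm, ...]

    def __post_init__(self) -> None:
        arms = tuple(self.arms)
        object.__setattr__(self, "arms", arms)
        if not 1 <= len(arms) <= 2:
            raise ValueError(f"locus {self.locus_id}: expected 1-2 arms, got {len(arms)}")
        for arm in arms:
            if not self.hairpin.contains_interval(arm.interval):
                raise ValueError(
                    f"locus {self.locus_id}: arm {arm.arm_id} outside hairpin"
                )
            if arm.interval.strand != self.hairpin.strand:
                raise ValueError(
                    f"locus {self.locus_id}: arm {arm.arm_id} strand mismatch"
                )
        if len(arms) == 2 and arms[0].interval.overlaps(arms[1].interval):
            raise ValueError(f"locus {self.locus_id}: arms overlap")

    def arm_at(self, pos: int) -> MatureArm | None:
        """Return the arm covering genomic position ``pos``, if any."""
        for arm in self.arms:
            if arm.interval.contains(pos):
                return arm
        return None


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP. ``pos`` is 0-based (converted from 1-based VCF)."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    pop_presence: Mapping[str, bool] = field(default_factory=dict)
    alt_freq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref not in _DNA or self.alt not in _DNA:
            raise ValueError(
                f"variant {self.vid}: ref/alt must be single bases in ACGT, "
                f"got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"variant {self.vid}: ref == alt ({self.ref})")
        for pop, f in self.alt_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"variant {self.vid}: frequency {f} for {pop} not in [0,1]")


@dataclass(frozen=True)
class UTRModel:
    """A (possibly spliced) 3'UTR gene model.

    ``blocks`` are stored in transcript 5'->3' order, so for a minus-strand
    transcript the first block is the one with the highest genomic
    coordinates.  ``spliced_sequence`` is the mRNA-sense sequence.
    """

    transcript_id: str
    gene_id: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    spliced_sequence: str

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        seq = self.spliced_sequence.upper().replace("U", "T")
        object.__setattr__(self, "spliced_sequence", seq)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"UTR {self.transcript_id}: strand must be + or -")
        for a, b in zip(blocks, blocks[1:]):
            if a.overlaps(b):
                raise ValueError(f"UTR {self.transcript_id}: overlapping blocks")
        total = sum(b.length for b in blocks)
        if len(seq) != total:
            raise ValueError(
                f"UTR {self.transcript_id}: spliced length {len(seq)} != "
                f"sum of block lengths {total}"
            )

    @property
    def spliced_length(self) -> int:
        return len(self.spliced_sequence)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA sequence (strict A/C/G/T alphabet).

    Ambiguous bases are rejected; callers that must tolerate them (e.g. the
    target scanner) handle ambiguity with a no-match rule before calling.
    """
    bad = set(seq.upper()) - _DNA
    if bad:
        raise ValueError(f"ambiguous or non-DNA bases in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def genomic_to_mature_position(arm: MatureArm, genomic_pos: int) -> int:
    """Map a 0-based genomic position inside an arm to the 1-based mature
    position ``p`` counted from the miRNA 5' end.

    On the plus strand the 5' end is the lowest genomic coordinate; on the
    minus strand it is the highest, so the index runs backwards.
    """
    iv = arm.interval
    if not iv.contains(genomic_pos):
        raise ValueError(
            f"position {genomic_pos} outside arm {arm.arm_id} "
            f"({iv.chrom}:{iv.start}-{iv.end})"
        )
    if iv.strand == "-":
        return iv.end - genomic_pos
    return genomic_pos - iv.start + 1
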