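"""Readers and writers for the standard formats the pipeline consumes.

FASTA is handled through Biopython, GFF3 through gffutils and VCF through
cyvcf2.  Coordinates are converted between the 1-based inclusive file
conventions (GFF3, VCF) and the package's internal 0-based half-open
convention at this boundary and nowhere else.

The miRNA GFF3 dialect follows miRBase/miRCarta: hairpins are
``miRNA_primary_transcript`` features and mature arms are ``miRNA``
features pointing at their hairpin via ``Derives_from`` (``Parent`` is
accepted too).  Because mature-arm sequences are needed for seed
extraction, the writer embeds a ``seq`` attribute; the reader takes the
sequence from the genome when one is supplied and falls back to that
attribute otherwise.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from cyvcf2 import VCF

from .model import (
    GenomicInterval,
    MatureArm,
    MiRNALocus,
    UTRModel,
    Variant,
    reverse_complement,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mirna_gff3",
    "write_mirna_gff3",
    "read_vcf_snps",
    "write_vcf",
    "read_utr_bed12",
    "write_bed12",
]

_DNA = frozenset("ACGT")

HAIRPIN_FEATURE = "miRNA_primary_transcript"
MATURE_FEATURE = "miRNA"


def read_fasta(path: str | os.PathLike, with_alphabet: bool = False):
    """Read a FASTA file into an ordered mapping ``id -> sequence``.

    Sequences are uppercased and RNA (U) is normalised to DNA (T).  With
    ``with_alphabet=True`` a second mapping ``id -> "DNA"|"RNA"`` records
    the original alphabet so sequences can be re-emitted as they arrived.
    Duplicate identifiers raise a ``ValueError`` naming the identifier.
    """
    seqs: dict[str, str] = {}
    alphabet: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        raw = str(rec.seq).upper()
        alphabet[rec.id] = "RNA" if "U" in raw else "DNA"
        seqs[rec.id] = raw.replace("U", "T")
    if with_alphabet:
        return seqs, alphabet
    return seqs


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _arm_sequence(iv: GenomicInterval, genome: Mapping[str, str]) -> str:
    if iv.chrom not in genome:
        raise ValueError(f"chromosome {iv.chrom} not in genome")
    sub = genome[iv.chrom][iv.start : iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub


def read_mirna_gff3(
    path: str | os.PathLike, genome: Mapping[str, str] | None = None
) -> list[MiRNALocus]:
    """Parse a miRBase/miRCarta-style GFF3 into :class:`MiRNALocus` objects.

    1-based inclusive GFF3 coordinates become 0-based half-open.  Arm
    sequences come from ``genome`` when given (reverse-complemented for
    minus-strand arms), else from a ``seq`` attribute on the mature
    feature.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    hairpins: dict[str, gffutils.Feature] = {}
    order: list[str] = []
    for feat in db.features_of_type(HAIRPIN_FEATURE, order_by="start"):
        hid = feat.attributes.get("ID", [feat.id])[0]
        hairpins[hid] = feat
        order.append(hid)

    arms_by_parent: dict[str, list[MatureArm]] = {hid: [] for hid in hairpins}
    for feat in db.features_of_type(MATURE_FEATURE, order_by="start"):
        parents = feat.attributes.get("Derives_from") or feat.attributes.get("Parent")
        if not parents or parents[0] not in hairpins:
            raise ValueError(
                f"mature feature {feat.attributes.get('ID', ['?'])[0]} has no "
                "resolvable hairpin parent"
            )
        parent = parents[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if genome is not None:
            seq = _arm_sequence(iv, genome)
        elif "seq" in feat.attributes:
            seq = feat.attributes["seq"][0]
        else:
            raise ValueError(
                f"mature feature in {parent}: no genome given and no seq attribute"
            )
        arm_id = feat.attributes.get("ID", [f"{parent}_arm{len(arms_by_parent[parent])}"])[0]
        arms_by_parent[parent].append(MatureArm(arm_id, iv, seq))

    loci = []
    for hid in order:
        feat = hairpins[hid]
        hp = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        # arms ordered 5' -> 3' of the hairpin: descending start on "-"
        arms = sorted(
            arms_by_parent[hid],
            key=lambda a: -a.interval.start if hp.strand == "-" else a.interval.start,
        )
        try:
            loci.append(MiRNALocus(hid, hp, tuple(arms)))
        except ValueError as exc:
            raise ValueError(f"invalid locus {hid}: {exc}") from exc
    return loci


def write_mirna_gff3(path: str | os.PathLike, loci: Iterable[MiRNALocus]) -> None:
    """Write loci back to GFF3 (1-based inclusive), embedding arm sequences."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            hp = locus.hairpin
            fh.write(
                "\t".join(
                    [
                        hp.chrom, "mirvar", HAIRPIN_FEATURE,
                        str(hp.start + 1), str(hp.end), ".", hp.strand, ".",
                        f"ID={locus.locus_id};Name={locus.locus_id}",
                    ]
                )
                + "\n"
            )
            for arm in locus.arms:
                iv = arm.interval
                fh.write(
                    "\t".join(
                        [
                            iv.chrom, "mirvar", MATURE_FEATURE,
                            str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                            f"ID={arm.arm_id};Derives_from={locus.locus_id};seq={arm.sequence}",
                        ]
                    )
                    + "\n"
                )


def read_vcf_snps(
    path: str | os.PathLike, population_label: str | None = None
) -> list[Variant]:
    """Read biallelic SNPs from a VCF.

    Multiallelic records are split into one :class:`Variant` per single-base
    ALT; non-SNP alleles (InDels, symbolic) are dropped.  Positions become
    0-based.  Per-population presence and alternative-allele frequencies are
    taken from ``PRES`` / ``PAF`` INFO fields when present (the encoding the
    simulator writes); ``population_label``, if given, marks every retained
    variant as present in that population.
    """
    out: list[Variant] = []
    vcf = VCF(str(path))
    for rec in vcf:
        ref = rec.REF.upper()
        if len(ref) != 1 or ref not in _DNA:
            continue
        presence: dict[str, bool] = {}
        freqs: dict[str, float] = {}
        pres_info = rec.INFO.get("PRES")
        if pres_info:
            for pop in str(pres_info).split(","):
                presence[pop] = True
        paf_info = rec.INFO.get("PAF")
        if paf_info:
            for item in str(paf_info).split(","):
                pop, _, f = item.partition(":")
                freqs[pop] = float(f)
        if population_label is not None:
            presence[population_label] = True
        for k, alt in enumerate(rec.ALT):
            alt = alt.upper()
            if len(alt) != 1 or alt not in _DNA:
                continue
            vid = rec.ID if rec.ID and len(rec.ALT) == 1 else (
                f"{rec.ID or rec.CHROM + '_' + str(rec.POS)}"
                + (f"_{alt}" if len(rec.ALT) > 1 else "")
            )
            out.append(
                Variant(
                    chrom=rec.CHROM, pos=rec.POS - 1, vid=vid,
                    ref=ref, alt=alt,
                    pop_presence=dict(presence), alt_freq=dict(freqs),
                )
            )
    return out


def write_vcf(
    path: str | os.PathLike,
    variants: Iterable[Variant],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write variants as VCF 4.2, encoding per-population presence in
    ``PRES`` and frequencies in ``PAF`` INFO fields."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=PRES,Number=.,Type=String,'
            'Description="Populations where the ALT allele segregates">\n'
        )
        fh.write(
            '##INFO=<ID=PAF,Number=.,Type=String,'
            'Description="Per-population ALT frequency, pop:freq">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info_parts = []
            pres = [p for p, flag in v.pop_presence.items() if flag]
            if pres:
                info_parts.append("PRES=" + ",".join(pres))
            if v.alt_freq:
                info_parts.append(
                    "PAF=" + ",".join(f"{p}:{f:.6g}" for p, f in v.alt_freq.items())
                )
            info = ";".join(info_parts) or "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


def read_utr_bed12(
    path: str | os.PathLike, genome: Mapping[str, str]
) -> list[UTRModel]:
    """Read 3'UTR gene models from BED12 and assemble spliced sequences.

    The BED name field may carry ``transcript_id|gene_id``; a bare name is
    used for both.  For minus-strand models the blocks are reordered into
    transcript 5'->3' order and the spliced sequence reverse-complemented.
    """
    utrs: list[UTRModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path} line {lineno}: expected 12 BED fields")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path} line {lineno}: block count mismatch")
            if chrom not in genome:
                raise ValueError(f"{path} line {lineno}: unknown chromosome {chrom}")
            chrom_len = len(genome[chrom])
            blocks_fwd = []
            for size, off in zip(sizes, starts):
                b0 = chrom_start + off
                b1 = b0 + size
                if b1 > chrom_len:
                    raise ValueError(
                        f"{path} line {lineno}: block {b0}-{b1} outside {chrom} "
                        f"(length {chrom_len})"
                    )
                blocks_fwd.append(GenomicInterval(chrom, b0, b1, strand))
            plus_seq = "".join(genome[chrom][b.start : b.end] for b in blocks_fwd)
            if strand == "-":
                blocks = tuple(reversed(blocks_fwd))
                seq = reverse_complement(plus_seq)
            else:
                blocks = tuple(blocks_fwd)
                seq = plus_seq
            tx_id, _, gene_id = name.partition("|")
            utrs.append(UTRModel(tx_id, gene_id or tx_id, strand, blocks, seq))
    return utrs


def write_bed12(path: str | os.PathLike, utrs: Iterable[UTRModel]) -> None:
    with open(path, "w") as fh:
        for utr in utrs:
            blocks = sorted(utr.blocks, key=lambda b: b.start)
            chrom_start = blocks[0].start
            chrom_end = blocks[-1].end
            sizes = ",".join(str(b.length) for b in blocks)
            offsets = ",".join(str(b.start - chrom_start) for b in blocks)
            name = (
                utr.transcript_id
                if utr.gene_id == utr.transcript_id
                else f"{utr.transcript_id}|{utr.gene_id}"
            )
            fh.write(
                "\t".join(
                    [
                        blocks[0].chrom, str(chrom_start), str(chrom_end), name,
                        "0", utr.strand, str(chrom_start), str(chrom_end), "0",
                        str(len(blocks)), sizes, offsets,
                    ]
                )
                + "\n"
            )
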