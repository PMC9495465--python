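"""Allele-aware pseudo-promoters and the chromatin-accessibility gate.

A pseudo-promoter is the 2 kb of sequence immediately upstream of a gene's
transcription start site, re-written so that every embedded common SNP
carries its major allele. Scoring a variant then swaps in the minor allele
one SNP at a time (all other SNPs stay at major allele), which mirrors how
per-SNP effects are reported.

For minus-strand genes the promoter is the reverse complement of the
genomic slice downstream of the TSS, so the TSS-proximal end is always the
rightmost base and motif offsets read 5'->3' on the transcribed strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._seq import complement, revcomp
from .formats import AccessibilityTrack, SNPRecord

logger = logging.getLogger(__name__)

__all__ = ["PromoterSpec", "PseudoPromoter", "build_pseudopromoter",
           "apply_minor_allele", "is_accessible"]


@dataclass(frozen=True)
class PromoterSpec:
    """Where to cut a proximal promoter: gene, contig, 1-based TSS, strand."""

    gene_symbol: str
    chrom: str
    tss: int            # 1-based genomic coordinate of the TSS
    strand: str = "+"
    length: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_symbol}: strand must be '+' or '-'")
        if self.length <= 0:
            raise ValueError(f"{self.gene_symbol}: length must be positive")
        if self.tss < 1:
            raise ValueError(f"{self.gene_symbol}: tss must be 1-based")


@dataclass(frozen=True)
class PseudoPromoter:
    """A promoter sequence carrying major alleles at every embedded SNP."""

    gene_symbol: str
    sequence: str                                  # uppercase, promoter orientation
    chrom: str
    start: int                                     # 0-based half-open genomic interval
    end: int
    strand: str
    snps: tuple[tuple[SNPRecord, int], ...]        # (record, local offset) pairs

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.gene_symbol}: sequence length != interval length")
        for snp, offset in self.snps:
            if not 0 <= offset < len(self.sequence):
                raise ValueError(f"{self.gene_symbol}/{snp.rsid}: offset {offset} out of range")

    @property
    def genomic_interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def offset_of(self, rsid: str) -> int:
        for snp, offset in self.snps:
            if snp.rsid == rsid:
                return offset
        raise KeyError(f"{rsid} not embedded in promoter of {self.gene_symbol}")

    def snp(self, rsid: str) -> SNPRecord:
        for snp, _ in self.snps:
            if snp.rsid == rsid:
                return snp
        raise KeyError(f"{rsid} not embedded in promoter of {self.gene_symbol}")

    def to_fasta_header(self) -> str:
        return f"{self.gene_symbol}|{self.chrom}:{self.start}-{self.end}|{self.strand}"


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a dict-of-strings or any indexed FASTA source."""
    try:
        contig = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not in genome") from exc
    if start < 0 or end > len(contig):
        raise ValueError(
            f"interval [{start}, {end}) outside contig {chrom} (length {len(contig)})")
    return str(contig[start:end]).upper()


def build_pseudopromoter(
    spec: PromoterSpec,
    genome: Mapping[str, object],
    snps: Sequence[SNPRecord],
) -> PseudoPromoter:
    """Extract the promoter interval and substitute major alleles at SNPs.

    Plus strand: interval ``[tss-1-length, tss-1)``. Minus strand: interval
    ``[tss, tss+length)``, sequence reverse-complemented. SNPs outside the
    interval are excluded (logged). A reference base disagreeing with both
    alleles is a warning; the major allele is substituted regardless, since
    the pseudo-promoter is defined by the SNP catalogue.
    """
    tss0 = spec.tss - 1
    if spec.strand == "+":
        start, end = tss0 - spec.length, tss0
    else:
        start, end = tss0 + 1, tss0 + 1 + spec.length
    seq = list(_fetch(genome, spec.chrom, start, end))

    kept: list[tuple[SNPRecord, int]] = []
    for snp in snps:
        if snp.chrom != spec.chrom or not (start <= snp.pos - 1 < end):
            logger.info("%s: SNP %s at %s:%d outside promoter [%d, %d); excluded",
                        spec.gene_symbol, snp.rsid, snp.chrom, snp.pos, start, end)
            continue
        # substitute in genomic orientation; the final reverse complement of
        # a minus-strand promoter complements the base automatically
        offset = snp.pos - 1 - start
        ref = seq[offset]
        if ref not in (snp.major_allele, snp.minor_allele):
            logger.warning("%s: reference base %s at %s:%d matches neither allele of %s "
                           "(%s/%s); major allele substituted",
                           spec.gene_symbol, ref, snp.chrom, snp.pos, snp.rsid,
                           snp.major_allele, snp.minor_allele)
        seq[offset] = snp.major_allele
        kept.append((snp, offset))

    if spec.strand == "-":
        sequence = revcomp("".join(seq))
        kept = [(snp, spec.length - 1 - off) for snp, off in kept]
    else:
        sequence = "".join(seq)
    kept.sort(key=lambda pair: pair[1])
    return PseudoPromoter(
        gene_symbol=spec.gene_symbol, sequence=sequence, chrom=spec.chrom,
        start=start, end=end, strand=spec.strand, snps=tuple(kept),
    )


def apply_minor_allele(pp: PseudoPromoter, rsid: str) -> str:
    """Promoter sequence with exactly one SNP switched to its minor allele.

    The promoter-strand base is the minor allele (complemented for minus-
    strand genes); every other SNP stays at major allele. Raises KeyError
    for an unknown rsid.
    """
    offset = pp.offset_of(rsid)
    snp = pp.snp(rsid)
    minor = snp.minor_allele if pp.strand == "+" else complement(snp.minor_allele)
    return pp.sequence[:offset] + minor + pp.sequence[offset + 1:]


def is_accessible(track: AccessibilityTrack, chrom: str, pos_1based: int) -> bool:
    """True iff the 1-based position falls in an open-chromatin interval.

    Intervals are 0-based half-open, so position ``p`` is accessible when
    ``p-1 in [start, end)`` for some interval on the same chromosome.
    """
    p = pos_1based - 1
    for c, start, end in track.intervals:
        if c == chrom and start <= p < end:
            return True
    return False
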