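"""Readers and writers for every external representation the pipeline touches.

Supported formats: JASPAR-text position frequency matrices, SNP tables
(named-column TSV or a minimal VCF subset), BED3(+name) accessibility
intervals, FASTA, and the tab-separated call report mirroring the scoring
output layout.

Coordinate convention: all interval inputs are normalized to 0-based
half-open on read. The only 1-based coordinate in the package is
``SNPRecord.pos`` (VCF convention); it is converted wherever intervals or
promoter offsets are built.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import RSNPCall

logger = logging.getLogger(__name__)

#: ENCODE DNase cell lines used as accessibility gates: human cardiac
#: myocytes, primary cardiac fibroblasts, cerebellar astrocytes, umbilical
#: vein endothelial cells, and T-helper-1 lymphocytes.
CELL_LINES = ("Hcm", "Hcf", "Hac", "Huvec", "TH1")

#: Minor allele frequency above which a SNP counts as "common".
COMMON_MAF = 0.01


class FormatError(ValueError):
    """Malformed input in one of the supported text formats."""


def _as_stream(stream: Union[str, TextIO]) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class PanelCategory(str, Enum):
    """Disease-process groups of the candidate modifier-gene panel."""

    interleukins = "interleukins"
    fibrosis_sclerosis = "fibrosis_sclerosis"
    renal = "renal"
    endothelial_vascular = "endothelial_vascular"


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene of the candidate panel with its common-SNP count."""

    gene_symbol: str
    category: PanelCategory
    n_common_snps: int

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.n_common_snps < 0:
            raise ValueError("n_common_snps must be >= 0")


@dataclass(frozen=True)
class PFM:
    """A position frequency matrix: per-column base counts, rows A,C,G,T."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, width), non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise FormatError(
                f"matrix {self.matrix_id}: counts must be 4 x w with w >= 1"
            )
        if np.any(counts < 0):
            raise FormatError(f"matrix {self.matrix_id}: negative count")
        if np.any(counts.sum(axis=0) <= 0):
            raise FormatError(
                f"matrix {self.matrix_id}: column with no positive count"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties resolved in A,C,G,T order)."""
        return "".join(BASES[j] for j in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP with 1-based genomic position and minor allele frequency."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    major_allele: str
    minor_allele: str
    maf: float
    population: str = "ALL"

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be 1-based (>= 1)")
        for name, allele in (("major", self.major_allele), ("minor", self.minor_allele)):
            if allele not in ("A", "C", "G", "T"):
                raise ValueError(f"{self.rsid}: {name} allele {allele!r} is not a single base")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: major and minor alleles are identical")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf {self.maf} outside (0, 0.5]")

    @property
    def common(self) -> bool:
        """True for common SNPs (MAF > 1%), the analysis universe."""
        return self.maf > COMMON_MAF


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> tuple[tuple[str, int, int], ...]:
    """Sort and merge overlapping/bookended 0-based half-open intervals."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return tuple(merged)


@dataclass
class AccessibilityTrack:
    """Open-chromatin intervals for one cell line (0-based half-open, merged)."""

    cell_line: str
    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(
                f"unknown cell line {self.cell_line!r}; expected one of {CELL_LINES}"
            )
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.cell_line}: empty interval {chrom}:{start}-{end}")
        self.intervals = merge_intervals(self.intervals)

    @property
    def covered_length(self) -> int:
        return sum(end - start for _, start, end in self.intervals)


# ---------------------------------------------------------------------------
# JASPAR-text PFMs
# ---------------------------------------------------------------------------

def read_jaspar_pfm(stream: Union[str, TextIO]) -> list[PFM]:
    """Parse JASPAR-text matrices: ``>ID NAME`` then four count rows (A,C,G,T).

    Rows may be bracketed (``A [ 1 2 3 ]``) or bare numbers; the writer always
    emits bracketed rows. Raises :class:`FormatError` naming the matrix ID on
    a missing row, ragged widths, or a negative count.
    """
    lines = [ln.strip() for ln in _as_stream(stream) if ln.strip()]
    pfms: list[PFM] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"expected '>' header, got {header!r}")
        parts = header[1:].split(None, 1)
        if not parts:
            raise FormatError("empty JASPAR header line")
        matrix_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else matrix_id
        i += 1
        rows: list[list[float]] = []
        for base in BASES:
            if i >= len(lines) or lines[i].startswith(">"):
                raise FormatError(
                    f"matrix {matrix_id}: missing count row for {base}"
                )
            rows.append(_parse_jaspar_row(lines[i], base, matrix_id))
            i += 1
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"matrix {matrix_id}: ragged row widths {sorted(widths)}")
        counts = np.array(rows, dtype=float)
        if np.any(counts < 0):
            raise FormatError(f"matrix {matrix_id}: negative count")
        pfms.append(PFM(matrix_id=matrix_id, tf_name=tf_name, counts=counts))
    return pfms


def _parse_jaspar_row(line: str, expected_base: str, matrix_id: str) -> list[float]:
    tokens = line.replace("[", " ").replace("]", " ").split()
    if tokens and tokens[0].isalpha():
        if tokens[0].upper() != expected_base:
            raise FormatError(
                f"matrix {matrix_id}: row labelled {tokens[0]!r} where {expected_base} expected"
            )
        tokens = tokens[1:]
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"matrix {matrix_id}: unparsable count in row {line!r}") from exc


def write_jaspar_pfm(pfms: Sequence[PFM]) -> str:
    """Serialize PFMs in bracketed JASPAR-text form."""
    out: list[str] = []
    for pfm in pfms:
        out.append(f">{pfm.matrix_id} {pfm.tf_name}")
        for base, row in zip(BASES, pfm.counts):
            cells = " ".join(_fmt_num(v) for v in row)
            out.append(f"{base} [ {cells} ]")
    return "\n".join(out) + ("\n" if out else "")


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

_TSV_ALIASES = {
    "rsid": "rsid", "id": "rsid",
    "chrom": "chrom", "chr": "chrom",
    "pos": "pos", "position": "pos",
    "major": "major_allele", "major_allele": "major_allele", "ref": "major_allele",
    "minor": "minor_allele", "minor_allele": "minor_allele", "alt": "minor_allele",
    "maf": "maf",
    "population": "population", "pop": "population",
}


def read_snp_table(stream: Union[str, TextIO], dialect: str = "tsv") -> list[SNPRecord]:
    """Read biallelic SNPs from a named-column TSV or a minimal VCF.

    Multi-allelic VCF lines are reduced to the most frequent ALT (logged);
    records with MAF <= 1% are retained and flagged not-common via
    :attr:`SNPRecord.common`. REF/ALT fields that are not single bases skip
    the record with a warning; an unparsable frequency raises.
    """
    if dialect == "tsv":
        return _read_snp_tsv(_as_stream(stream))
    if dialect == "vcf_min":
        return _read_snp_vcf(_as_stream(stream))
    raise ValueError(f"unknown SNP table dialect {dialect!r}")


def _read_snp_tsv(stream: TextIO) -> list[SNPRecord]:
    rows = [ln.rstrip("\n") for ln in stream if ln.strip() and not ln.startswith("#")]
    if not rows:
        return []
    header = [_TSV_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in rows[0].split("\t")]
    required = {"rsid", "chrom", "pos", "major_allele", "minor_allele", "maf"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"SNP TSV missing columns: {sorted(missing)}")
    records: list[SNPRecord] = []
    for lineno, row in enumerate(rows[1:], start=2):
        cells = dict(zip(header, row.split("\t")))
        major, minor = cells["major_allele"].upper(), cells["minor_allele"].upper()
        if major not in ("A", "C", "G", "T") or minor not in ("A", "C", "G", "T"):
            logger.warning("SNP TSV line %d (%s): alleles %s/%s not single bases; record skipped",
                           lineno, cells.get("rsid", "?"), major, minor)
            continue
        try:
            maf = float(cells["maf"])
        except ValueError as exc:
            raise FormatError(f"SNP TSV line {lineno}: unparsable maf {cells['maf']!r}") from exc
        records.append(SNPRecord(
            rsid=cells["rsid"], chrom=cells["chrom"], pos=int(cells["pos"]),
            major_allele=major, minor_allele=minor, maf=maf,
            population=cells.get("population", "ALL") or "ALL",
        ))
    return records


def _read_snp_vcf(stream: TextIO, af_key: str = "AF") -> list[SNPRecord]:
    records: list[SNPRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"VCF line {lineno}: fewer than 5 columns")
        chrom, pos_s, rsid, ref, alt_field = fields[:5]
        info = fields[7] if len(fields) >= 8 else ""
        alts = alt_field.split(",")
        afs = _parse_af(info, af_key, n_alts=len(alts), lineno=lineno)
        # multi-allelic: reduce to the most frequent ALT
        best = int(np.argmax(afs))
        if len(alts) > 1:
            logger.info("VCF line %d (%s): multi-allelic reduced to most frequent ALT %s "
                        "(AF=%s)", lineno, rsid, alts[best], afs[best])
        alt, af = alts[best].upper(), afs[best]
        ref = ref.upper()
        if ref not in ("A", "C", "G", "T") or alt not in ("A", "C", "G", "T"):
            logger.warning("VCF line %d (%s): REF/ALT %s/%s not single bases; record skipped",
                           lineno, rsid, ref, alt)
            continue
        if not 0.0 < af < 1.0:
            raise FormatError(f"VCF line {lineno} ({rsid}): allele frequency {af} outside (0,1)")
        if af > 0.5:  # ALT is actually the major allele
            major, minor, maf = alt, ref, 1.0 - af
            logger.info("VCF line %d (%s): ALT frequency %.3f > 0.5; ALT taken as major allele",
                        lineno, rsid, af)
        else:
            major, minor, maf = ref, alt, af
        if rsid in (".", ""):
            rsid = f"{chrom}_{pos_s}"
        records.append(SNPRecord(rsid=rsid, chrom=chrom, pos=int(pos_s),
                                 major_allele=major, minor_allele=minor, maf=maf))
    return records


def _parse_af(info: str, af_key: str, n_alts: int, lineno: int) -> list[float]:
    for entry in info.split(";"):
        if "=" in entry:
            key, _, value = entry.partition("=")
            if key == af_key:
                try:
                    afs = [float(v) for v in value.split(",")]
                except ValueError as exc:
                    raise FormatError(
                        f"VCF line {lineno}: unparsable {af_key} value {value!r}"
                    ) from exc
                if len(afs) != n_alts:
                    raise FormatError(
                        f"VCF line {lineno}: {af_key} has {len(afs)} values for {n_alts} ALTs"
                    )
                return afs
    raise FormatError(f"VCF line {lineno}: no {af_key} key in INFO")


def write_snp_table(snps: Sequence[SNPRecord]) -> str:
    """Serialize SNPs as the named-column TSV dialect."""
    lines = ["rsid\tchrom\tpos\tmajor_allele\tminor_allele\tmaf\tpopulation"]
    for s in snps:
        lines.append(f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.major_allele}\t"
                     f"{s.minor_allele}\t{s.maf:.6g}\t{s.population}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BED accessibility intervals
# ---------------------------------------------------------------------------

def read_bed(stream: Union[str, TextIO], cell_line: str = "Hcm") -> AccessibilityTrack:
    """Read BED3/BED3+name intervals (0-based half-open), sorted and merged."""
    intervals: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(_as_stream(stream), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"BED line {lineno}: fewer than 3 fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise FormatError(f"BED line {lineno}: start {start} >= end {end}")
        intervals.append((chrom, start, end))
    return AccessibilityTrack(cell_line=cell_line, intervals=tuple(intervals))


def write_bed(track: AccessibilityTrack) -> str:
    lines = [f"{chrom}\t{start}\t{end}\t{track.cell_line}"
             for chrom, start, end in track.intervals]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: Union[str, TextIO]) -> dict[str, str]:
    """Read a FASTA stream into an ordered {name: uppercase sequence} map."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(_as_stream(stream), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 60) -> str:
    """Serialize name->sequence pairs as wrapped FASTA."""
    items = records.items() if isinstance(records, Mapping) else records
    buf = io.StringIO()
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        buf, "fasta")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Call report TSV (mirrors the published result-table layout)
# ---------------------------------------------------------------------------

CALLS_HEADER = ("Gene", "rSNP", "CellLine", "TF", "RBS_M", "RBSm",
                "AffinityImpactPct", "HR", "HWF", "FIF", "Category")


def write_calls_tsv(calls: Sequence["RSNPCall"]) -> str:
    """Serialize scored calls; numeric fields are rendered to 2 decimals."""
    lines = ["\t".join(CALLS_HEADER)]
    for c in calls:
        lines.append("\t".join((
            c.gene_symbol, c.rsid, c.cell_line, c.tf_name,
            f"{c.rbs_major:.2f}", f"{c.rbs_minor:.2f}",
            f"{c.affinity_impact_pct:.2f}", str(c.hr), f"{c.hwf:.2f}",
            f"{c.fif:.2f}", c.category.value,
        )))
    return "\n".join(lines) + "\n"


def read_calls_tsv(stream: Union[str, TextIO]) -> list["RSNPCall"]:
    """Read a call report back into RSNPCall records (round-trips the writer)."""
    from .scoring import Category, RSNPCall  # deferred: avoids import cycle

    rows = [ln.rstrip("\n") for ln in _as_stream(stream) if ln.strip()]
    if not rows:
        return []
    header = tuple(rows[0].split("\t"))
    if header != CALLS_HEADER:
        raise FormatError(f"unexpected calls header {header!r}")
    calls = []
    for row in rows[1:]:
        (gene, rsid, cell_line, tf, rbs_m, rbs_n, impact, hr, _hwf, fif, cat) = row.split("\t")
        calls.append(RSNPCall(
            gene_symbol=gene, rsid=rsid, cell_line=cell_line, tf_name=tf,
            rbs_major=float(rbs_m), rbs_minor=float(rbs_n),
            affinity_impact_pct=float(impact), hr=int(hr), fif=float(fif),
            category=Category(cat),
        ))
    return calls
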