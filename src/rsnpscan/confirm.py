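"""Evidence aggregation over externally produced variant annotations.

The pipeline's motif-based predictions are cross-checked against scores
that external tools and databases assign to the same variants: GWAVA and
FunSeq2 deleteriousness calls, DeepSEA's probability that the variant is an
eQTL, Ensembl/GTEx eQTL effect evidence, and expression level of the host
gene in the relevant cell line. Those scores are ingested as data — this
module never runs the external models.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Optional, Sequence, TextIO, Union

from .formats import FormatError, _as_stream

__all__ = [
    "EvidenceRecord", "MValueCategory", "ExpressionCategory", "ConfirmRules",
    "mvalue_category", "expression_category", "confirm_rsnp",
    "summarize_predictions", "Summary", "read_evidence_tsv", "write_evidence_tsv",
]


class MValueCategory(str, Enum):
    """Per-tissue posterior call for an eQTL effect (GTEx m-value)."""

    no_eqtl_effect = "no_eqtl_effect"
    indeterminate = "indeterminate"
    eqtl_effect = "eqtl_effect"


class ExpressionCategory(str, Enum):
    """Expression-level bins on the TPM/FPKM scale."""

    below_cutoff = "below_cutoff"
    low = "low"
    medium = "medium"
    high = "high"


_EXPR_RANK = {c: i for i, c in enumerate(ExpressionCategory)}


def mvalue_category(m: float) -> MValueCategory:
    """m < 0.1: no eQTL effect predicted; m > 0.9: eQTL effect; else indeterminate."""
    if m < 0:
        raise ValueError(f"m-value must be >= 0, got {m}")
    if m < 0.1:
        return MValueCategory.no_eqtl_effect
    if m > 0.9:
        return MValueCategory.eqtl_effect
    return MValueCategory.indeterminate


def expression_category(v: float) -> ExpressionCategory:
    """Bin a TPM/FPKM value: <0.5 below cutoff, <=10 low, <=1000 medium, else high.

    The published cutoffs leave a gap between 10 and 11; the boundary is
    closed at 10 (values in (10, 11) count as medium).
    """
    if v < 0:
        raise ValueError(f"expression value must be >= 0, got {v}")
    if v < 0.5:
        return ExpressionCategory.below_cutoff
    if v <= 10:
        return ExpressionCategory.low
    if v <= 1000:
        return ExpressionCategory.medium
    return ExpressionCategory.high


_EVIDENCE_FIELDS = (
    "gwava_score", "gwava_label", "funseq2_score", "funseq2_label",
    "deepsea_eqtl_prob", "ensembl_effect_size", "gtex_m_value", "expression_value",
)


@dataclass(frozen=True)
class EvidenceRecord:
    """External annotations for one (rsid, cell line); absent fields are None."""

    rsid: str
    cell_line: str
    gene_symbol: Optional[str] = None
    gwava_score: Optional[float] = None
    gwava_label: Optional[str] = None             # "deleterious" | "neutral"
    funseq2_score: Optional[float] = None
    funseq2_label: Optional[str] = None
    deepsea_eqtl_prob: Optional[float] = None
    ensembl_effect_size: Optional[float] = None
    gtex_m_value: Optional[float] = None
    expression_value: Optional[float] = None      # TPM or FPKM
    encode_log2_expression: Optional[float] = None  # log2(TPM/FPKM + 0.01)

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if all(getattr(self, f) is None for f in _EVIDENCE_FIELDS):
            raise ValueError(f"{self.rsid}: evidence record with no evidence fields")
        for label in (self.gwava_label, self.funseq2_label):
            if label is not None and label not in ("deleterious", "neutral"):
                raise ValueError(f"{self.rsid}: label {label!r} not deleterious/neutral")
        if self.deepsea_eqtl_prob is not None and not 0.0 <= self.deepsea_eqtl_prob <= 1.0:
            raise ValueError(f"{self.rsid}: DeepSEA probability outside [0, 1]")


@dataclass(frozen=True)
class ConfirmRules:
    """Configurable any-evidence confirmation rule set.

    A variant is confirmed as a true rSNP when ANY enabled clause holds on
    ANY of its evidence records. Each satisfied clause contributes a tag.
    """

    deepsea_cutoff: float = 0.5
    min_expression: ExpressionCategory = ExpressionCategory.low
    use_gwava: bool = True
    use_funseq2: bool = True
    use_deepsea: bool = True
    use_gtex: bool = True
    use_ensembl: bool = True
    use_expression: bool = True


def confirm_rsnp(
    evidence: Sequence[EvidenceRecord],
    rules: ConfirmRules | None = None,
) -> tuple[bool, list[str]]:
    """Aggregate evidence records for one rsid into a confirmation verdict.

    Returns ``(confirmed, tags)`` where tags name the satisfied clauses in a
    deterministic order. Adding evidence can only add tags, never remove
    them, so confirmation is monotone. Raises on an empty record list.
    """
    if not evidence:
        raise ValueError("confirm_rsnp requires at least one evidence record")
    rsids = {ev.rsid for ev in evidence}
    if len(rsids) > 1:
        raise ValueError(f"evidence records span multiple rsids: {sorted(rsids)}")
    rules = rules or ConfirmRules()
    tags: list[str] = []

    def any_record(pred) -> bool:
        return any(pred(ev) for ev in evidence)

    if rules.use_gwava and any_record(lambda ev: ev.gwava_label == "deleterious"):
        tags.append("gwava_deleterious")
    if rules.use_funseq2 and any_record(lambda ev: ev.funseq2_label == "deleterious"):
        tags.append("funseq2_deleterious")
    if rules.use_deepsea and any_record(
            lambda ev: ev.deepsea_eqtl_prob is not None
            and ev.deepsea_eqtl_prob >= rules.deepsea_cutoff):
        tags.append("deepsea_eqtl")
    if rules.use_gtex and any_record(
            lambda ev: ev.gtex_m_value is not None
            and mvalue_category(ev.gtex_m_value) is MValueCategory.eqtl_effect):
        tags.append("gtex_eqtl")
    if rules.use_ensembl and any_record(lambda ev: ev.ensembl_effect_size is not None):
        tags.append("ensembl_effect")
    if rules.use_expression and any_record(
            lambda ev: ev.expression_value is not None
            and _EXPR_RANK[expression_category(ev.expression_value)]
            >= _EXPR_RANK[rules.min_expression]):
        tags.append("expressed_in_cell_line")
    return bool(tags), tags


@dataclass(frozen=True)
class Summary:
    """Deterministic roll-up of calls plus external evidence."""

    n_rsnps: int
    n_genes: int
    n_cell_lines: int
    gwava_deleterious_fraction: float
    rsnps_by_gene: tuple[tuple[str, tuple[str, ...]], ...]
    confirmed: tuple[tuple[str, bool, tuple[str, ...]], ...]
    unmatched_call_rsids: tuple[str, ...]
    unmatched_evidence_rsids: tuple[str, ...]

    def to_text(self) -> str:
        lines = [
            f"distinct rSNPs: {self.n_rsnps}",
            f"genes: {self.n_genes}",
            f"cell lines: {self.n_cell_lines}",
            f"GWAVA-deleterious fraction: {100 * self.gwava_deleterious_fraction:.1f}%",
        ]
        for gene, rsids in self.rsnps_by_gene:
            lines.append(f"  {gene}: {', '.join(rsids)}")
        for rsid, ok, tags in self.confirmed:
            status = "confirmed" if ok else "unconfirmed"
            lines.append(f"  {rsid}: {status} ({', '.join(tags) if tags else '-'})")
        if self.unmatched_call_rsids:
            lines.append(f"calls without evidence: {', '.join(self.unmatched_call_rsids)}")
        if self.unmatched_evidence_rsids:
            lines.append(f"evidence without calls: {', '.join(self.unmatched_evidence_rsids)}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        lines = ["metric\tvalue",
                 f"n_rsnps\t{self.n_rsnps}",
                 f"n_genes\t{self.n_genes}",
                 f"n_cell_lines\t{self.n_cell_lines}",
                 f"gwava_deleterious_fraction\t{self.gwava_deleterious_fraction:.4f}"]
        return "\n".join(lines) + "\n"


def summarize_predictions(
    calls: Sequence,
    evidence: Sequence[EvidenceRecord],
    rules: ConfirmRules | None = None,
) -> Summary:
    """Count distinct rSNPs/genes/cell lines and fold in the evidence verdicts.

    ``calls`` may be any records with gene_symbol/rsid/cell_line attributes
    (scored calls or the published-table fixture). When no calls are given
    the evidence table alone defines the variant universe. The
    GWAVA-deleterious fraction is over distinct rSNPs.
    """
    call_rsids = sorted({c.rsid for c in calls})
    ev_by_rsid: dict[str, list[EvidenceRecord]] = {}
    for ev in evidence:
        ev_by_rsid.setdefault(ev.rsid, []).append(ev)
    universe = call_rsids or sorted(ev_by_rsid)

    genes = sorted({c.gene_symbol for c in calls}
                   or {ev.gene_symbol for ev in evidence if ev.gene_symbol})
    cell_lines = sorted({c.cell_line for c in calls}
                        or {ev.cell_line for ev in evidence if ev.cell_line})

    deleterious = [rsid for rsid in universe
                   if any(ev.gwava_label == "deleterious"
                          for ev in ev_by_rsid.get(rsid, []))]
    fraction = len(deleterious) / len(universe) if universe else 0.0

    by_gene: dict[str, set[str]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_symbol, set()).add(c.rsid)
    if not calls:
        for ev in evidence:
            if ev.gene_symbol:
                by_gene.setdefault(ev.gene_symbol, set()).add(ev.rsid)

    confirmed = tuple(
        (rsid, *(lambda r: (r[0], tuple(r[1])))(confirm_rsnp(ev_by_rsid[rsid], rules)))
        for rsid in sorted(ev_by_rsid))
    return Summary(
        n_rsnps=len(universe),
        n_genes=len(genes),
        n_cell_lines=len(cell_lines),
        gwava_deleterious_fraction=fraction,
        rsnps_by_gene=tuple((g, tuple(sorted(r))) for g, r in sorted(by_gene.items())),
        confirmed=confirmed,
        unmatched_call_rsids=tuple(r for r in call_rsids if r not in ev_by_rsid),
        unmatched_evidence_rsids=tuple(r for r in sorted(ev_by_rsid) if r not in call_rsids),
    )


# ---------------------------------------------------------------------------
# Evidence TSV (the published-table column set; "ND" or empty means absent)
# ---------------------------------------------------------------------------

_EV_HEADER = ("gene", "rsid", "cell_line", "gwava_score", "gwava_label",
              "funseq2_score", "funseq2_label", "deepsea_eqtl_prob",
              "ensembl_effect_size", "gtex_m_value", "expression_value",
              "encode_log2_expression")


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return None if cell in ("", "ND", "NA", ".") else float(cell)


def _opt_str(cell: str) -> Optional[str]:
    cell = cell.strip()
    return None if cell in ("", "ND", "NA", ".") else cell


def read_evidence_tsv(stream: Union[str, TextIO]) -> list[EvidenceRecord]:
    rows = [ln.rstrip("\n") for ln in _as_stream(stream) if ln.strip()]
    if not rows:
        return []
    header = tuple(c.strip() for c in rows[0].split("\t"))
    if header != _EV_HEADER:
        raise FormatError(f"unexpected evidence header {header!r}")
    records = []
    for row in rows[1:]:
        c = row.split("\t")
        if len(c) != len(_EV_HEADER):
            raise FormatError(f"evidence row has {len(c)} cells, expected {len(_EV_HEADER)}")
        records.append(EvidenceRecord(
            gene_symbol=_opt_str(c[0]), rsid=c[1].strip(), cell_line=c[2].strip(),
            gwava_score=_opt_float(c[3]), gwava_label=_opt_str(c[4]),
            funseq2_score=_opt_float(c[5]), funseq2_label=_opt_str(c[6]),
            deepsea_eqtl_prob=_opt_float(c[7]), ensembl_effect_size=_opt_float(c[8]),
            gtex_m_value=_opt_float(c[9]), expression_value=_opt_float(c[10]),
            encode_log2_expression=_opt_float(c[11]),
        ))
    return records


def write_evidence_tsv(records: Sequence[EvidenceRecord]) -> str:
    def cell(v) -> str:
        return "ND" if v is None else (v if isinstance(v, str) else f"{v:g}")

    lines = ["\t".join(_EV_HEADER)]
    for r in records:
        lines.append("\t".join(cell(v) for v in (
            r.gene_symbol, r.rsid, r.cell_line, r.gwava_score, r.gwava_label,
            r.funseq2_score, r.funseq2_label, r.deepsea_eqtl_prob,
            r.ensembl_effect_size, r.gtex_m_value, r.expression_value,
            r.encode_log2_expression)))
    return "\n".join(lines) + "\n"
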