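"""Packaged result-table fixtures: the gene panel, the 27 scored calls, and
the external-evidence table, transcribed verbatim from the published study.

Two FIF cells of the scored-call table (both at rs4987025) are printed with
a sign inconsistent with their own affinity impact; they are preserved
exactly as printed and carry ``sign_inconsistent=True`` so validation code
can compare magnitudes there and flag the discrepancy.
"""
from __future__ import annotations

from dataclasses import dataclass

from .confirm import EvidenceRecord, read_evidence_tsv
from .formats import GenePanelEntry, PanelCategory

__all__ = ["PrintedCall", "gene_panel", "printed_calls", "evidence_records",
           "table_fixtures"]


@dataclass(frozen=True)
class PrintedCall:
    """One row of the published call table, exactly as printed."""

    gene_symbol: str
    rsid: str
    cell_line: str
    tf_name: str
    rbs_major: float
    rbs_minor: float
    affinity_impact_pct: float
    hr: int
    hwf: float
    fif: float
    sign_inconsistent: bool = False


_PANEL = (
    ("TNF", PanelCategory.interleukins, 3),
    ("IL10", PanelCategory.interleukins, 8),
    ("IL1A", PanelCategory.interleukins, 6),
    ("IL1B", PanelCategory.interleukins, 5),
    ("IL6", PanelCategory.interleukins, 7),
    ("TGFB1", PanelCategory.fibrosis_sclerosis, 9),
    ("FGF2", PanelCategory.fibrosis_sclerosis, 11),
    ("MMP1", PanelCategory.fibrosis_sclerosis, 9),
    ("REN", PanelCategory.renal, 14),
    ("AGTR1", PanelCategory.renal, 8),
    ("AGT", PanelCategory.renal, 3),
    ("EDN1", PanelCategory.endothelial_vascular, 8),
    ("NOS3", PanelCategory.endothelial_vascular, 10),
    ("MTHFR", PanelCategory.endothelial_vascular, 9),
)

# gene, rsid, cell line, TF, RBS_M, RBSm, impact %, HR, HWF, FIF, flagged
_CALLS = (
    ("IL10", "rs76176414", "Hcm", "SPIB", 0.87, 0.70, -19.57, 1, 1.0, -19.57, False),
    ("IL10", "rs76176414", "Hac", "BATF:JUN", 0.82, 0.72, -11.54, 1, 1.0, -11.54, False),
    ("IL10", "rs1800895", "TH1", "USF2", 0.94, 0.81, -13.27, 1, 1.0, -13.27, False),
    ("IL10", "rs1800895", "TH1", "MLX", 0.80, 0.68, -15.10, 1, 1.0, -15.10, False),
    ("IL10", "rs1800895", "TH1", "BHLHE41", 0.81, 0.70, -13.42, 1, 1.0, -13.42, False),
    ("IL10", "rs1800895", "TH1", "BHLHE23", 0.87, 0.96, 10.40, 1, 1.0, 10.40, False),
    ("IL10", "rs1800895", "TH1", "BHLHE22", 0.86, 0.96, 11.51, 1, 1.0, 11.51, False),
    ("TGFB1", "rs1800468", "Hcm", "ESRRB", 0.84, 0.73, -12.77, 1, 1.0, -12.77, False),
    ("TGFB1", "rs1800468", "Hcm", "GMEB2", 0.83, 0.66, -20.76, 1, 1.0, -20.76, False),
    ("TGFB1", "rs1800468", "Hcm", "CREB1", 0.86, 0.73, -15.32, 1, 1.0, -15.32, False),
    ("TGFB1", "rs538246709", "Huvec", "LBX1", 0.80, 0.67, -16.15, 1, 1.0, -16.15, False),
    ("TGFB1", "rs538246709", "Huvec", "GATA3", 0.86, 0.73, -14.65, 1, 1.0, -14.65, False),
    ("TGFB1", "rs538246709", "Huvec", "ZEB1", 0.83, 0.69, -16.54, 1, 1.0, -16.54, False),
    # the next two FIF cells are printed with the opposite sign of their impact
    ("TGFB1", "rs4987025", "Huvec", "BATF::JUN", 0.80, 0.68, -14.20, 1, 1.0, 14.20, True),
    ("TGFB1", "rs4987025", "Huvec", "SMAD3", 0.80, 0.70, 12.52, 1, 1.0, -12.52, True),
    ("TGFB1", "rs538246709", "TH1", "LBX1", 0.80, 0.67, -16.15, 1, 1.0, -16.15, False),
    ("TGFB1", "rs538246709", "TH1", "GATA3", 0.86, 0.73, -14.65, 1, 1.0, -14.65, False),
    ("TGFB1", "rs538246709", "TH1", "ZEB1", 0.83, 0.69, -16.54, 1, 1.0, -16.54, False),
    ("EDN1", "rs879287158", "TH1", "CREB1", 0.80, 0.93, 16.53, 1, 1.0, 16.53, False),
    ("EDN1", "rs879287158", "TH1", "NOTO", 0.80, 0.61, -23.68, 2, 0.5, -11.84, False),
    ("EDN1", "rs572006226", "Hac", "HOXD12", 0.81, 0.69, -14.93, 1, 1.0, -14.93, False),
    ("EDN1", "rs879287158", "Hcf", "CREB1", 0.80, 0.93, 16.53, 1, 1.0, 16.53, False),
    ("EDN1", "rs879287158", "Hcf", "TCF3", 0.82, 0.65, -20.09, 2, 0.5, -10.04, False),
    ("EDN1", "rs879287158", "Hcm", "CREB1", 0.80, 0.93, 16.53, 1, 1.0, 16.53, False),
    ("EDN1", "rs879287158", "Huvec", "USF1", 0.81, 0.69, -15.61, 1, 1.0, -15.61, False),
    ("EDN1", "rs879287158", "Huvec", "CREB1", 0.80, 0.93, 16.53, 1, 1.0, 16.53, False),
    ("EDN1", "rs879287158", "Huvec", "TCF3", 0.82, 0.65, -20.09, 2, 0.5, -10.04, False),
)

# Column set of the published evidence table; ND = no data available.
# GWAVA/FunSeq2/DeepSEA scores apply per rsid and are repeated on each of its
# cell-line rows, as in the printed layout.
_EVIDENCE_TSV = """\
gene\trsid\tcell_line\tgwava_score\tgwava_label\tfunseq2_score\tfunseq2_label\tdeepsea_eqtl_prob\tensembl_effect_size\tgtex_m_value\texpression_value\tencode_log2_expression
IL10\trs76176414\tHcm\t0.32\tneutral\tND\tND\t0.68\tND\tND\t0.7\t0.01
IL10\trs76176414\tHac\t0.32\tneutral\tND\tND\t0.68\tND\tND\t0.4\t0.01
IL10\trs1800895\tTH1\t0.33\tneutral\t0\tneutral\t0.70\t0.22\tND\t0.9\t0.37
TGFB1\trs1800468\tHcm\t0.78\tdeleterious\t0.49\tneutral\t0.64\t0.24\tND\t27\t8.05
TGFB1\trs538246709\tHuvec\t0.58\tdeleterious\t0.49\tneutral\t0.55\tND\tND\t145\t7.25
TGFB1\trs4987025\tHuvec\t0.55\tdeleterious\t0.49\tneutral\t0.57\tND\tND\t145\t7.25
TGFB1\trs538246709\tTH1\t0.58\tdeleterious\t0.49\tneutral\t0.55\tND\tND\t38\t4.93
EDN1\trs879287158\tTH1\t0.71\tdeleterious\t3.22\tdeleterious\t0.95\tND\tND\t2\t1.04
EDN1\trs572006226\tHac\t0.47\tdeleterious\t3.59\tdeleterious\tND\tND\tND\t6\t5.85
EDN1\trs879287158\tHcf\t0.71\tdeleterious\t3.22\tdeleterious\t0.95\tND\tND\t8\t2.05
EDN1\trs879287158\tHcm\t0.71\tdeleterious\t3.22\tdeleterious\t0.95\tND\tND\t8\t1.18
EDN1\trs879287158\tHuvec\t0.71\tdeleterious\t3.22\tdeleterious\t0.95\tND\tND\t557\t5.69
"""


def gene_panel() -> list[GenePanelEntry]:
    """The 14-gene candidate-modifier panel with common-SNP counts."""
    return [GenePanelEntry(gene_symbol=g, category=c, n_common_snps=n)
            for g, c, n in _PANEL]


def printed_calls() -> list[PrintedCall]:
    """All 27 scored-call rows, values exactly as printed."""
    return [PrintedCall(*row[:10], sign_inconsistent=row[10]) for row in _CALLS]


def evidence_records() -> list[EvidenceRecord]:
    """The external-evidence table; ND cells are preserved as absent."""
    return read_evidence_tsv(_EVIDENCE_TSV)


def table_fixtures() -> tuple[list[GenePanelEntry], list[PrintedCall], list[EvidenceRecord]]:
    """The three packaged tables as typed records."""
    return gene_panel(), printed_calls(), evidence_records()
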