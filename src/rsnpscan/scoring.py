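"""The quantitative scoring chain for regulatory-SNP calls.

For a SNP inside an accessible promoter, each transcription factor matrix
yields a pair of relative binding scores (RBS_M for the major allele, RBSm
for the minor) at the best shared window. From those:

  affinity impact (%) = 100 * (RBSm - RBS_M) / RBS_M
  HR   = homotypic redundancy, the count of same-TF sites in the promoter
  HWF  = 1 / HR, discounting the loss of one site among redundant copies
  FIF  = affinity impact * HWF, the functional impact factor

Calls are reported when the best RBS clears the reporting floor (default
0.80) and |FIF| exceeds the reporting gate (default 10). Negative FIF
predicts decreased TF affinity for the minor allele; positive FIF above the
gate suggests the creation of a new binding site.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .formats import AccessibilityTrack
from .motif import PWM, count_homotypic_sites, scan_snp
from .promoter import PseudoPromoter, apply_minor_allele, is_accessible

logger = logging.getLogger(__name__)

__all__ = ["Category", "RSNPCall", "ScanConfig", "affinity_impact",
           "hwf_of", "fif_of", "categorize", "call_rsnps"]


class Category(str, Enum):
    """Qualitative outcome of a scored SNP-TF pair."""

    decreased_affinity = "decreased_affinity"
    increased_affinity = "increased_affinity"
    new_tfbs_suggested = "new_tfbs_suggested"
    below_threshold = "below_threshold"


@dataclass(frozen=True)
class RSNPCall:
    """One scored (gene, SNP, cell line, TF) record.

    ``hwf`` is derived (exactly 1/hr); ``fif`` is stored so that reports
    round-trip at 2-decimal printing, and is validated against
    impact * hwf within print rounding.
    """

    gene_symbol: str
    rsid: str
    cell_line: str
    tf_name: str
    rbs_major: float
    rbs_minor: float
    affinity_impact_pct: float
    hr: int
    fif: float
    category: Category

    def __post_init__(self) -> None:
        for name, v in (("rbs_major", self.rbs_major), ("rbs_minor", self.rbs_minor)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.rsid}/{self.tf_name}: {name} {v} outside [0, 1]")
        if self.hr < 1:
            raise ValueError(f"{self.rsid}/{self.tf_name}: hr must be >= 1")
        if abs(self.fif - self.affinity_impact_pct / self.hr) > 0.011:
            raise ValueError(
                f"{self.rsid}/{self.tf_name}: fif {self.fif} inconsistent with "
                f"impact {self.affinity_impact_pct} / hr {self.hr}")
        if self.fif != 0 and np.sign(self.fif) != np.sign(self.affinity_impact_pct):
            raise ValueError(f"{self.rsid}/{self.tf_name}: fif sign differs from impact sign")

    @property
    def hwf(self) -> float:
        """Homotypic redundancy weight factor, exactly 1/HR."""
        return 1.0 / self.hr

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.gene_symbol, self.rsid, self.cell_line, self.tf_name)


def affinity_impact(rbs_major: float, rbs_minor: float) -> float:
    """Signed percent change in binding score from major to minor allele.

    Negative values mean the minor allele loses affinity. Undefined (raises)
    when the major-allele score is zero.
    """
    if rbs_major <= 0:
        raise ValueError("affinity impact undefined for rbs_major = 0")
    return 100.0 * (rbs_minor - rbs_major) / rbs_major


def hwf_of(hr: int) -> float:
    """Homotypic redundancy weight factor: the exact reciprocal of HR."""
    if hr < 1:
        raise ValueError(f"hr must be >= 1, got {hr}")
    return 1.0 / hr


def fif_of(affinity_impact_pct: float, hr: int) -> float:
    """Functional impact factor: affinity impact discounted by redundancy."""
    return affinity_impact_pct * hwf_of(hr)


def categorize(
    fif: float,
    rbs_major: float,
    rbs_minor: float,
    fif_threshold: float = 10.0,
    rbs_floor: float = 0.80,
    creation_requires_weak_major: bool = False,
) -> Category:
    """Map a FIF value and its RBS pair to a qualitative category.

    |FIF| <= threshold is below_threshold; FIF < -threshold is
    decreased_affinity. A positive FIF above the threshold suggests the
    creation of a new TFBS (the published reading). With
    ``creation_requires_weak_major=True`` the creation label is reserved for
    sites the major allele does not already bind at reporting strength
    (RBS_M < rbs_floor); strengthened existing sites are then labelled
    increased_affinity.
    """
    if abs(fif) <= fif_threshold:
        return Category.below_threshold
    if fif < 0:
        return Category.decreased_affinity
    if creation_requires_weak_major and rbs_major >= rbs_floor and rbs_minor > rbs_major:
        return Category.increased_affinity
    if rbs_minor > rbs_major:
        return Category.new_tfbs_suggested
    return Category.increased_affinity  # unreachable under the standard impact definition


@dataclass(frozen=True)
class ScanConfig:
    """Tunable thresholds of the calling pipeline.

    rbs_floor: minimum best-allele RBS for a SNP-TF pair to be scored (the
        reporting floor, also the site threshold for HR counting).
    fif_threshold: symmetric reporting gate on |FIF|.
    pseudocount / background: PWM construction parameters.
    require_common: restrict calling to common SNPs (MAF > 1%).
    """

    rbs_floor: float = 0.80
    fif_threshold: float = 10.0
    pseudocount: float = 0.8
    background: Optional[tuple[float, float, float, float]] = None
    require_common: bool = True
    creation_requires_weak_major: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.rbs_floor <= 1.0:
            raise ValueError("rbs_floor must be in (0, 1]")
        if self.fif_threshold < 0:
            raise ValueError("fif_threshold must be >= 0")


def call_rsnps(
    promoters: Sequence[PseudoPromoter],
    pwms: Sequence[PWM],
    tracks: Sequence[AccessibilityTrack],
    config: ScanConfig | None = None,
) -> list[RSNPCall]:
    """Score every (promoter SNP, cell line, TF) combination and emit calls.

    For each SNP accessible in a cell line's open chromatin, every matrix is
    scanned over both alleles at the best shared window. Pairs whose best
    RBS clears ``config.rbs_floor`` are scored through the impact/HR/HWF/FIF
    chain (HR counted promoter-wide on the major-allele sequence, floored at
    1 since the SNP's own site passed the gate); calls with |FIF| above
    ``config.fif_threshold`` are kept. Output order is deterministic:
    (gene, rsid, cell line, TF). An empty result is valid.
    """
    config = config or ScanConfig()
    hr_cache: dict[tuple[str, str], int] = {}
    calls: list[RSNPCall] = []
    for pp in promoters:
        minor_seqs = {snp.rsid: apply_minor_allele(pp, snp.rsid) for snp, _ in pp.snps}
        for snp, offset in pp.snps:
            if config.require_common and not snp.common:
                continue
            for track in tracks:
                if not is_accessible(track, snp.chrom, snp.pos):
                    continue
                for pwm in pwms:
                    result = scan_snp(pwm, pp.sequence, minor_seqs[snp.rsid], offset)
                    if result is None:
                        continue
                    ws_major, ws_minor = result
                    if max(ws_major.rbs, ws_minor.rbs) < config.rbs_floor:
                        continue
                    if ws_major.rbs <= 0:
                        logger.warning("%s/%s: zero major-allele score; pair skipped",
                                       snp.rsid, pwm.tf_name)
                        continue
                    impact = affinity_impact(ws_major.rbs, ws_minor.rbs)
                    key = (pp.gene_symbol, pwm.source.matrix_id)
                    if key not in hr_cache:
                        hr_cache[key] = count_homotypic_sites(
                            pwm, pp.sequence, rbs_threshold=config.rbs_floor)
                    hr = max(1, hr_cache[key])  # the SNP's own site counts
                    fif = fif_of(impact, hr)
                    if abs(fif) <= config.fif_threshold:
                        continue
                    calls.append(RSNPCall(
                        gene_symbol=pp.gene_symbol, rsid=snp.rsid,
                        cell_line=track.cell_line, tf_name=pwm.tf_name,
                        rbs_major=ws_major.rbs, rbs_minor=ws_minor.rbs,
                        affinity_impact_pct=impact, hr=hr, fif=fif,
                        category=categorize(
                            fif, ws_major.rbs, ws_minor.rbs,
                            fif_threshold=config.fif_threshold,
                            rbs_floor=config.rbs_floor,
                            creation_requires_weak_major=config.creation_requires_weak_major),
                    ))
    calls.sort(key=RSNPCall.sort_key)
    return calls
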