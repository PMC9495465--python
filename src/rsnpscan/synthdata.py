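"""Seeded generator of synthetic promoters, motifs, SNPs and accessibility
tracks with planted ground truth.

The generator stands in for the population-variant, open-chromatin and
motif-database inputs of the real analysis so the whole pipeline runs with
no downloads. Each synthetic gene gets its own contig whose first 2 kb is
the promoter; motif instances are planted at well-separated offsets on
either DNA strand and three kinds of SNPs are embedded:

destroyer  at the maximally informative (anchor) column of a planted
           consensus site, major = consensus base, minor = worst base;
creator    at the anchor column of a near-miss site (consensus with the
           anchor base pre-mutated), where the minor allele restores the
           consensus;
neutral    in background sequence, rejection-sampled so that no window
           overlapping the SNP reaches the reporting floor for either
           allele under any generated matrix.

Truth labels are guaranteed by construction: after planting, each gene is
verified with the scoring machinery itself (site counts, score gates) and
its background is redrawn from the seed stream when a chance motif match
would contaminate the labels. All outputs are byte-reproducible from the
seed and are written through the formats module only.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._seq import BASES, complement, revcomp
from .formats import (PFM, AccessibilityTrack, CELL_LINES, SNPRecord,
                      write_bed, write_fasta, write_jaspar_pfm, write_snp_table)
from .motif import PWM, count_homotypic_sites, pfm_to_pwm, scan_snp
from .promoter import PromoterSpec, PseudoPromoter, apply_minor_allele, build_pseudopromoter
from .scoring import ScanConfig
from .tables import table_fixtures  # re-exported: packaged published tables

__all__ = ["SyntheticTruth", "PlantedSite", "SyntheticFixture",
           "generate_fixture", "exact_label_counts", "background_from_gc",
           "table_fixtures"]

#: motif design shared by every generated matrix (see docs/methods.md):
#: one maximally informative anchor column flanked by medium columns.
MOTIF_WIDTH = 16
ANCHOR_COL = MOTIF_WIDTH // 2
_ANCHOR_COUNTS = (100.0, 0.0)      # consensus, non-consensus
_MEDIUM_COUNTS = (73.0, 9.0)
_MIN_SLOT_SEP = 3 * MOTIF_WIDTH    # between SNP slot starts
_PEAK_HALFWIDTH = 12
_MAX_GENE_ATTEMPTS = 25

LABELS = ("destroyer", "creator", "neutral")


def background_from_gc(gc: float) -> tuple[float, float, float, float]:
    """Base composition (A,C,G,T) implied by a GC fraction, AT/GC symmetric."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


def exact_label_counts(proportions: Sequence[float], n: int) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n SNPs to the three effect labels."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("effect_mix must be 3 non-negative proportions summing to 1")
    raw = p * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts), kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


@dataclass(frozen=True)
class PlantedSite:
    gene_symbol: str
    tf_name: str
    offset: int          # 0-based start within the promoter
    strand: str          # strand the motif instance reads 5'->3' on
    kind: str            # "site" (intact consensus) or "near_miss"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated fixture, reproducible from the seed."""

    planted_sites: tuple[PlantedSite, ...]
    snp_effects: dict[str, str]               # rsid -> destroyer|creator|neutral
    accessible_snps: frozenset[str]
    seed: int

    def rsids(self, label: str) -> list[str]:
        return sorted(r for r, lab in self.snp_effects.items() if lab == label)


@dataclass
class SyntheticFixture:
    """In-memory fixture plus writers for the standard on-disk formats."""

    genome: dict[str, str]
    promoter_specs: list[PromoterSpec]
    snps: list[SNPRecord]
    pfms: list[PFM]
    tracks: list[AccessibilityTrack]
    truth: SyntheticTruth
    background: tuple[float, float, float, float]
    params: dict

    def pwms(self, pseudocount: float = 0.8) -> list[PWM]:
        return [pfm_to_pwm(p, pseudocount=pseudocount, background=self.background)
                for p in self.pfms]

    def scan_config(self, **overrides) -> ScanConfig:
        """Default scoring config sharing the generator's base composition."""
        kwargs = dict(background=self.background)
        kwargs.update(overrides)
        return ScanConfig(**kwargs)

    def build_promoters(self) -> list[PseudoPromoter]:
        by_chrom: dict[str, list[SNPRecord]] = {}
        for snp in self.snps:
            by_chrom.setdefault(snp.chrom, []).append(snp)
        return [build_pseudopromoter(spec, self.genome, by_chrom.get(spec.chrom, []))
                for spec in self.promoter_specs]

    def manifest(self) -> dict:
        params = dict(self.params)
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]
        return {
            "seed": self.truth.seed,
            "params": params,
            "config_hash": digest,
            "snp_effects": dict(sorted(self.truth.snp_effects.items())),
            "accessible_snps": sorted(self.truth.accessible_snps),
            "planted_sites": [
                {"gene": s.gene_symbol, "tf": s.tf_name, "offset": s.offset,
                 "strand": s.strand, "kind": s.kind}
                for s in self.truth.planted_sites],
        }

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/TSV/BED/JASPAR files plus a JSON manifest with truth."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genome.fa").write_text(write_fasta(self.genome))
        (out / "snps.tsv").write_text(write_snp_table(self.snps))
        (out / "pfms.jaspar").write_text(write_jaspar_pfm(self.pfms))
        for track in self.tracks:
            (out / f"dnase_{track.cell_line}.bed").write_text(write_bed(track))
        lines = ["gene\tchrom\ttss\tstrand\tlength"]
        lines += [f"{s.gene_symbol}\t{s.chrom}\t{s.tss}\t{s.strand}\t{s.length}"
                  for s in self.promoter_specs]
        (out / "promoters.tsv").write_text("\n".join(lines) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")


def _make_pfms(rng: np.random.Generator, n_tfs: int, width: int) -> list[PFM]:
    pfms = []
    for t in range(n_tfs):
        consensus = rng.integers(0, 4, size=width)
        counts = np.full((4, width), _MEDIUM_COUNTS[1])
        counts[consensus, np.arange(width)] = _MEDIUM_COUNTS[0]
        anchor_base = consensus[ANCHOR_COL]
        counts[:, ANCHOR_COL] = _ANCHOR_COUNTS[1]
        counts[anchor_base, ANCHOR_COL] = _ANCHOR_COUNTS[0]
        pfms.append(PFM(matrix_id=f"SYN{t + 1:04d}", tf_name=f"TF{t + 1:02d}",
                        counts=counts))
    return pfms


def _slot_positions(rng: np.random.Generator, n: int, length: int, width: int) -> np.ndarray:
    lo, hi = width, length - 2 * width
    span = hi - lo - (n - 1) * _MIN_SLOT_SEP
    if span <= 0:
        raise ValueError(
            f"motif density too high: cannot place {n} non-overlapping slots "
            f"in a {length} bp promoter at separation {_MIN_SLOT_SEP}")
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    return lo + offsets + np.arange(n) * _MIN_SLOT_SEP


def _worst_base(pfm: PFM, col: int) -> int:
    return int(pfm.counts[:, col].argmin())


def generate_fixture(
    n_genes: int = 14,
    length: int = 2000,
    gc: float = 0.41,
    n_snps_per_gene: int = 8,
    effect_mix: Sequence[float] = (0.3, 0.3, 0.4),
    accessible_fraction: float = 0.7,
    n_tfs: int = 8,
    seed: int = 0,
    rbs_floor: float = 0.80,
) -> SyntheticFixture:
    """Generate a fully self-consistent fixture with planted ground truth.

    Proportions in ``effect_mix`` (destroyer, creator, neutral) are realized
    exactly over the total SNP count by largest-remainder rounding.
    ``accessible_fraction`` of all SNPs (rounded) are covered by open-
    chromatin peaks in at least one cell line; the remaining SNPs are
    covered in none. Identical arguments give byte-identical outputs.
    """
    bg = background_from_gc(gc)
    master = np.random.default_rng(seed)
    pfms = _make_pfms(master, n_tfs=n_tfs, width=MOTIF_WIDTH)
    pwms = [pfm_to_pwm(p, background=bg) for p in pfms]

    total = n_genes * n_snps_per_gene
    n_destroyer, n_creator, n_neutral = exact_label_counts(effect_mix, total)
    labels = (["destroyer"] * n_destroyer + ["creator"] * n_creator
              + ["neutral"] * n_neutral)
    master.shuffle(labels)

    genome: dict[str, str] = {}
    specs: list[PromoterSpec] = []
    all_snps: list[SNPRecord] = []
    planted: list[PlantedSite] = []
    effects: dict[str, str] = {}

    for gi in range(n_genes):
        gene = f"GENE{gi + 1:02d}"
        chrom = f"syn{gi + 1:02d}"
        gene_labels = labels[gi * n_snps_per_gene:(gi + 1) * n_snps_per_gene]
        for attempt in range(_MAX_GENE_ATTEMPTS):
            result = _generate_gene(
                gene, chrom, gene_labels, pfms, pwms, bg, length,
                n_snps_per_gene, rbs_floor,
                rng=np.random.default_rng([seed, 1000 + gi, attempt]))
            if result is not None:
                break
        else:
            raise RuntimeError(f"{gene}: could not realize truth labels in "
                               f"{_MAX_GENE_ATTEMPTS} attempts")
        contig, gene_snps, gene_sites = result
        genome[chrom] = contig
        specs.append(PromoterSpec(gene_symbol=gene, chrom=chrom, tss=length + 1,
                                  strand="+", length=length))
        all_snps.extend(gene_snps)
        planted.extend(gene_sites)
        for snp, label in zip(gene_snps, gene_labels):
            effects[snp.rsid] = label

    # accessibility: an exact fraction of all SNPs is covered somewhere
    n_accessible = int(round(accessible_fraction * len(all_snps)))
    order = master.permutation(len(all_snps))
    accessible_idx = sorted(order[:n_accessible])
    peaks: dict[str, list[tuple[str, int, int]]] = {cl: [] for cl in CELL_LINES}
    accessible: set[str] = set()
    for i in accessible_idx:
        snp = all_snps[i]
        accessible.add(snp.rsid)
        cells = [cl for cl in CELL_LINES if master.random() < 0.6]
        if not cells:
            cells = [CELL_LINES[int(master.integers(len(CELL_LINES)))]]
        p0 = snp.pos - 1
        iv = (snp.chrom, max(0, p0 - _PEAK_HALFWIDTH), p0 + _PEAK_HALFWIDTH + 1)
        for cl in cells:
            peaks[cl].append(iv)
    tracks = [AccessibilityTrack(cell_line=cl, intervals=tuple(peaks[cl]))
              for cl in CELL_LINES]

    truth = SyntheticTruth(
        planted_sites=tuple(planted), snp_effects=effects,
        accessible_snps=frozenset(accessible), seed=seed)
    params = {
        "n_genes": n_genes, "length": length, "gc": gc,
        "n_snps_per_gene": n_snps_per_gene, "effect_mix": list(effect_mix),
        "accessible_fraction": accessible_fraction, "n_tfs": n_tfs,
        "seed": seed, "rbs_floor": rbs_floor, "motif_width": MOTIF_WIDTH,
    }
    return SyntheticFixture(genome=genome, promoter_specs=specs, snps=all_snps,
                            pfms=pfms, tracks=tracks, truth=truth,
                            background=bg, params=params)


def _generate_gene(
    gene: str,
    chrom: str,
    gene_labels: list[str],
    pfms: list[PFM],
    pwms: list[PWM],
    bg: tuple[float, float, float, float],
    length: int,
    n_snps: int,
    rbs_floor: float,
    rng: np.random.Generator,
) -> Optional[tuple[str, list[SNPRecord], list[PlantedSite]]]:
    """One attempt at a gene; returns None when a chance motif match breaks
    the truth labels (the caller redraws with the next sub-seed)."""
    w = MOTIF_WIDTH
    seq = [BASES[b] for b in rng.choice(4, size=length, p=bg)]
    downstream = "".join(BASES[b] for b in rng.choice(4, size=100, p=bg))
    slots = _slot_positions(rng, n_snps, length, w)
    slot_order = rng.permutation(n_snps)

    n_planted = sum(1 for lab in gene_labels if lab != "neutral")
    if n_planted > len(pfms):
        raise ValueError(f"{gene}: {n_planted} planted sites exceed {len(pfms)} TFs; "
                         "increase n_tfs or reduce the destroyer/creator mix")
    tf_order = rng.permutation(len(pfms))

    snps: list[SNPRecord] = []
    sites: list[PlantedSite] = []
    planted_tf: dict[int, str] = {}  # pfm index -> kind
    tf_cursor = 0
    for si, label in enumerate(gene_labels):
        slot = int(slots[slot_order[si]])
        rsid = f"rs{9000000 + int(gene.removeprefix('GENE')) * 100 + si}"
        maf = float(rng.uniform(0.05, 0.5))
        if label == "neutral":
            pos0 = slot + w // 2
            major = seq[pos0]
            minor = rng.choice([b for b in BASES if b != major])
            snps.append(SNPRecord(rsid=rsid, chrom=chrom, pos=pos0 + 1,
                                  major_allele=major, minor_allele=str(minor), maf=maf))
            continue
        ti = int(tf_order[tf_cursor])
        tf_cursor += 1
        pfm = pfms[ti]
        strand = "+" if rng.random() < 0.5 else "-"
        consensus = pfm.consensus
        worst = BASES[_worst_base(pfm, ANCHOR_COL)]
        if label == "destroyer":
            site_seq = consensus
            anchor_major, anchor_minor = consensus[ANCHOR_COL], worst
            kind = "site"
        else:  # creator: near-miss site, minor allele restores consensus
            site_seq = consensus[:ANCHOR_COL] + worst + consensus[ANCHOR_COL + 1:]
            anchor_major, anchor_minor = worst, consensus[ANCHOR_COL]
            kind = "near_miss"
        planted_seq = site_seq if strand == "+" else revcomp(site_seq)
        seq[slot:slot + w] = list(planted_seq)
        if strand == "+":
            pos0 = slot + ANCHOR_COL
            major, minor = anchor_major, anchor_minor
        else:
            pos0 = slot + w - 1 - ANCHOR_COL
            major, minor = complement(anchor_major), complement(anchor_minor)
        snps.append(SNPRecord(rsid=rsid, chrom=chrom, pos=pos0 + 1,
                              major_allele=major, minor_allele=minor, maf=maf))
        sites.append(PlantedSite(gene_symbol=gene, tf_name=pfm.tf_name,
                                 offset=slot, strand=strand, kind=kind))
        planted_tf[ti] = label

    contig = "".join(seq) + downstream
    if not _verify_gene(gene, chrom, contig, snps, gene_labels, pwms,
                        planted_tf, length, rbs_floor):
        return None
    return contig, snps, sites


def _verify_gene(
    gene: str,
    chrom: str,
    contig: str,
    snps: list[SNPRecord],
    gene_labels: list[str],
    pwms: list[PWM],
    planted_tf: dict[int, str],
    length: int,
    rbs_floor: float,
) -> bool:
    """Check the attempt realizes its labels under the scoring machinery."""
    spec = PromoterSpec(gene_symbol=gene, chrom=chrom, tss=length + 1,
                        strand="+", length=length)
    pp = build_pseudopromoter(spec, {chrom: contig}, snps)
    for ti, pwm in enumerate(pwms):
        expected = 1 if ti in planted_tf else 0
        if count_homotypic_sites(pwm, pp.sequence, rbs_threshold=rbs_floor) != expected:
            return False
    label_by_rsid = {snp.rsid: lab for snp, lab in zip(snps, gene_labels)}
    for snp, offset in pp.snps:
        minor_seq = apply_minor_allele(pp, snp.rsid)
        label = label_by_rsid[snp.rsid]
        if label == "neutral":
            for pwm in pwms:
                result = scan_snp(pwm, pp.sequence, minor_seq, offset)
                if result and max(result[0].rbs, result[1].rbs) >= rbs_floor:
                    return False
            continue
        best = max(
            (scan_snp(pwm, pp.sequence, minor_seq, offset) for pwm in pwms),
            key=lambda r: max(r[0].rbs, r[1].rbs) if r else -1.0)
        ws_major, ws_minor = best
        impact = 100.0 * (ws_minor.rbs - ws_major.rbs) / ws_major.rbs
        if label == "destroyer":
            if not (ws_major.rbs > 0.99 and impact < -10.0):
                return False
        else:
            if not (ws_minor.rbs > 0.99 and ws_major.rbs >= rbs_floor and impact > 10.0):
                return False
    return True
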