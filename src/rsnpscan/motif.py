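"""PFM-to-PWM transformation and both-strand scanning.

The scanner reports a *relative binding score* (RBS): the log-odds score of
a window, min-max normalized to [0, 1] using the lowest and highest scores
the matrix can achieve. 1.0 is the consensus site, 0.0 the anti-consensus.
Scores on the minus strand are computed on the reverse complement of the
window with the same matrix, which is equivalent to scoring with the
reverse-complemented matrix at the same offset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import BASES, revcomp
from .formats import PFM

__all__ = [
    "PWM", "WindowScore", "pfm_to_pwm", "relative_score", "scan_snp",
    "count_homotypic_sites", "window_relative_scores",
]

_CODE_TABLE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; anything else -> 4."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix derived from a PFM.

    ``weights[b, j] = log2((count[b,j] + pc*bg[b]) / (total_j + pc) / bg[b])``
    with pseudocount ``pc`` split across bases proportionally to the
    background. ``score_min``/``score_max`` are the sums of the column-wise
    minima/maxima and anchor the min-max normalization.
    """

    source: PFM
    weights: np.ndarray          # (4, w)
    background: np.ndarray      # (4,)
    pseudocount: float
    score_min: float
    score_max: float
    # weights with complemented rows and reversed columns; scoring the plus
    # strand with these equals scoring the reverse complement of the window
    weights_rc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"{self.source.matrix_id}: non-finite PWM weights")
        if self.score_min > self.score_max:
            raise ValueError(f"{self.source.matrix_id}: score_min above score_max")
        object.__setattr__(self, "weights_rc", self.weights[::-1, ::-1].copy())

    def _span(self) -> float:
        # all-uniform matrices are valid PWMs but have no score range to
        # normalize over; scoring them is undefined
        span = self.score_max - self.score_min
        if span <= 0:
            raise ValueError(
                f"{self.source.matrix_id}: degenerate matrix (score_min == score_max)")
        return span

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def tf_name(self) -> str:
        return self.source.tf_name

    def to_tsv(self) -> str:
        """Debug dump: one row per base, weights to 4 decimals."""
        lines = ["\t".join(["base"] + [str(j) for j in range(self.width)])]
        for b, row in zip(BASES, self.weights):
            lines.append("\t".join([b] + [f"{w:.4f}" for w in row]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class WindowScore:
    """Best-window result for one allele: offset, strand, and RBS in [0,1]."""

    offset: int
    strand: str  # '+' or '-'
    rbs: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.rbs <= 1.0:
            raise ValueError(f"rbs {self.rbs} outside [0, 1]")


def pfm_to_pwm(
    pfm: PFM,
    pseudocount: float = 0.8,
    background: Optional[Sequence[float]] = None,
) -> PWM:
    """Convert counts to a log2-odds PWM with a background-split pseudocount.

    The default pseudocount 0.8 follows the JASPAR convention; the default
    background is uniform. Raises on a non-positive pseudocount or an
    invalid background distribution.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError(f"{pfm.matrix_id}: all-zero column")
    probs = (counts + pseudocount * bg[:, None]) / (totals[None, :] + pseudocount)
    weights = np.log2(probs / bg[:, None])
    return PWM(
        source=pfm, weights=weights, background=bg, pseudocount=pseudocount,
        score_min=float(weights.min(axis=0).sum()),
        score_max=float(weights.max(axis=0).sum()),
    )


def relative_score(pwm: PWM, window: str) -> float:
    """Min-max normalized log-odds score of one window; requires ACGT only."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != matrix width {pwm.width}")
    codes = encode(window)
    if np.any(codes > 3):
        raise ValueError(f"window {window!r} contains non-ACGT characters")
    raw = float(pwm.weights[codes, np.arange(pwm.width)].sum())
    return (raw - pwm.score_min) / pwm._span()


def window_relative_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """RBS of every window on both strands of ``seq``.

    Returns ``(plus, minus)`` arrays of length ``len(seq) - w + 1``; windows
    containing non-ACGT characters are NaN. ``minus[o]`` is the score of the
    reverse complement of ``seq[o:o+w]``.
    """
    w = pwm.width
    if len(seq) < w:
        return np.empty(0), np.empty(0)
    codes = encode(seq)
    windows = sliding_window_view(codes, w)
    cols = np.arange(w)
    padded = np.vstack([pwm.weights, np.zeros(w)])        # row 4 absorbs 'N'
    padded_rc = np.vstack([pwm.weights_rc, np.zeros(w)])
    plus = padded[windows, cols].sum(axis=1)
    minus = padded_rc[windows, cols].sum(axis=1)
    invalid = (windows > 3).any(axis=1)
    plus[invalid] = np.nan
    minus[invalid] = np.nan
    span = pwm._span()
    return (plus - pwm.score_min) / span, (minus - pwm.score_min) / span


def scan_snp(
    pwm: PWM,
    seq_major: str,
    seq_minor: str,
    snp_offset: int,
) -> Optional[tuple[WindowScore, WindowScore]]:
    """Score both alleles of a SNP at the best overlapping window.

    Every window/strand combination covering ``snp_offset`` is a candidate
    (minus-strand candidates score the reverse complement of the window).
    The reported pair comes from the single (offset, strand) maximizing
    ``max(RBS_major, RBS_minor)`` so both alleles are compared at the same
    site; ties resolve to the smaller offset, then '+' before '-'. Windows
    containing N are skipped. Returns None when no candidate window exists.
    """
    if len(seq_major) != len(seq_minor):
        raise ValueError("allele sequences must have equal length")
    if not 0 <= snp_offset < len(seq_major):
        raise ValueError(f"snp_offset {snp_offset} outside sequence")
    w = pwm.width
    lo = max(0, snp_offset - w + 1)
    hi = min(len(seq_major) - w, snp_offset)
    best: Optional[tuple[float, WindowScore, WindowScore]] = None
    for o in range(lo, hi + 1):
        win_major = seq_major[o:o + w]
        win_minor = seq_minor[o:o + w]
        for strand in "+-":
            try:
                if strand == "+":
                    r_major = relative_score(pwm, win_major)
                    r_minor = relative_score(pwm, win_minor)
                else:
                    r_major = relative_score(pwm, revcomp(win_major))
                    r_minor = relative_score(pwm, revcomp(win_minor))
            except ValueError:  # window contains N
                continue
            key = max(r_major, r_minor)
            if best is None or key > best[0] + 1e-12:
                best = (key,
                        WindowScore(offset=o, strand=strand, rbs=r_major),
                        WindowScore(offset=o, strand=strand, rbs=r_minor))
    if best is None:
        return None
    return best[1], best[2]


def count_homotypic_sites(pwm: PWM, seq: str, rbs_threshold: float = 0.80) -> int:
    """Count non-overlapping sites with RBS >= threshold on either strand.

    Candidate windows are taken greedily best-score-first; a window is
    suppressed when it overlaps an already accepted one (regardless of
    strand). This is the homotypic redundancy HR of a transcription factor
    within one promoter.
    """
    if not 0.0 < rbs_threshold <= 1.0:
        raise ValueError("rbs_threshold must be in (0, 1]")
    plus, minus = window_relative_scores(pwm, seq)
    w = pwm.width
    candidates: list[tuple[float, int, int]] = []  # (-rbs, offset, strand_rank)
    for strand_rank, scores in enumerate((plus, minus)):
        for o in np.flatnonzero(~np.isnan(scores) & (scores >= rbs_threshold)):
            candidates.append((-float(scores[o]), int(o), strand_rank))
    candidates.sort()
    kept_offsets: list[int] = []
    for _neg_rbs, o, _rank in candidates:
        if all(abs(o - k) >= w for k in kept_offsets):
            kept_offsets.append(o)
    return len(kept_offsets)
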