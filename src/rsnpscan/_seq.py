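"""Tiny DNA-sequence helpers shared across modules."""
from __future__ import annotations

BASES = "ACGT"
VALID_BASES = frozenset("ACGTN")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    """Watson-Crick complement of a single base (N maps to N)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]
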