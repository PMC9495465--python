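"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from rsnpscan.formats import PFM
from rsnpscan.motif import PWM, pfm_to_pwm, relative_score
from rsnpscan.synthdata import generate_fixture

BASES = "ACGT"

# fixed seeds: the study conditions of the synthetic experiments
SMALL_SEED = 11
RECOVERY_SEED = 1287


@pytest.fixture(scope="session")
def toy_pfm() -> PFM:
    """Minimal two-column matrix with consensus AC."""
    return PFM(matrix_id="MX0001", tf_name="TOY",
               counts=np.array([[10.0, 0.0], [0.0, 10.0], [0.0, 0.0], [0.0, 0.0]]))


@pytest.fixture(scope="session")
def random_pfm() -> PFM:
    """A 6-wide matrix with rough, uneven counts for oracle comparisons."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 20, size=(4, 6)).astype(float)
    counts[rng.integers(0, 4, size=6), np.arange(6)] += 5  # no all-zero column
    return PFM(matrix_id="RND0001", tf_name="RND", counts=counts)


@pytest.fixture(scope="session")
def random_pwm(random_pfm) -> PWM:
    return pfm_to_pwm(random_pfm)


@pytest.fixture(scope="session")
def small_fixture():
    """Three synthetic genes; enough to exercise every pipeline stage."""
    return generate_fixture(n_genes=3, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def recovery_fixture():
    """The 20-gene fixture used for the end-to-end recovery experiment."""
    return generate_fixture(n_genes=20, seed=RECOVERY_SEED)


def brute_force_scan(pwm: PWM, seq_major: str, seq_minor: str, snp_offset: int):
    """Exhaustive oracle for the SNP scanner: enumerate every window/strand
    covering the SNP and report the pair at the overall best site."""
    from rsnpscan._seq import revcomp

    w = pwm.width
    best = None
    for o in range(max(0, snp_offset - w + 1), min(len(seq_major) - w, snp_offset) + 1):
        for strand in "+-":
            wa, wb = seq_major[o:o + w], seq_minor[o:o + w]
            if strand == "-":
                wa, wb = revcomp(wa), revcomp(wb)
            if set(wa) - set(BASES) or set(wb) - set(BASES):
                continue
            ra, rb = relative_score(pwm, wa), relative_score(pwm, wb)
            key = max(ra, rb)
            if best is None or key > best[0] + 1e-12:
                best = (key, o, strand, ra, rb)
    return best


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=n))
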