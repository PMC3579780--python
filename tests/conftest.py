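import numpy as np
import pytest

from ecrkit.seqcoords import SequenceRecord
from ecrkit.pairwise import PairwiseAlignment
from ecrkit.seqcoords import GenomicInterval
from ecrkit.tfbs import PWM

BASES = "ACGT"


def make_pwm(consensus: str, peak: float = 20.0, name: str = "toy") -> PWM:
    """Strongly peaked count matrix whose consensus is the given string."""
    counts = np.zeros((4, len(consensus)))
    for j, c in enumerate(consensus):
        counts[BASES.index(c), j] = peak
    return PWM(name, counts)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def random_alignment(rng: np.random.Generator, ncols: int = 600,
                     p_mismatch: float = 0.2, p_gap: float = 0.05,
                     seq_id_a: str = "a", seq_id_b: str = "b"
                     ) -> PairwiseAlignment:
    """Random gapped alignment pair with controlled mismatch/gap density."""
    row_a, row_b = [], []
    for _ in range(ncols):
        u = rng.random()
        base = BASES[rng.integers(4)]
        if u < p_gap / 2:
            row_a.append("-")
            row_b.append(base)
        elif u < p_gap:
            row_a.append(base)
            row_b.append("-")
        elif u < p_gap + p_mismatch:
            other = BASES[(BASES.index(base) + 1 + rng.integers(3)) % 4]
            row_a.append(base)
            row_b.append(other)
        else:
            row_a.append(base)
            row_b.append(base)
    ra, rb = "".join(row_a), "".join(row_b)
    la, lb = len(ra.replace("-", "")), len(rb.replace("-", ""))
    return PairwiseAlignment(
        ra, rb,
        a_span=GenomicInterval(seq_id_a, 1, la),
        b_span=GenomicInterval(seq_id_b, 1, lb))


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    union = a.length + b.length - inter
    return inter / union


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130222)


@pytest.fixture
def toy_pwm() -> PWM:
    return make_pwm("TGACTACG")
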