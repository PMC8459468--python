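import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from backsplice.annotation import Gene, GenomeAnnotation, Transcript

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Independent reverse-complement oracle for the tests."""
    return seq.translate(_COMP)[::-1]


def _arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def placement_mismatches(ref: str, read: str) -> np.ndarray:
    """Mismatch count of the read at every ungapped placement on ref.

    Vectorized exhaustive oracle; any N (read or reference) counts as a
    mismatch.  Returns an empty array when the read does not fit.
    """
    r, q = _arr(ref), _arr(read)
    if len(r) < len(q):
        return np.empty(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(r, len(q))
    mm = (win != q).sum(axis=1)
    n = ord("N")
    mm = mm + ((win == n) & (q == n)).sum(axis=1)
    return mm


def oracle_junction_placements(
    read: str, ref: str, offset: int, j: int, m: int
) -> list[tuple[int, int]]:
    """Exhaustive sliding-window oracle for junction matching.

    Returns all (mismatches_outside_seed, placement) pairs where the read
    covers >= j bases on each side of the junction, the 2j seed matches
    exactly and at most m mismatches occur outside the seed.
    """
    L = len(read)
    out = []
    lo, hi = offset - j + 1, offset + j + 1  # seed zone on the reference
    for p in range(len(ref) - L + 1):
        if not (p <= lo and p + L >= hi):
            continue
        ok = True
        mm = 0
        for r in range(L):
            a, b = read[r], ref[p + r]
            bad = a != b or a == "N"
            if lo <= p + r < hi:
                if bad:
                    ok = False
                    break
            elif bad:
                mm += 1
        if ok and mm <= m:
            out.append((mm, p))
    return out


def oracle_has_linear_placement(read: str, targets: dict[str, str], m: int) -> bool:
    """Exhaustive exclusion oracle: any end-to-end placement with <= m
    mismatches on any target, either strand."""
    for seq in targets.values():
        for probe in (read, revcomp(read)):
            mm = placement_mismatches(seq, probe)
            if len(mm) and mm.min() <= m:
                return True
    return False


@pytest.fixture
def toy_transcript() -> Transcript:
    return Transcript(
        id="txA",
        gene_id="gA",
        chrom="chr1",
        strand="+",
        exons=((100, 200), (300, 500)),
    )


@pytest.fixture
def toy_annotation(toy_transcript) -> GenomeAnnotation:
    gene = Gene(id="gA", chrom="chr1", strand="+", transcripts=(toy_transcript,))
    return GenomeAnnotation([gene])


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(1234)
    return {"chr1": random_seq(rng, 1200)}
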