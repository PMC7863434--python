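import numpy as np
import pytest

from vir.align import encode


def sw_oracle(query: str, target: str, match=1, mismatch=-4,
              gap_open=-6, gap_extend=-1) -> int:
    """Plain, full-matrix affine Smith-Waterman best score (no traceback).

    Independent of the package's kernel: three dense matrices, no seeding,
    no windows. Gap of length L costs gap_open + (L-1)*gap_extend; N never
    matches.
    """
    q = encode(query)
    t = encode(target)
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def random_seq(rng: np.random.Generator, length: int, alphabet="ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        r = rng.random()
        if r < rate * 0.6:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        elif r < rate * 0.8:
            continue  # deletion
        elif r < rate:
            out.append(c)
            out.append(rng.choice(list("ACGT")))  # insertion
        else:
            out.append(c)
    return "".join(out) or "A"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
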