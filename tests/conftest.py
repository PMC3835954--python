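import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# --- independent oracles (naive reimplementations used only by tests) ------


def naive_window_count(row_a: str, row_b: str, k: int):
    """All-windows scan: (m, starts) counting windows of k identical
    non-gap, non-N columns."""
    L = len(row_a)
    starts = []
    for t in range(L - k + 1):
        ok = all(
            row_a[i] == row_b[i] and row_a[i] not in "-N" and row_b[i] != "-"
            for i in range(t, t + k)
        )
        if ok:
            starts.append(t + 1)
    return len(starts), starts


def naive_longest_run(row_a: str, row_b: str) -> int:
    best = cur = 0
    for x, y in zip(row_a, row_b):
        if x == y and x not in "-N":
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_pair(rng, L: int, n_snps: int):
    """Gap-free pair of length L with SNPs at n_snps random positions."""
    bases = np.array(list("ACGT"))
    a = rng.choice(bases, size=L)
    b = a.copy()
    pos = rng.choice(L, size=n_snps, replace=False)
    for p in pos:
        alts = [x for x in "ACGT" if x != a[p]]
        b[p] = alts[rng.integers(3)]
    return "".join(a), "".join(b), sorted(int(p) + 1 for p in pos)
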