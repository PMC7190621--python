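"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately implemented from first principles, without calling
the code path it checks: the Fisher tail by exact integer binomials, Vst by
explicit variance sums, and the map-order tolerance rule by exhaustive
enumeration of deletion subsets.
"""

from functools import lru_cache
from math import comb


def fisher_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact one-sided hypergeometric tail P(X >= a) with all margins fixed."""
    r1, r2, c1 = a + b, c + d, a + c
    num = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(a, min(r1, c1) + 1)
        if 0 <= c1 - x <= r2
    )
    return num / comb(r1 + r2, c1)


def vst_oracle(values, labels) -> float:
    """Vst by explicit variance decomposition (population variance, size weights)."""
    def popvar(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    groups = []
    for lab in dict.fromkeys(labels):
        groups.append([v for v, l in zip(values, labels) if l == lab])
    assert len(groups) == 2
    g1, g2 = groups
    vt = popvar(list(g1) + list(g2))
    if vt == 0:
        return 0.0
    vs = (len(g1) * popvar(g1) + len(g2) * popvar(g2)) / (len(g1) + len(g2))
    return (vt - vs) / vt


@lru_cache(maxsize=None)
def _masks_by_cost(n: int):
    """All deletion subsets of n probes, sorted by how many deletions are
    charged (a deletion is free only when no other deletion sits within two
    map positions, i.e. within its window of three consecutive probes)."""
    entries = []
    for mask in range(1 << n):
        ds = {i for i in range(n) if mask >> i & 1}
        cost = sum(
            1 for i in ds if (i - 1 in ds) or (i - 2 in ds) or (i + 1 in ds) or (i + 2 in ds)
        )
        kept = tuple(i for i in range(n) if i not in ds)
        entries.append((cost, kept))
    entries.sort(key=lambda e: e[0])
    return tuple(entries)


def map_order_oracle(coords) -> int:
    """Minimum charged deletions to make ``coords`` strictly monotone
    (either orientation), by scanning deletion subsets in cost order."""
    coords = list(coords)
    for cost, kept in _masks_by_cost(len(coords)):
        vals = [coords[i] for i in kept]
        if all(x < y for x, y in zip(vals, vals[1:])) or all(
            x > y for x, y in zip(vals, vals[1:])
        ):
            return cost
    raise AssertionError("unreachable: deleting everything is always monotone")
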