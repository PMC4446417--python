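"""Independent oracles used to cross-check the implementation.

Everything here recomputes expected values by brute force (enumeration,
tail summation, exhaustive triple scans) without sharing code paths with
the package.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from cassex.io import Junction


def wilcoxon_exact_enumeration(differences: Sequence[float]) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped; magnitudes must be tie-free.  The
    statistic is the positive-rank sum W+; the two-sided p-value doubles
    the smaller tail mass min(P[W+ <= w], P[W+ >= w]), capped at 1.
    """
    d = [x for x in differences if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: abs(d[i])), start=1)}
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    w_values = []
    for signs in itertools.product((0, 1), repeat=n):
        w_values.append(sum(ranks[i] for i in range(n) if signs[i]))
    total = len(w_values)
    lower = sum(w <= w_obs for w in w_values) / total
    upper = sum(w >= w_obs for w in w_values) / total
    return min(1.0, 2 * min(lower, upper))


def bh_stepup(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values computed from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running_min = min(running_min, p[i] * m / (rank_idx + 1))
        q[i] = running_min
    return np.minimum(q, 1.0)


def hypergeom_upper_tail(overlap: int, n_universe: int, n_marked: int, n_draws: int) -> float:
    """P[X >= overlap] by direct summation of hypergeometric terms."""
    total = 0.0
    denom = math.comb(n_universe, n_draws)
    for k in range(overlap, min(n_marked, n_draws) + 1):
        if n_draws - k > n_universe - n_marked:
            continue
        total += math.comb(n_marked, k) * math.comb(n_universe - n_marked, n_draws - k) / denom
    return min(1.0, total)


def hypergeom_by_enumeration(set_a: Set, set_b: Set, universe: Set) -> float:
    """P[|draw ∩ B| >= |A ∩ B|] by enumerating every |A|-subset of the universe."""
    target = len(set_a & set_b)
    hits = 0
    total = 0
    for draw in itertools.combinations(sorted(universe), len(set_a)):
        total += 1
        if len(set(draw) & set_b) >= target:
            hits += 1
    return hits / total


def _strand_ok(a: str, b: str) -> bool:
    return a == b or a == "unknown" or b == "unknown"


def triplets_bruteforce(junctions: Sequence[Junction]) -> Set[Tuple[str, int, int, int, int]]:
    """Exhaustive scan over ALL ordered junction triples (vectorised).

    Returns the set of (chrom, UJ.start, UJ.end, DJ.start, DJ.end) keys of
    valid cassette triplets: SJ shares both outer boundaries, the inner
    junctions leave at least one exonic base between them, and the three
    strands are jointly compatible (at most one defined strand value).
    """
    js = list(junctions)
    n = len(js)
    if n < 3:
        return set()
    chrom = np.array([j.chrom for j in js])
    start = np.array([j.start for j in js])
    end = np.array([j.end for j in js])
    strand = np.array([j.strand for j in js])

    same_chrom = chrom[:, None] == chrom[None, :]
    compat = (
        (strand[:, None] == strand[None, :])
        | (strand[:, None] == "unknown")
        | (strand[None, :] == "unknown")
    )
    # pairwise conditions, then combined over every ordered triple (u, d, s)
    ud_ok = same_chrom & compat & (start[None, :] >= end[:, None] + 2)  # d starts >= u.end+2
    us_ok = same_chrom & compat & (start[None, :] == start[:, None])  # s.start == u.start
    ds_ok = same_chrom & compat & (end[None, :] == end[:, None])  # s.end == d.end
    s_longer_u = end[None, :] > end[:, None]  # s.end > u.end

    triple = (
        ud_ok[:, :, None]
        & us_ok[:, None, :]
        & ds_ok[None, :, :]
        & s_longer_u[:, None, :]
    )
    # distinct junction objects in the three roles
    idx = np.arange(n)
    triple &= idx[:, None, None] != idx[None, None, :]
    triple &= idx[None, :, None] != idx[None, None, :]
    triple &= idx[:, None, None] != idx[None, :, None]

    keys = set()
    for u, d, s in zip(*np.nonzero(triple)):
        # joint strand compatibility: the three strands carry at most one
        # defined value (pairwise checks alone admit +,- pairs via unknown)
        defined = {x for x in (strand[u], strand[d], strand[s]) if x != "unknown"}
        if len(defined) > 1:
            continue
        keys.add((str(chrom[u]), int(start[u]), int(end[u]), int(start[d]), int(end[d])))
    return keys


def chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pearson chi-square statistic for a 2×2 table, from the definition."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())
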