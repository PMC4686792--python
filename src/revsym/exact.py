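"""Exact minimum-cost sorting for small permutations.

The state space of all permutations of a given length (times all sign
assignments in the signed case) forms a weighted graph: vertices are
permutations, edges connect permutations one inversion apart, and the edge
weight is the inversion's cost.  Because inversions are involutions the
graph is undirected, so a single-source Dijkstra run from the identity
yields the optimal sorting cost of every permutation at once, together with
predecessor links from which one optimal scenario can be reconstructed.

States are indexed densely: the element order is ranked with the factorial
number system and, for signed permutations, multiplied by a sign bitmask,
giving ranks in ``[0, n!)`` or ``[0, 2^n * n!)``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

from .permutation import Inversion, Permutation, SortingScenario, identity, inversion_cost

#: Default refusal bounds: the unsigned space at n = 10 (3.6M states) and the
#: signed space at n = 8 (10.3M states) outgrow interactive memory/time.
MAX_N_UNSIGNED = 9
MAX_N_SIGNED = 7


class StateSpaceIndex:
    """Dense invertible ranking of the permutation state space.

    The magnitude sequence is ranked lexicographically via the factorial
    number system; signed states append an ``n``-bit sign mask (bit ``k - 1``
    set iff position ``k`` is negative), so
    ``rank = order_rank * 2**n + mask``.
    """

    def __init__(self, n: int, signed: bool):
        self.n = n
        self.signed = signed
        self._fact = [1] * (n + 1)
        for k in range(2, n + 1):
            self._fact[k] = self._fact[k - 1] * k
        self.size = self._fact[n] * (2**n if signed else 1)

    def rank(self, perm: Permutation) -> int:
        n = self.n
        if perm.n != n or perm.signed != self.signed:
            raise ValueError("permutation does not belong to this state space")
        mags = [abs(e) for e in perm.elements]
        avail = list(range(1, n + 1))
        r = 0
        for k, m in enumerate(mags):
            idx = avail.index(m)
            r += idx * self._fact[n - 1 - k]
            avail.pop(idx)
        if self.signed:
            mask = 0
            for k, e in enumerate(perm.elements):
                if e < 0:
                    mask |= 1 << k
            r = r * (2**n) + mask
        return r

    def unrank(self, r: int) -> Permutation:
        n = self.n
        if not 0 <= r < self.size:
            raise ValueError(f"rank {r} outside [0, {self.size})")
        mask = 0
        if self.signed:
            r, mask = divmod(r, 2**n)
        avail = list(range(1, n + 1))
        mags = []
        for k in range(n):
            idx, r = divmod(r, self._fact[n - 1 - k])
            mags.append(avail.pop(idx))
        if self.signed:
            mags = [-m if mask >> k & 1 else m for k, m in enumerate(mags)]
        return Permutation(tuple(mags), self.signed)


@dataclass
class OptimalResult:
    permutation: Permutation
    cost: int
    scenario: SortingScenario


_CACHE: dict[tuple[int, bool], tuple[StateSpaceIndex, list[int], list[Optional[tuple[int, Inversion]]]]] = {}


def exact_all(
    n: int,
    signed: bool,
    max_n_unsigned: int = MAX_N_UNSIGNED,
    max_n_signed: int = MAX_N_SIGNED,
) -> tuple[StateSpaceIndex, list[int], list[Optional[tuple[int, Inversion]]]]:
    """Optimal sorting cost of every permutation of length ``n``.

    Returns the state index, the distance array (rank -> optimal cost) and a
    predecessor array (rank -> (previous rank, inversion)) for scenario
    recovery.  Results are memoised per ``(n, signed)``.  Edges are
    enumerated in increasing ``(i, j)`` order and predecessors follow
    first-improvement, so the recovered scenarios are deterministic.
    """
    bound = max_n_signed if signed else max_n_unsigned
    if n > bound:
        raise ValueError(
            f"{'signed' if signed else 'unsigned'} exact solving refused for n={n} > {bound}; "
            "raise the bound explicitly if you have the memory and time"
        )
    key = (n, signed)
    if key in _CACHE:
        return _CACHE[key]
    index = StateSpaceIndex(n, signed)
    ident = identity(n, signed)
    inversions = list(ident.inversions())
    costs = [inversion_cost(n, inv) for inv in inversions]
    INF = float("inf")
    dist: list[int] = [INF] * index.size  # type: ignore[list-item]
    pred: list[Optional[tuple[int, Inversion]]] = [None] * index.size
    src = index.rank(ident)
    dist[src] = 0
    heap = [(0, src)]
    while heap:
        d, r = heapq.heappop(heap)
        if d > dist[r]:
            continue
        perm = index.unrank(r)
        for inv, c in zip(inversions, costs):
            nr = index.rank(perm.apply(inv))
            nd = d + c
            if nd < dist[nr]:
                dist[nr] = nd
                pred[nr] = (r, inv)
                heapq.heappush(heap, (nd, nr))
    _CACHE[key] = (index, dist, pred)
    return _CACHE[key]


def exact_cost(
    perm: Permutation,
    max_n_unsigned: int = MAX_N_UNSIGNED,
    max_n_signed: int = MAX_N_SIGNED,
) -> OptimalResult:
    """Optimal cost and one optimal scenario for a single permutation.

    The shortest path runs from the identity; since every edge is an
    involution, replaying its inversions from ``perm`` in reverse path order
    reaches the identity at the same total cost.
    """
    index, dist, pred = exact_all(perm.n, perm.signed, max_n_unsigned, max_n_signed)
    r = index.rank(perm)
    steps: list[tuple[Inversion, int]] = []
    while pred[r] is not None:
        prev, inv = pred[r]
        steps.append((inv, inversion_cost(perm.n, inv)))
        r = prev
    sc = SortingScenario(perm, steps, method="exact")
    sc.validate()
    return OptimalResult(perm, dist[index.rank(perm)], sc)
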